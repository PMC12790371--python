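"""Forward simulation of raster-scanned, azimuthally segmented projections.

For every scan point and reduced azimuthal segment the noiseless signal is
the line integral of the voxel reciprocal-space maps evaluated at the
probing direction of that segment,

    s(ray, seg, q) = sum_vox W[ray, vox] * S_vox(q) * f_vox(u(seg, rotation)),

with W the exact Siddon path lengths (um) and S the per-voxel radial factor.
Counts are Poisson distributed with expectation
``signal * flux * dwell * transmission``; the transmission itself follows
Beer-Lambert, T = exp(-∫ mu dl), as recorded by a semi-transparent
beamstop in the real experiment.

Noise streams are split per (rotation, repetition) from one master seed
with `numpy.random.SeedSequence` spawn keys, so projections can be
simulated in any order with bit-identical results.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .geometry import AcquisitionGeometry
from .phantom import Phantom
from .projector import Projector


@dataclass
class ProjectionScan:
    """One raster-scanned projection after 16 -> 8 segment reduction."""

    phi: float
    chi: float
    segments: np.ndarray  # (n_slow, n_fast, n_reduced_segments, n_q) counts
    transmission: np.ndarray  # (n_slow, n_fast) in (0, 1]
    dwell_time: float
    flux: float
    q_edges: np.ndarray
    noiseless: bool = False

    def __post_init__(self):
        if np.any(self.segments < 0):
            raise ValueError("counts must be nonnegative")
        if np.any(self.transmission <= 0) or np.any(self.transmission > 1):
            raise ValueError("transmission must lie in (0, 1]")

    @property
    def n_reduced_segments(self) -> int:
        return self.segments.shape[2]

    @property
    def n_q(self) -> int:
        return self.segments.shape[3]

    def copy(self) -> "ProjectionScan":
        return replace(self, segments=self.segments.copy(),
                       transmission=self.transmission.copy())


def _rng_for(seed, rotation_index: int, stream: int = 0) -> np.random.Generator:
    return np.random.Generator(
        np.random.Philox(np.random.SeedSequence(seed, spawn_key=(rotation_index, stream)))
    )


def noiseless_signal(phantom: Phantom, projector: Projector, k: int) -> np.ndarray:
    """Expected per-(ray, segment, q) intensity before flux/dwell/noise.

    Returns array (n_slow, n_fast, n_seg, n_q).  Linear in the phantom's
    coefficients, so the signal of a sum of phantoms is the sum of signals.
    """
    geom = projector.geometry
    w = projector.weights(k)
    y = projector.sh_matrix(k)  # (n_seg, 6)
    coeffs = phantom.sh_coeffs()  # (n_vox, 6)
    radial = phantom.radial_factors(geom.q_centers)  # (n_vox, n_q)
    n_seg, n_q = y.shape[0], geom.n_q
    out = np.empty((projector.n_rays, n_seg, n_q))
    for iq in range(n_q):
        proj = w @ (coeffs * radial[:, iq : iq + 1])  # (n_rays, 6)
        out[:, :, iq] = proj @ y.T
    return out.reshape(geom.n_slow, geom.n_fast, n_seg, n_q)


def simulate_scan(
    phantom: Phantom,
    geometry: AcquisitionGeometry,
    rotation_index: int,
    flux: float = 1.0e6,
    seed: int = 0,
    noiseless: bool = False,
    projector: Projector | None = None,
    _stream: int = 0,
) -> ProjectionScan:
    """Simulate one projection scan (counts + transmission).

    ``flux`` is incident photons per second per point; expected counts are
    ``signal * flux * dwell * transmission``.  With ``noiseless=True`` the
    expectation itself is returned instead of a Poisson draw.
    """
    if flux <= 0:
        raise ValueError("flux must be positive")
    if projector is None:
        projector = Projector(phantom.shape, phantom.voxel_size, geometry)
    geom = geometry
    phi, chi = geom.rotations[rotation_index]
    w = projector.weights(rotation_index)
    signal = noiseless_signal(phantom, projector, rotation_index)
    mu_path = (w @ phantom.attenuation.reshape(-1)).reshape(geom.n_slow, geom.n_fast)
    transmission = np.exp(-mu_path)
    expected = signal * (flux * geom.dwell_time) * transmission[:, :, None, None]
    if noiseless:
        counts = expected
    else:
        rng = _rng_for(seed, rotation_index, _stream)
        counts = rng.poisson(expected).astype(float)
    return ProjectionScan(
        phi=phi, chi=chi, segments=counts, transmission=transmission,
        dwell_time=geom.dwell_time, flux=flux, q_edges=geom.q_edges.copy(),
        noiseless=noiseless,
    )


def simulate_tomogram(
    phantom: Phantom,
    geometry: AcquisitionGeometry,
    flux: float = 1.0e6,
    seed: int = 0,
    noiseless: bool = False,
    dtype=np.float64,
) -> list[ProjectionScan]:
    """Simulate every rotation of the protocol, sharing one projector cache."""
    projector = Projector(phantom.shape, phantom.voxel_size, geometry)
    scans = []
    for k in range(geometry.n_rotations):
        scan = simulate_scan(phantom, geometry, k, flux=flux, seed=seed,
                             noiseless=noiseless, projector=projector)
        scan.segments = scan.segments.astype(dtype)
        scans.append(scan)
    return scans


def simulate_framerate_series(
    phantom: Phantom,
    geometry: AcquisitionGeometry,
    rates_hz,
    flux: float = 1.0e6,
    seed: int = 0,
    rotation_index: int = 0,
    noiseless: bool = False,
) -> list[ProjectionScan]:
    """One scan per acquisition rate at identical geometry and flux.

    The dwell time is 1/rate, so the expected counts scale inversely with
    the rate — the photon-statistics ladder of a 10...500 Hz dose series.
    Noise streams for the different rates are independent substreams of
    ``seed``.
    """
    rates = np.asarray(list(rates_hz), dtype=float)
    if np.any(rates <= 0):
        raise ValueError("rates must be positive")
    if np.any(np.diff(rates) < 0):
        raise ValueError("rates must be sorted ascending")
    projector = Projector(phantom.shape, phantom.voxel_size, geometry)
    scans = []
    for i, rate in enumerate(rates):
        geom_i = AcquisitionGeometry(
            rotations=geometry.rotations,
            n_fast=geometry.n_fast,
            n_slow=geometry.n_slow,
            step=geometry.step,
            q_edges=geometry.q_edges,
            n_segments=geometry.n_segments,
            dwell_time=1.0 / rate,
        )
        projector.geometry = geom_i
        scans.append(
            simulate_scan(phantom, geom_i, rotation_index, flux=flux, seed=seed,
                          noiseless=noiseless, projector=projector, _stream=i + 1)
        )
    projector.geometry = geometry
    return scans


# ---------------------------------------------------------------------------
# minimal detector-frame rasterizer (testing aid for frame reduction only)

def rasterize_frame(shape, beam_center, pixel_size_um, distance_mm,
                    wavelength_nm, intensity_fn) -> np.ndarray:
    """Paint a synthetic detector frame from an intensity function I(q, psi).

    Pixel azimuth psi is measured from the +horizontal (column) axis toward
    +row; q follows the exact flat-detector geometry
    q = (4 pi / lambda) sin(arctan(r / L) / 2).
    """
    rows, cols = np.indices(shape, dtype=float)
    dr = rows - beam_center[0]
    dc = cols - beam_center[1]
    radius_mm = np.hypot(dr, dc) * pixel_size_um * 1e-3
    two_theta = np.arctan2(radius_mm, distance_mm)
    q = 4.0 * np.pi / wavelength_nm * np.sin(0.5 * two_theta)
    psi = np.arctan2(dr, dc)
    return intensity_fn(q, psi)
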