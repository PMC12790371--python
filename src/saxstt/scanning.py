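"""Per-projection scanning-SAXS analysis.

Implements the standard azimuthal-anisotropy chain: detector-frame
reduction to (segment, q) bins, transmission normalisation, the
doubled-angle cosine fit

    I(psi) = a0 + a1 * cos(2 (psi - theta0)),

HSV orientation maps (hue = orientation, saturation = degree of
orientation a1/a0, value = symmetric intensity), and the photon-statistics
similarity metrics used to compare acquisitions at different frame rates:
the normalised root-mean-square error

    E = sqrt( sum (I - R)^2 / sum R^2 )

for the mean intensity and the anisotropic amplitude, and an angular
dissimilarity sqrt(1 - s) built from doubled-angle orientation vectors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from matplotlib.colors import hsv_to_rgb

from .geometry import segment_azimuths
from .simulate import ProjectionScan


@dataclass
class OrientationMap:
    """Per-scan-point (a0, a1, theta0) from the azimuthal cosine fit."""

    a0: np.ndarray
    a1: np.ndarray  # >= 0, clipped to a0 so that a1/a0 in [0, 1]
    theta0: np.ndarray  # radians in [0, pi); NaN where undefined
    q_range: tuple
    transmission_normalized: bool = True
    valid: np.ndarray | None = None

    def __post_init__(self):
        if self.valid is None:
            self.valid = np.isfinite(self.a0)

    @property
    def degree_of_orientation(self) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            doo = np.where(self.a0 > 0, self.a1 / self.a0, 0.0)
        return doo


@dataclass
class SimilarityReport:
    """Similarity of one acquisition against a reference acquisition."""

    E_mean: float
    E_aniso: float
    E_angle: float
    reference: str
    q_range: tuple


# ---------------------------------------------------------------------------
# detector-frame reduction


def reduce_frame(counts, mask, beam_center, pixel_size_um, distance_mm,
                 wavelength_nm, q_edges, n_segments: int = 16):
    """Reduce a detector frame to per-(reduced segment, q bin) mean intensity.

    Pixels are assigned to (q, azimuth) bins by exact flat-detector
    geometry; opposing segments (i, i + n/2) are averaged weighted by their
    valid-pixel counts (inversion symmetry).  Bins without valid pixels are
    NaN with a zero pixel count rather than an error.

    Returns (means (n_reduced, n_q), pixel_counts (n_reduced, n_q)).
    """
    counts = np.asarray(counts, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    q_edges = np.asarray(q_edges, dtype=float)
    if n_segments % 2:
        raise ValueError("n_segments must be even")
    if not (0 <= beam_center[0] < counts.shape[0] and 0 <= beam_center[1] < counts.shape[1]):
        raise ValueError("beam_center must lie inside the frame")

    rows, cols = np.indices(counts.shape, dtype=float)
    dr = rows - beam_center[0]
    dc = cols - beam_center[1]
    radius_mm = np.hypot(dr, dc) * pixel_size_um * 1e-3
    q = 4.0 * np.pi / wavelength_nm * np.sin(0.5 * np.arctan2(radius_mm, distance_mm))
    psi = np.mod(np.arctan2(dr, dc), 2.0 * np.pi)

    # segment 0 centred on +horizontal: wedge edges at psi = (i +- 1/2)*width
    width = 2.0 * np.pi / n_segments
    seg = np.mod(np.floor(psi / width + 0.5).astype(int), n_segments)
    qi = np.searchsorted(q_edges, q, side="right") - 1
    ok = mask & (qi >= 0) & (qi < len(q_edges) - 1)

    n_q = len(q_edges) - 1
    sums = np.zeros((n_segments, n_q))
    npix = np.zeros((n_segments, n_q))
    np.add.at(sums, (seg[ok], qi[ok]), counts[ok])
    np.add.at(npix, (seg[ok], qi[ok]), 1.0)

    half = n_segments // 2
    pair_sums = sums[:half] + sums[half:]
    pair_npix = npix[:half] + npix[half:]
    with np.errstate(invalid="ignore", divide="ignore"):
        means = np.where(pair_npix > 0, pair_sums / pair_npix, np.nan)
    return means, pair_npix


def normalize_transmission(segments: np.ndarray, transmission: np.ndarray) -> np.ndarray:
    """Divide each scan point's intensities by its transmission."""
    transmission = np.asarray(transmission, dtype=float)
    if np.any(transmission <= 0):
        raise ValueError("transmission must be positive")
    segments = np.asarray(segments, dtype=float)
    return segments / transmission[(...,) + (None,) * (segments.ndim - transmission.ndim)]


# ---------------------------------------------------------------------------
# cosine orientation fit


def fit_orientation(intensities, azimuths=None, weights=None):
    """Weighted least-squares fit of a0 + a1 cos(2 (psi - theta0)).

    ``intensities``: (..., n_seg) with NaN marking missing segments;
    ``azimuths``: segment centre azimuths (default: 8 reduced segments);
    ``weights``: optional nonnegative weights (e.g. valid-pixel counts).

    For 8 complete, equispaced segments the fit reduces to the discrete
    Fourier coefficient at the doubled angle and is exact for any function
    in the model span.  ``a1`` is clipped to ``a0`` so the degree of
    orientation a1/a0 stays in [0, 1] for nonnegative data; ``theta0`` is
    NaN where a1 vanishes or fewer than 3 segments are available.

    Returns (a0, a1, theta0) broadcasting over leading axes.
    """
    y = np.asarray(intensities, dtype=float)
    psi = segment_azimuths(y.shape[-1]) if azimuths is None else np.asarray(azimuths)
    if weights is None:
        w = np.isfinite(y).astype(float)
    else:
        w = np.asarray(weights, dtype=float) * np.isfinite(y)
    yw = np.where(np.isfinite(y), y, 0.0)

    n_ok = np.sum(w > 0, axis=-1)
    c = np.cos(2.0 * psi)
    s = np.sin(2.0 * psi)
    # normal equations of the design [1, cos 2psi, sin 2psi]
    s00 = np.sum(w, axis=-1)
    s01 = np.sum(w * c, axis=-1)
    s02 = np.sum(w * s, axis=-1)
    s11 = np.sum(w * c * c, axis=-1)
    s12 = np.sum(w * c * s, axis=-1)
    s22 = np.sum(w * s * s, axis=-1)
    b0 = np.sum(w * yw, axis=-1)
    b1 = np.sum(w * yw * c, axis=-1)
    b2 = np.sum(w * yw * s, axis=-1)

    ata = np.stack(
        [
            np.stack([s00, s01, s02], axis=-1),
            np.stack([s01, s11, s12], axis=-1),
            np.stack([s02, s12, s22], axis=-1),
        ],
        axis=-2,
    )
    atb = np.stack([b0, b1, b2], axis=-1)
    scalar_input = atb.ndim == 1
    ata = np.atleast_3d(ata).reshape((-1, 3, 3)) if scalar_input else ata
    atb = np.atleast_2d(atb) if scalar_input else atb
    n_ok = np.atleast_1d(n_ok) if scalar_input else n_ok
    sol = np.full(atb.shape, np.nan)
    # guard nearly singular systems (e.g. all weights in 2 segments)
    ok = (n_ok >= 3) & (
        np.abs(np.linalg.det(ata))
        > 1e-12 * np.maximum(np.abs(ata).max(axis=(-2, -1)) ** 3, 1e-30)
    )
    if np.any(ok):
        sol[ok] = np.linalg.solve(ata[ok], atb[ok][..., None])[..., 0]
    if scalar_input:
        sol = sol[0]
    a0 = sol[..., 0]
    amp = np.hypot(sol[..., 1], sol[..., 2])
    theta0 = np.mod(0.5 * np.arctan2(sol[..., 2], sol[..., 1]), np.pi)
    a1 = np.minimum(amp, np.maximum(a0, 0.0))
    theta0 = np.where(amp > 1e-12 * np.maximum(np.abs(a0), 1e-300), theta0, np.nan)
    return a0, a1, theta0


def select_q_bins(q_edges: np.ndarray, q_range) -> np.ndarray:
    """Indices of bins whose centres fall in [q_lo, q_hi]."""
    centers = 0.5 * (np.asarray(q_edges)[:-1] + np.asarray(q_edges)[1:])
    lo, hi = q_range
    idx = np.flatnonzero((centers >= lo) & (centers <= hi))
    if len(idx) == 0:
        raise ValueError(f"no q bins with centres inside {q_range}")
    return idx


def build_orientation_map(scan: ProjectionScan, q_range,
                          normalize: bool = True) -> OrientationMap:
    """Cosine-fit every scan point of a projection in a q range.

    Bins whose centres fall inside [q_lo, q_hi] are averaged with equal
    weights; counts are converted to intensity units (divided by
    flux * dwell, so maps from different frame rates are comparable) and
    transmission-normalised first.
    """
    idx = select_q_bins(scan.q_edges, q_range)
    seg = scan.segments[:, :, :, idx].mean(axis=3) / (scan.flux * scan.dwell_time)
    if normalize:
        seg = normalize_transmission(seg, scan.transmission)
    a0, a1, theta0 = fit_orientation(seg)
    return OrientationMap(a0=a0, a1=a1, theta0=theta0, q_range=tuple(q_range),
                          transmission_normalized=normalize)


def render_colormap(omap: OrientationMap, value_percentile: float = 99.0) -> np.ndarray:
    """HSV-coded RGB image of an orientation map.

    hue = theta0/pi, saturation = a1/a0 (0 where the orientation is
    undefined), value = a0 clipped at the given percentile.  Deterministic
    for a fixed percentile.
    """
    hue = np.where(np.isfinite(omap.theta0), omap.theta0 / np.pi, 0.0)
    sat = np.where(np.isfinite(omap.theta0), omap.degree_of_orientation, 0.0)
    a0 = np.where(np.isfinite(omap.a0), np.maximum(omap.a0, 0.0), 0.0)
    scale = np.percentile(a0, value_percentile)
    val = np.clip(a0 / scale, 0.0, 1.0) if scale > 0 else a0 * 0.0
    return hsv_to_rgb(np.stack([hue, np.clip(sat, 0, 1), val], axis=-1))


# ---------------------------------------------------------------------------
# similarity metrics


def save_orientation_png(path, rgb: np.ndarray) -> None:
    """Write an HSV-rendered orientation map as a 16-bit RGB PNG.

    ``rgb`` is a float array in [0, 1] of shape (h, w, 3).  Encoded
    directly (PNG color type 2, bit depth 16) because common imaging
    libraries only write 8-bit RGB PNGs.
    """
    import struct
    import zlib

    arr = np.clip(np.asarray(rgb, dtype=float), 0.0, 1.0)
    data16 = (arr * 65535.0 + 0.5).astype(">u2")
    h, w = data16.shape[:2]
    raw = b"".join(b"\x00" + data16[row].tobytes() for row in range(h))

    def chunk(tag, payload):
        body = tag + payload
        return struct.pack(">I", len(payload)) + body + struct.pack(
            ">I", zlib.crc32(body) & 0xFFFFFFFF)

    with open(path, "wb") as fh:
        fh.write(b"\x89PNG\r\n\x1a\n")
        fh.write(chunk(b"IHDR", struct.pack(">IIBBBBB", w, h, 16, 2, 0, 0, 0)))
        fh.write(chunk(b"IDAT", zlib.compress(raw, 6)))
        fh.write(chunk(b"IEND", b""))


def similarity_error(image, reference) -> float:
    """Normalised RMSE, E = sqrt( sum (I-R)^2 / sum R^2 ).

    0 means the images are identical; missing points (NaN in either) are
    excluded pairwise.  An all-zero/empty reference is rejected.
    """
    i = np.asarray(image, dtype=float)
    r = np.asarray(reference, dtype=float)
    if i.shape != r.shape:
        raise ValueError("image and reference must share a shape")
    ok = np.isfinite(i) & np.isfinite(r)
    denom = np.sum(r[ok] ** 2)
    if not np.any(ok) or denom == 0:
        raise ValueError("reference has no nonzero valid points")
    return float(np.sqrt(np.sum((i[ok] - r[ok]) ** 2) / denom))


def orientation_dissimilarity(theta, theta_ref) -> float:
    """Angular dissimilarity E_angle = sqrt(1 - s) in [0, 1].

    Orientations are half-turn quantities, so each angle is encoded as a
    doubled-angle unit vector v = (cos 2 theta, sin 2 theta) and the
    per-point similarity (1 + v . v_ref)/2 is averaged over the common
    support: identical maps give 0, everywhere-perpendicular maps give 1.
    """
    t = np.asarray(theta, dtype=float)
    r = np.asarray(theta_ref, dtype=float)
    if t.shape != r.shape:
        raise ValueError("maps must share a shape")
    ok = np.isfinite(t) & np.isfinite(r)
    if not np.any(ok):
        raise ValueError("no common support between the orientation maps")
    dot = np.cos(2.0 * t[ok]) * np.cos(2.0 * r[ok]) + np.sin(2.0 * t[ok]) * np.sin(2.0 * r[ok])
    s = float(np.mean(0.5 * (1.0 + dot)))
    return float(np.sqrt(max(0.0, 1.0 - s)))


def compare_maps(omap: OrientationMap, ref: OrientationMap,
                 reference_id: str = "reference") -> SimilarityReport:
    """The three similarity metrics of a map against a reference map."""
    return SimilarityReport(
        E_mean=similarity_error(omap.a0, ref.a0),
        E_aniso=similarity_error(omap.a1, ref.a1),
        E_angle=orientation_dissimilarity(omap.theta0, ref.theta0),
        reference=reference_id,
        q_range=omap.q_range,
    )


def framerate_study(series: list[ProjectionScan], q_ranges,
                    rates_hz=None) -> pd.DataFrame:
    """Similarity of each acquisition rate against the slowest rate.

    ``series`` must be ordered by rate with the slowest (reference) first.
    Returns a tidy table with one row per (rate, q_range).
    """
    if rates_hz is None:
        rates_hz = [1.0 / s.dwell_time for s in series]
    rows = []
    for q_range in q_ranges:
        ref = build_orientation_map(series[0], q_range)
        for scan, rate in zip(series, rates_hz):
            omap = build_orientation_map(scan, q_range)
            rep = compare_maps(omap, ref, reference_id=f"{rates_hz[0]:g} Hz")
            rows.append(
                {"rate_hz": rate, "q_lo": q_range[0], "q_hi": q_range[1],
                 "E_mean": rep.E_mean, "E_aniso": rep.E_aniso,
                 "E_angle": rep.E_angle}
            )
    return pd.DataFrame(rows)
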