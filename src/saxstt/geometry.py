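"""Acquisition geometry: goniometer rotations, scan grid, detector segments.

Conventions (fixed for the whole package so that simulation and
reconstruction share one forward model):

* The sample frame is right-handed; the beam travels along lab +x.
* Tomographic rotation phi is about the lab vertical axis z; the tilt chi is
  about the horizontal axis y (perpendicular to the beam).  A sample-frame
  point p maps to the lab as R p with R = R_chi(y) @ R_phi(z).
* Small-angle approximation: the reciprocal-space direction probed by a
  detector azimuth psi is exactly perpendicular to the beam,
  u_lab(psi) = (0, cos psi, sin psi).
* The detector is divided into 16 azimuthal segments of 22.5 deg, segment 0
  centred on the +horizontal detector axis; opposing segments (i, i+8) are
  averaged assuming inversion symmetry, leaving 8 reduced segments with
  centre azimuths psi_k = k * 22.5 deg.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

N_SEGMENTS_FULL = 16


def rotation_matrix(phi_deg: float, chi_deg: float) -> np.ndarray:
    """Sample-to-lab rotation R = R_chi(y) @ R_phi(z)."""
    p = np.deg2rad(phi_deg)
    c = np.deg2rad(chi_deg)
    r_phi = np.array(
        [[np.cos(p), -np.sin(p), 0.0], [np.sin(p), np.cos(p), 0.0], [0.0, 0.0, 1.0]]
    )
    r_chi = np.array(
        [[np.cos(c), 0.0, np.sin(c)], [0.0, 1.0, 0.0], [-np.sin(c), 0.0, np.cos(c)]]
    )
    return r_chi @ r_phi


def segment_azimuths(n_reduced: int = 8) -> np.ndarray:
    """Centre azimuths (radians) of the reduced segments."""
    return np.arange(n_reduced) * np.pi / n_reduced


def probing_directions(phi_deg: float, chi_deg: float, n_reduced: int = 8) -> np.ndarray:
    """Sample-frame unit vectors probed by each reduced segment, shape (n, 3).

    u_lab(psi) = (0, cos psi, sin psi) pulled back by R^T into the sample
    frame.  Because f is even, psi and psi+pi probe the same value, which is
    exactly the inversion symmetry exploited by the 16 -> 8 reduction.
    """
    psi = segment_azimuths(n_reduced)
    u_lab = np.stack([np.zeros_like(psi), np.cos(psi), np.sin(psi)], axis=-1)
    r = rotation_matrix(phi_deg, chi_deg)
    return u_lab @ r  # (R^T u)_i = u_j R_ji  ==  u @ R


@dataclass
class AcquisitionGeometry:
    """Scan and rotation protocol of a tensor-tomography measurement.

    Parameters
    ----------
    rotations : (n, 2) array
        (phi, chi) pairs in degrees; phi in [0, 360), chi in [0, 45].
    n_fast, n_slow : int
        Raster grid size; fast axis is the lab y (horizontal) direction,
        slow axis the lab z (vertical) direction.
    step : float
        Scan step in micrometres; equals the voxel size of the phantom.
    q_edges : array
        Strictly increasing radial bin edges in 1/nm.
    n_segments : int
        Full azimuthal segment count before inversion-symmetry reduction.
    dwell_time : float
        Exposure per point in seconds (reciprocal of the frame rate).
    """

    rotations: np.ndarray
    n_fast: int
    n_slow: int
    step: float
    q_edges: np.ndarray = field(default_factory=lambda: np.array([0.5, 0.6]))
    n_segments: int = N_SEGMENTS_FULL
    dwell_time: float = 0.012

    def __post_init__(self):
        self.rotations = np.atleast_2d(np.asarray(self.rotations, dtype=float))
        self.q_edges = np.asarray(self.q_edges, dtype=float)
        if self.rotations.shape[1] != 2:
            raise ValueError("rotations must be (n, 2) array of (phi, chi) degrees")
        chi = self.rotations[:, 1]
        if np.any(chi < 0) or np.any(chi > 45):
            raise ValueError("tilt chi must lie in [0, 45] degrees")
        if self.q_edges.ndim != 1 or len(self.q_edges) < 2:
            raise ValueError("q_edges must hold at least two edges")
        if np.any(np.diff(self.q_edges) <= 0) or self.q_edges[0] <= 0:
            raise ValueError("q_edges must be positive and strictly increasing")
        if self.n_segments % 2 != 0:
            raise ValueError("n_segments must be even (inversion symmetry)")
        if self.dwell_time <= 0:
            raise ValueError("dwell_time must be positive")

    @property
    def n_rotations(self) -> int:
        return len(self.rotations)

    @property
    def n_reduced_segments(self) -> int:
        return self.n_segments // 2

    @property
    def q_centers(self) -> np.ndarray:
        return 0.5 * (self.q_edges[:-1] + self.q_edges[1:])

    @property
    def n_q(self) -> int:
        return len(self.q_edges) - 1

    def scan_offsets(self):
        """Lab-frame (fast, slow) ray offsets in micrometres, centred on the
        rotation axis.  Returns (fast (n_fast,), slow (n_slow,))."""
        fast = (np.arange(self.n_fast) - (self.n_fast - 1) / 2.0) * self.step
        slow = (np.arange(self.n_slow) - (self.n_slow - 1) / 2.0) * self.step
        return fast, slow

    def untilted_indices(self, tol: float = 1e-9) -> np.ndarray:
        """Indices of chi = 0 rotations (the subset scalar FBP can use)."""
        return np.flatnonzero(np.abs(self.rotations[:, 1]) <= tol)


def tomo_rotations(n_phi: int, tilts_deg) -> np.ndarray:
    """Standard protocol: for each tilt chi, n_phi equally spaced phi in
    [0, 360).  Mirrors a multi-sub-tomogram acquisition at tilts 0..45 deg."""
    tilts = np.atleast_1d(np.asarray(tilts_deg, dtype=float))
    phis = np.arange(n_phi) * 360.0 / n_phi
    out = [(p, c) for c in tilts for p in phis]
    return np.array(out)


def geometry_for_phantom(phantom, rotations, q_edges=(0.5, 0.6), dwell_time=0.012,
                         margin: float = 1.55) -> AcquisitionGeometry:
    """Build a scan grid wide enough to cover the phantom at every rotation.

    With chi <= 45 deg the projected extent of an n-voxel cube is at most
    n*(cos chi + sin chi) <= n*sqrt(2) in either direction; the default
    margin adds a safety row.
    """
    n = int(np.ceil(max(phantom.shape) * margin)) + 1
    if (n - max(phantom.shape)) % 2:
        n += 1  # keep scan grid and voxel grid concentric without half-pixel offsets
    return AcquisitionGeometry(
        rotations=np.asarray(rotations, dtype=float),
        n_fast=n,
        n_slow=n,
        step=phantom.voxel_size,
        q_edges=np.asarray(q_edges, dtype=float),
        dwell_time=dwell_time,
    )
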