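"""Siddon-style ray tracing and the linear projection operator.

For each rotation the raster scan defines a bundle of parallel rays (one per
scan point) traversing the voxel grid.  `trace_rays` computes the exact
intersection length of every ray with every voxel it crosses (Siddon's
method, vectorised over the whole bundle) and returns a sparse matrix
W (n_rays, n_voxels) of path lengths in micrometres.

The same W serves the forward simulation, the absorption line integrals, and
the tensor-reconstruction forward/adjoint operator, which guarantees that
simulation and reconstruction share one discretisation.
"""

from __future__ import annotations

import numpy as np
from scipy import sparse

from .geometry import AcquisitionGeometry, probing_directions, rotation_matrix
from .harmonics import sh_basis

_EPS = 1e-12


def trace_rays(origins: np.ndarray, direction: np.ndarray, shape, voxel_size: float):
    """Exact path lengths of parallel rays through a voxel grid.

    Parameters
    ----------
    origins : (n_rays, 3) sample-frame points on each ray (micrometres,
        relative to the grid centre).
    direction : (3,) unit vector shared by all rays.
    shape : (nx, ny, nz) voxel grid dimensions.
    voxel_size : voxel edge length in micrometres.

    Returns
    -------
    scipy.sparse.csr_matrix of shape (n_rays, nx*ny*nz), entries in um.
    """
    origins = np.asarray(origins, dtype=float)
    d = np.asarray(direction, dtype=float)
    n_rays = len(origins)
    shape = tuple(int(s) for s in shape)
    lo = -0.5 * voxel_size * np.asarray(shape, dtype=float)

    # candidate parameters where any ray crosses any axis-aligned voxel plane
    t_list = []
    for ax in range(3):
        if abs(d[ax]) < _EPS:
            continue
        planes = lo[ax] + voxel_size * np.arange(shape[ax] + 1)
        t_list.append((planes[None, :] - origins[:, ax : ax + 1]) / d[ax])
    if not t_list:
        return sparse.csr_matrix((n_rays, int(np.prod(shape))))
    t = np.sort(np.concatenate(t_list, axis=1), axis=1)  # (n_rays, K)

    dt = np.diff(t, axis=1)
    t_mid = 0.5 * (t[:, 1:] + t[:, :-1])
    # voxel index of each candidate segment's midpoint
    pts = origins[:, None, :] + t_mid[:, :, None] * d[None, None, :]
    idx = np.floor((pts - lo[None, None, :]) / voxel_size).astype(np.int64)
    inside = (
        (dt > _EPS)
        & (idx[..., 0] >= 0) & (idx[..., 0] < shape[0])
        & (idx[..., 1] >= 0) & (idx[..., 1] < shape[1])
        & (idx[..., 2] >= 0) & (idx[..., 2] < shape[2])
    )
    flat = (idx[..., 0] * shape[1] + idx[..., 1]) * shape[2] + idx[..., 2]
    rows = np.broadcast_to(np.arange(n_rays)[:, None], dt.shape)[inside]
    cols = flat[inside]
    data = dt[inside]
    w = sparse.coo_matrix((data, (rows, cols)), shape=(n_rays, int(np.prod(shape))))
    return w.tocsr()


class Projector:
    """Cached per-rotation projection weights and probing-direction bases.

    Ray ordering is row-major over (slow, fast), i.e. ray r = i_slow*n_fast
    + i_fast, matching the (n_slow, n_fast, ...) layout of projection data.
    """

    def __init__(self, shape, voxel_size: float, geometry: AcquisitionGeometry):
        self.shape = tuple(int(s) for s in shape)
        self.voxel_size = float(voxel_size)
        self.geometry = geometry
        self._weights: dict[int, sparse.csr_matrix] = {}

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.shape))

    @property
    def n_rays(self) -> int:
        return self.geometry.n_fast * self.geometry.n_slow

    def ray_bundle(self, k: int):
        """Sample-frame (origins, direction) of the ray bundle of rotation k."""
        phi, chi = self.geometry.rotations[k]
        r = rotation_matrix(phi, chi)
        fast, slow = self.geometry.scan_offsets()
        # lab offsets u*yhat + v*zhat; origins pulled back into sample frame
        lab = np.zeros((self.geometry.n_slow, self.geometry.n_fast, 3))
        lab[..., 1] = fast[None, :]
        lab[..., 2] = slow[:, None]
        origins = lab.reshape(-1, 3) @ r  # R^T applied row-wise
        direction = r.T @ np.array([1.0, 0.0, 0.0])
        return origins, direction

    def weights(self, k: int) -> sparse.csr_matrix:
        if k not in self._weights:
            origins, direction = self.ray_bundle(k)
            self._weights[k] = trace_rays(origins, direction, self.shape, self.voxel_size)
        return self._weights[k]

    def sh_matrix(self, k: int) -> np.ndarray:
        """(n_reduced_segments, 6) harmonic basis at the probing directions."""
        phi, chi = self.geometry.rotations[k]
        dirs = probing_directions(phi, chi, self.geometry.n_reduced_segments)
        return sh_basis(dirs)
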