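"""Real spherical harmonics of degrees 0 and 2 and closed-form readouts.

The per-voxel reciprocal-space map is modelled as an even, band-limited
function on the unit sphere,

    f(u) = c00*Y00 + sum_m c2m*Y2m(u),

expanded in *orthonormal* real spherical harmonics.  Six coefficients fully
describe the function; the degree-0 term carries the spherical mean (the
isotropic scattering strength) and the five degree-2 terms carry the lowest
even anisotropy.  Everything the downstream analysis needs — the spherical
mean, the standard deviation over the sphere, and the second angular moment
tensor M = ∫ f(u) u u^T dΩ — has a closed form in these coefficients.

Coefficient ordering throughout the package:
    [ (0,0), (2,-2), (2,-1), (2,0), (2,1), (2,2) ]
"""

from __future__ import annotations

import numpy as np

N_COEFFS = 6

_Y00 = 0.5 / np.sqrt(np.pi)
_K2 = 0.5 * np.sqrt(15.0 / np.pi)   # prefactor of xy, yz, xz harmonics
_K20 = 0.25 * np.sqrt(5.0 / np.pi)  # prefactor of (3z^2 - 1)
_K22 = 0.25 * np.sqrt(15.0 / np.pi)  # prefactor of (x^2 - y^2)


def sh_basis(directions: np.ndarray) -> np.ndarray:
    """Evaluate the six real harmonics at unit vectors.

    Parameters
    ----------
    directions : array, shape (..., 3)
        Unit vectors on the sphere.

    Returns
    -------
    array, shape (..., 6)
    """
    d = np.asarray(directions, dtype=float)
    x, y, z = d[..., 0], d[..., 1], d[..., 2]
    out = np.empty(d.shape[:-1] + (N_COEFFS,), dtype=float)
    out[..., 0] = _Y00
    out[..., 1] = _K2 * x * y
    out[..., 2] = _K2 * y * z
    out[..., 3] = _K20 * (3.0 * z * z - 1.0)
    out[..., 4] = _K2 * x * z
    out[..., 5] = _K22 * (x * x - y * y)
    return out


def evaluate(coeffs: np.ndarray, directions: np.ndarray) -> np.ndarray:
    """Evaluate f(u) for coefficient vectors; broadcasts over leading axes."""
    return np.asarray(coeffs) @ np.moveaxis(sh_basis(directions), -1, 0)


def uniaxial_coeffs(axis, anisotropy, mean_density) -> np.ndarray:
    """Coefficients of the uniaxial kernel used by the phantom forward model.

        f(u) = m * [1 + kappa*(1 - (u.a)^2) - 2*kappa/3]

    i.e. intensity concentrated on the plane perpendicular to the fibril
    axis ``a``, with spherical mean exactly ``m`` (the spherical mean of
    (u.a)^2 is 1/3).  The function is an even polynomial of degree 2 in u,
    hence exactly band-limited to degrees {0, 2}.

    ``axis`` may be (..., 3); ``anisotropy`` and ``mean_density`` broadcast.
    Where anisotropy is 0 the axis is irrelevant (may be NaN).
    """
    a = np.asarray(axis, dtype=float)
    kappa = np.asarray(anisotropy, dtype=float)
    m = np.asarray(mean_density, dtype=float)
    if np.any(kappa < 0) or np.any(kappa >= 1):
        raise ValueError("anisotropy must lie in [0, 1)")

    safe_axis = np.where(np.isfinite(a), a, 0.0)
    # -(u.a)^2 has spherical mean -1/3; its degree-2 part is
    # -(2/3) P2(u.a) = -(2/3) (4pi/5) sum_m Y2m(u) Y2m(a)  (addition theorem).
    y_axis = sh_basis(safe_axis)  # (..., 6)
    coeffs = np.zeros(np.broadcast_shapes(kappa.shape, m.shape, a.shape[:-1]) + (N_COEFFS,))
    coeffs[..., 0] = m * 2.0 * np.sqrt(np.pi)
    amp = -(m * kappa) * (2.0 / 3.0) * (4.0 * np.pi / 5.0)
    coeffs[..., 1:] = amp[..., None] * y_axis[..., 1:]
    return coeffs


def spherical_mean(coeffs: np.ndarray) -> np.ndarray:
    """Mean of f over the sphere; proportional to the degree-0 coefficient."""
    return np.asarray(coeffs)[..., 0] * _Y00


def spherical_std(coeffs: np.ndarray) -> np.ndarray:
    """Standard deviation of f over the sphere (Parseval on degree 2)."""
    c2 = np.asarray(coeffs)[..., 1:]
    return np.sqrt(np.sum(c2 * c2, axis=-1)) / (2.0 * np.sqrt(np.pi))


def degree_of_orientation(coeffs: np.ndarray) -> np.ndarray:
    """DoO = std(f)/mean(f) = sqrt(sum c2m^2)/c00; NaN where the mean is <= 0."""
    c = np.asarray(coeffs, dtype=float)
    c00 = c[..., 0]
    with np.errstate(divide="ignore", invalid="ignore"):
        doo = np.sqrt(np.sum(c[..., 1:] ** 2, axis=-1)) / c00
    return np.where(c00 > 0, doo, np.nan)


def second_moment(coeffs: np.ndarray) -> np.ndarray:
    """Rank-2 tensor M = ∫ f(u) u u^T dΩ in closed form.

    Uses ∫ f dΩ = 2 sqrt(pi) c00 together with the expansion of the
    quadratic monomials in the real degree-2 harmonics:
    xy = 2 sqrt(pi/15) Y2,-2, yz = 2 sqrt(pi/15) Y2,-1,
    xz = 2 sqrt(pi/15) Y2,1, x^2-y^2 = 4 sqrt(pi/15) Y2,2,
    z^2 = 1/3 + (4/3) sqrt(pi/5) Y2,0.

    Returns array of shape (..., 3, 3).
    """
    c = np.asarray(coeffs, dtype=float)
    i0 = 2.0 * np.sqrt(np.pi) * c[..., 0]
    koff = 2.0 * np.sqrt(np.pi / 15.0)
    m_xy = koff * c[..., 1]
    m_yz = koff * c[..., 2]
    m_xz = koff * c[..., 4]
    m_zz = i0 / 3.0 + (4.0 / 3.0) * np.sqrt(np.pi / 5.0) * c[..., 3]
    half_rest = 0.5 * (i0 - m_zz)
    dev22 = 2.0 * np.sqrt(np.pi / 15.0) * c[..., 5]
    m_xx = half_rest + dev22
    m_yy = half_rest - dev22
    out = np.empty(c.shape[:-1] + (3, 3), dtype=float)
    out[..., 0, 0] = m_xx
    out[..., 1, 1] = m_yy
    out[..., 2, 2] = m_zz
    out[..., 0, 1] = out[..., 1, 0] = m_xy
    out[..., 0, 2] = out[..., 2, 0] = m_xz
    out[..., 1, 2] = out[..., 2, 1] = m_yz
    return out


def sphere_quadrature(n_theta: int = 50, n_phi: int = 200):
    """Product quadrature on the sphere: Gauss–Legendre in cos(theta) times
    a uniform trapezoid in phi.  Exact for spherical polynomials up to high
    degree; used as the independent oracle for the closed forms above.

    Returns (points (N, 3), weights (N,)) with weights summing to 4*pi.
    """
    mu, w_mu = np.polynomial.legendre.leggauss(n_theta)
    phi = 2.0 * np.pi * (np.arange(n_phi) + 0.5) / n_phi
    w_phi = 2.0 * np.pi / n_phi
    sin_t = np.sqrt(1.0 - mu**2)
    x = sin_t[:, None] * np.cos(phi)[None, :]
    y = sin_t[:, None] * np.sin(phi)[None, :]
    z = np.broadcast_to(mu[:, None], x.shape)
    pts = np.stack([x, y, z], axis=-1).reshape(-1, 3)
    wts = (w_mu[:, None] * w_phi * np.ones(n_phi)[None, :]).reshape(-1)
    return pts, wts
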