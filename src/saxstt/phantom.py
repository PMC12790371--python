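"""Synthetic phantoms with known orientation fields and mineral populations.

A `Phantom` holds, per voxel, everything the forward model needs:

* ``attenuation`` (1/um) for Beer-Lambert transmission,
* ``fibril_axis`` (unit vector, NaN where undefined) and ``anisotropy``
  (kappa in [0, 1)) for the angular part of the reciprocal-space map,
* ``mean_density`` for the overall scattering strength,
* a mineral-phase label selecting a 1D radial intensity model
  (`MineralSpec`) with known power-law exponent / Porod behaviour.

The angular kernel is band-limited to spherical-harmonic degrees {0, 2}
(`saxstt.harmonics.uniaxial_coeffs`), so a degree-2 tensor reconstruction
can in principle recover it exactly; higher harmonic content is deliberately
not generated.

Recipes are named and deterministic for a fixed seed; overlapping regions
are resolved last-writer-wins, in recipe order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .harmonics import N_COEFFS, uniaxial_coeffs

# ---------------------------------------------------------------------------
# radial (1D) intensity models


@dataclass(frozen=True)
class MineralSpec:
    """Parametric 1D scattering model of one mineral population.

    kind:
      * ``powerlaw_porod`` — I(q) = A q^-G + P q^-4 + b
      * ``dilute_spheres`` — scale * FF_sphere(qR)^2 + b (orientation
        average of a sphere of radius R, dilute limit)
      * ``dilute_plates`` — scale * sinc^2(q d / 2) / q^2 + b (orientation
        average of a thin plate of thickness d, dilute limit)
    """

    kind: str
    params: tuple = ()

    def as_dict(self) -> dict:
        return {"kind": self.kind, "params": list(self.params)}


def _sphere_ff2(x: np.ndarray) -> np.ndarray:
    """Squared sphere form factor [3 (sin x - x cos x)/x^3]^2, FF(0) = 1."""
    x = np.asarray(x, dtype=float)
    out = np.ones_like(x)
    nz = x > 1e-4
    xs = x[nz]
    out[nz] = (3.0 * (np.sin(xs) - xs * np.cos(xs)) / xs**3) ** 2
    return out


def simulate_radial_curve(spec: MineralSpec, q: np.ndarray) -> np.ndarray:
    """Evaluate the 1D model intensity on radial bins q (1/nm).

    All models are nonnegative by construction; parameter sets that would
    produce negative intensity are rejected.
    """
    q = np.asarray(q, dtype=float)
    if np.any(q <= 0):
        raise ValueError("q must be positive")
    if spec.kind == "powerlaw_porod":
        a, g, p, b = spec.params
        if a < 0 or p < 0 or b < 0:
            raise ValueError("powerlaw_porod parameters must be nonnegative")
        return a * q ** (-g) + p * q ** (-4.0) + b
    if spec.kind == "dilute_spheres":
        r, scale, b = spec.params[:3]
        sigma_rel = spec.params[3] if len(spec.params) > 3 else 0.0
        if r <= 0 or scale < 0 or b < 0 or sigma_rel < 0:
            raise ValueError("dilute_spheres needs R > 0 and nonnegative scale/b")
        if sigma_rel == 0:
            return scale * _sphere_ff2(q * r) + b
        # polydisperse population: Gauss-Hermite average of V^2-weighted
        # form factors over a Gaussian size distribution (truncated > 0)
        nodes, wts = np.polynomial.hermite_e.hermegauss(11)
        radii = np.maximum(r * (1.0 + sigma_rel * nodes), 0.05 * r)
        v2 = radii**6
        acc = np.zeros_like(q)
        for rad, w, vol2 in zip(radii, wts, v2):
            acc += w * vol2 * _sphere_ff2(q * rad)
        return scale * acc / np.sum(wts * v2) + b
    if spec.kind == "dilute_plates":
        d, scale, b = spec.params
        if d <= 0 or scale < 0 or b < 0:
            raise ValueError("dilute_plates needs d > 0 and nonnegative scale/b")
        x = 0.5 * q * d
        return scale * np.sinc(x / np.pi) ** 2 / q**2 + b
    raise ValueError(f"unknown mineral model kind: {spec.kind!r}")


def voxel_reciprocal_map(axis, anisotropy: float, mean_density: float):
    """Return the spherical-function evaluator of a single voxel.

    f(u) = m * [1 + kappa (1 - (u . axis)^2) - 2 kappa / 3]

    Even, nonnegative for kappa in [0, 1), band-limited to degrees {0, 2},
    with spherical mean exactly ``mean_density``.  Intensity is maximal on
    the equator perpendicular to ``axis`` — the fibril scattering geometry.
    """
    kappa = float(anisotropy)
    m = float(mean_density)
    if not 0.0 <= kappa < 1.0:
        raise ValueError("anisotropy must lie in [0, 1)")
    if kappa > 0:
        a = np.asarray(axis, dtype=float)
        if abs(np.linalg.norm(a) - 1.0) > 1e-8:
            raise ValueError("axis must be unit-norm when anisotropy > 0")
    else:
        a = np.array([0.0, 0.0, 1.0])

    def f(u):
        u = np.asarray(u, dtype=float)
        proj = u @ a
        return m * (1.0 + kappa * (1.0 - proj**2) - 2.0 * kappa / 3.0)

    return f


# ---------------------------------------------------------------------------
# phantom container


@dataclass
class Phantom:
    voxel_size: float
    attenuation: np.ndarray
    fibril_axis: np.ndarray  # (nx, ny, nz, 3), NaN where undefined
    anisotropy: np.ndarray
    mean_density: np.ndarray
    mineral_label: np.ndarray  # int, -1 where no mineral model attached
    mineral_phases: list = field(default_factory=list)
    labels: np.ndarray | None = None  # region id per voxel
    ground_truth: dict = field(default_factory=dict)
    name: str = "phantom"
    seed: int | None = None

    def __post_init__(self):
        if np.any(self.attenuation < 0):
            raise ValueError("attenuation must be nonnegative")
        if np.any(self.mean_density < 0):
            raise ValueError("mean_density must be nonnegative")
        if np.any((self.anisotropy < 0) | (self.anisotropy >= 1)):
            raise ValueError("anisotropy must lie in [0, 1)")
        defined = self.anisotropy > 0
        norms = np.linalg.norm(self.fibril_axis, axis=-1)
        if defined.any() and not np.allclose(norms[defined], 1.0, atol=1e-6):
            raise ValueError("fibril_axis must be unit-norm where anisotropy > 0")

    @property
    def shape(self):
        return self.attenuation.shape

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.shape))

    def sh_coeffs(self) -> np.ndarray:
        """(n_voxels, 6) harmonic coefficients of the angular kernel,
        scaled by mean_density (spherical mean of voxel v = mean_density[v])."""
        c = uniaxial_coeffs(self.fibril_axis, self.anisotropy, self.mean_density)
        return c.reshape(-1, N_COEFFS)

    def radial_factors(self, q: np.ndarray) -> np.ndarray:
        """(n_voxels, n_q) radial intensity factor per voxel; voxels without
        a mineral model scatter with a flat (q-independent) factor 1."""
        q = np.atleast_1d(np.asarray(q, dtype=float))
        out = np.ones((self.n_voxels, len(q)))
        lab = self.mineral_label.reshape(-1)
        for i, spec in enumerate(self.mineral_phases):
            sel = lab == i
            if sel.any():
                out[sel] = simulate_radial_curve(spec, q)[None, :]
        return out

    def expected_mean_intensity(self, q) -> np.ndarray:
        """Ground-truth spherical-mean intensity per voxel at q, averaged
        over the supplied bins; shape = phantom shape."""
        fac = self.radial_factors(q).mean(axis=1).reshape(self.shape)
        return self.mean_density * fac


# ---------------------------------------------------------------------------
# region machinery

def _coords(shape, voxel_size):
    """Voxel-centre coordinates in um, origin at the grid centre."""
    idx = np.indices(shape, dtype=float)
    return [
        (idx[i] - (shape[i] - 1) / 2.0) * voxel_size for i in range(3)
    ]


def region_mask(region: dict, shape, voxel_size: float) -> np.ndarray:
    """Boolean membership mask of one region.  Geometric primitives are
    defined in voxel units relative to the grid centre (fractions of the
    grid size via 'r_frac' style parameters)."""
    x, y, z = _coords(shape, voxel_size)
    n = max(shape) * voxel_size
    kind = region["type"]
    if kind == "all":
        return np.ones(shape, dtype=bool)
    if kind == "cylinder_z":
        cx = region.get("cx", 0.0) * n
        cy = region.get("cy", 0.0) * n
        r = region["r_frac"] * n
        return (x - cx) ** 2 + (y - cy) ** 2 <= r**2
    if kind == "annulus_z":
        cx = region.get("cx", 0.0) * n
        cy = region.get("cy", 0.0) * n
        r_in = region["r_in_frac"] * n
        r_out = region["r_out_frac"] * n
        rho2 = (x - cx) ** 2 + (y - cy) ** 2
        return (rho2 >= r_in**2) & (rho2 <= r_out**2)
    if kind == "sphere":
        c = np.asarray(region.get("center", (0.0, 0.0, 0.0))) * n
        r = region["r_frac"] * n
        return (x - c[0]) ** 2 + (y - c[1]) ** 2 + (z - c[2]) ** 2 <= r**2
    if kind == "box":
        half = np.asarray(region["half_frac"]) * n
        c = np.asarray(region.get("center", (0.0, 0.0, 0.0))) * n
        return (
            (np.abs(x - c[0]) <= half[0])
            & (np.abs(y - c[1]) <= half[1])
            & (np.abs(z - c[2]) <= half[2])
        )
    if kind == "voxel":
        m = np.zeros(shape, dtype=bool)
        i, j, k = region.get("index", (shape[0] // 2, shape[1] // 2, shape[2] // 2))
        m[i, j, k] = True
        return m
    raise ValueError(f"unknown region type: {kind!r}")


_MINERAL_LIBRARY = {
    # window-analysis classes of the three-phase demo; amplitudes chosen so
    # simulated count rates are comparable between phases
    "compact": MineralSpec("powerlaw_porod", (5.0e-4, 2.5, 0.0, 0.01)),     # G > 2
    "coarse": MineralSpec("dilute_spheres", (4.0, 5.0, 0.01, 0.15)),        # large T
    "fine": MineralSpec("dilute_spheres", (1.2, 1.5, 0.01, 0.15)),          # small T
    "flat": MineralSpec("powerlaw_porod", (0.0, 0.0, 0.0, 1.0)),        # constant
}


def _build(shape, voxel_size, regions, name, seed, mineral_names):
    shape = tuple(int(s) for s in shape)
    att = np.zeros(shape)
    axis = np.full(shape + (3,), np.nan)
    kappa = np.zeros(shape)
    dens = np.zeros(shape)
    mlab = np.full(shape, -1, dtype=np.int64)
    labels = np.full(shape, -1, dtype=np.int64)
    phases = [_MINERAL_LIBRARY[m] for m in mineral_names]
    for rid, region in enumerate(regions):
        m = region_mask(region, shape, voxel_size)
        labels[m] = rid
        att[m] = region.get("attenuation", 0.0)
        dens[m] = region.get("density", 0.0)
        k = region.get("anisotropy", 0.0)
        kappa[m] = k
        if k > 0:
            a = np.asarray(region["axis"], dtype=float)
            a = a / np.linalg.norm(a)
            axis[m] = a
        else:
            axis[m] = np.nan
        if region.get("mineral") is not None:
            mlab[m] = mineral_names.index(region["mineral"])
        else:
            mlab[m] = -1
    gt = {
        "region_label": labels.copy(),
        "mineral_class": mlab.copy(),
        "fibril_axis": axis.copy(),
        "anisotropy": kappa.copy(),
        "mean_density": dens.copy(),
        "body_mask": dens > 0,
    }
    return Phantom(
        voxel_size=float(voxel_size),
        attenuation=att,
        fibril_axis=axis,
        anisotropy=kappa,
        mean_density=dens,
        mineral_label=mlab,
        mineral_phases=phases,
        labels=labels,
        ground_truth=gt,
        name=name,
        seed=seed,
    )


def three_paths_regions() -> list[dict]:
    """Region list of the `three_paths` recipe: a cylindrical body with a
    low-attenuation central channel, one oriented bundle wrapping the
    channel and two outer oriented bundles, plus an annular outer layer.
    Mineral classes: channel-adjacent bundle 'compact' (G > 2), bulk/outer
    bundles 'coarse' (large T), outer annulus 'fine' (small T)."""
    return [
        {"type": "cylinder_z", "r_frac": 0.44, "attenuation": 1.0e-3,
         "density": 1.0, "anisotropy": 0.0, "mineral": "coarse"},
        {"type": "annulus_z", "r_in_frac": 0.36, "r_out_frac": 0.44,
         "attenuation": 1.1e-3, "density": 1.0, "anisotropy": 0.3,
         "axis": (0, 0, 1), "mineral": "fine"},
        {"type": "cylinder_z", "cx": 0.24, "cy": 0.0, "r_frac": 0.09,
         "attenuation": 1.0e-3, "density": 1.2, "anisotropy": 0.8,
         "axis": (0, 0, 1), "mineral": "coarse"},
        {"type": "cylinder_z", "cx": -0.24, "cy": 0.0, "r_frac": 0.09,
         "attenuation": 1.0e-3, "density": 1.2, "anisotropy": 0.8,
         "axis": (0, 0, 1), "mineral": "coarse"},
        {"type": "annulus_z", "r_in_frac": 0.06, "r_out_frac": 0.17,
         "attenuation": 1.0e-3, "density": 1.2, "anisotropy": 0.8,
         "axis": (0, 0, 1), "mineral": "compact"},
        {"type": "cylinder_z", "r_frac": 0.06, "attenuation": 2.0e-4,
         "density": 0.15, "anisotropy": 0.0, "mineral": "compact"},
    ]


_RECIPES = {}


def _recipe(fn):
    _RECIPES[fn.__name__] = fn
    return fn


@_recipe
def uniform_isotropic(shape):
    regions = [{"type": "all", "attenuation": 5.0e-4, "density": 1.0,
                "anisotropy": 0.0, "mineral": "flat"}]
    return regions, ["flat"]


@_recipe
def single_rod(shape):
    regions = [{"type": "cylinder_z", "r_frac": 0.28, "attenuation": 1.0e-3,
                "density": 1.0, "anisotropy": 0.8, "axis": (0, 0, 1),
                "mineral": "flat"}]
    return regions, ["flat"]


@_recipe
def three_paths(shape):
    return three_paths_regions(), ["compact", "coarse", "fine", "flat"]


@_recipe
def cylinder(shape):
    regions = [{"type": "cylinder_z", "r_frac": 0.35, "attenuation": 1.0e-3,
                "density": 1.0, "anisotropy": 0.0, "mineral": "flat"}]
    return regions, ["flat"]


@_recipe
def point(shape):
    regions = [{"type": "voxel", "index": (shape[0] // 2 + shape[0] // 5,
                                           shape[1] // 2, shape[2] // 2),
                "attenuation": 1.0e-2, "density": 1.0, "anisotropy": 0.0,
                "mineral": "flat"}]
    return regions, ["flat"]


def make_phantom(config, seed: int = 0) -> Phantom:
    """Build a phantom from a recipe name or config dict.

    ``config`` may be a recipe name (str) or a dict with keys ``recipe``,
    ``shape`` (default (32, 32, 32); test recipes are capped at 64^3),
    ``voxel_size`` (um, default 20), and optionally an explicit ``regions``
    list plus ``minerals`` names overriding the named recipe.
    Deterministic for a fixed (config, seed).
    """
    if isinstance(config, str):
        config = {"recipe": config}
    name = config.get("recipe", "custom")
    shape = tuple(config.get("shape", (32, 32, 32)))
    if max(shape) > 64:
        raise ValueError("test recipes are limited to 64^3 voxels")
    voxel_size = float(config.get("voxel_size", 20.0))
    if "regions" in config:
        regions = config["regions"]
        minerals = config.get("minerals", list(_MINERAL_LIBRARY))
    else:
        if name not in _RECIPES:
            raise ValueError(f"unknown recipe: {name!r}")
        regions, minerals = _RECIPES[name](shape)
    return _build(shape, voxel_size, regions, name, seed, minerals)
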