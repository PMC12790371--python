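"""Alignment, FBP, tensor forward/adjoint, CG reconstruction, readouts."""

import copy
import warnings

import numpy as np
import pytest
from scipy import ndimage

from saxstt.geometry import geometry_for_phantom, tomo_rotations
from saxstt.harmonics import N_COEFFS, sh_basis, sphere_quadrature
from saxstt.phantom import make_phantom
from saxstt.projector import Projector
from saxstt.recon import (
    ReconConfig,
    SphericalFieldVolume,
    adjoint_operator,
    extract_orientation,
    forward_operator,
    prealign_projections,
    reconstruct_absorption,
    reconstruct_field,
    reconstruct_qbins,
    scans_to_tensor_data,
)
from saxstt.simulate import simulate_scan, simulate_tomogram
from saxstt.glyphs import export_glyphs, read_glyphs


# ---------------------------------------------------------------------------
# pre-alignment


def _cyl_scans(shape=(16, 16, 16), n_phi=12):
    ph = make_phantom({"recipe": "cylinder", "shape": shape})
    geom = geometry_for_phantom(ph, tomo_rotations(n_phi, [0.0]), q_edges=[0.5, 0.6])
    return ph, geom, simulate_tomogram(ph, geom, noiseless=True)


def test_prealign_already_aligned():
    ph, geom, scans = _cyl_scans()
    _, shifts, flags = prealign_projections(scans, geom)
    assert not flags.any()
    assert np.abs(shifts).max() < 0.25


def test_prealign_recovers_injected_shift():
    ph, geom, scans = _cyl_scans()
    shifted = [s.copy() for s in scans]
    k = 4
    a = -np.log(shifted[k].transmission)
    a = np.roll(a, 3, axis=1)  # +3 px along the fast axis
    shifted[k].transmission = np.exp(-a)
    _, shifts, flags = prealign_projections(shifted, geom)
    assert abs(shifts[k, 0] + 3.0) < 0.5
    others = np.delete(shifts[:, 0], k)
    assert np.abs(others).max() < 0.5


def test_prealign_featureless_flagged():
    ph, geom, scans = _cyl_scans()
    flat = []
    for s in scans:
        c = s.copy()
        c.transmission = np.full_like(c.transmission, 0.7)
        flat.append(c)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        _, shifts, flags = prealign_projections(flat, geom)
    assert flags.all()
    assert np.all(shifts == 0)


# ---------------------------------------------------------------------------
# absorption FBP


def test_absorption_uniform_cylinder_within_5pct():
    ph = make_phantom({"recipe": "cylinder", "shape": (32, 32, 32)})
    geom = geometry_for_phantom(ph, tomo_rotations(60, [0.0]), q_edges=[0.5, 0.6])
    scans = simulate_tomogram(ph, geom, noiseless=True)
    vol = reconstruct_absorption(scans, geom, shape=ph.shape)
    x, y, _ = np.indices(ph.shape)
    c = (ph.shape[0] - 1) / 2
    interior = (x - c) ** 2 + (y - c) ** 2 < (0.35 * 32 - 2.5) ** 2
    rel = np.abs(vol.mu[interior] - 1e-3) / 1e-3
    assert rel.max() < 0.05
    assert np.all(vol.mask[interior])


def test_absorption_zero_phantom():
    ph = make_phantom({"recipe": "cylinder", "shape": (12, 12, 12)})
    ph.attenuation[:] = 0.0
    geom = geometry_for_phantom(ph, tomo_rotations(12, [0.0]), q_edges=[0.5, 0.6])
    scans = simulate_tomogram(ph, geom, noiseless=True)
    vol = reconstruct_absorption(scans, geom, shape=ph.shape)
    assert np.allclose(vol.mu, 0.0, atol=1e-12)
    assert not vol.mask.any()


def test_absorption_impulse_argmax():
    ph = make_phantom({"recipe": "point", "shape": (16, 16, 16)})
    geom = geometry_for_phantom(ph, tomo_rotations(24, [0.0]), q_edges=[0.5, 0.6])
    scans = simulate_tomogram(ph, geom, noiseless=True)
    vol = reconstruct_absorption(scans, geom, shape=ph.shape)
    assert np.unravel_index(vol.mu.argmax(), ph.shape) == np.unravel_index(
        ph.attenuation.argmax(), ph.shape)


def test_absorption_few_projections_fallback_warns():
    ph = make_phantom({"recipe": "cylinder", "shape": (8, 8, 8)})
    geom = geometry_for_phantom(ph, tomo_rotations(4, [0.0]), q_edges=[0.5, 0.6])
    scans = simulate_tomogram(ph, geom, noiseless=True)
    with pytest.warns(UserWarning, match="untilted"):
        vol = reconstruct_absorption(scans, geom, shape=ph.shape)
    assert vol.mu.shape == ph.shape


# ---------------------------------------------------------------------------
# tensor operator


def test_forward_matches_simulation(rod_phantom, rod_geometry, rod_scans):
    """The reconstruction forward operator reproduces the noiseless
    simulation exactly (same kernel by construction)."""
    proj = Projector(rod_phantom.shape, rod_phantom.voxel_size, rod_geometry)
    pred = forward_operator(rod_phantom.sh_coeffs(), proj)
    data = scans_to_tensor_data(rod_scans)
    assert np.allclose(pred, data, rtol=1e-10, atol=1e-12)


def test_zero_field_zero_sinograms(rod_phantom, rod_geometry):
    proj = Projector(rod_phantom.shape, rod_phantom.voxel_size, rod_geometry)
    out = forward_operator(np.zeros((proj.n_voxels, N_COEFFS)), proj)
    assert not out.any()


def test_adjoint_dot_product():
    ph = make_phantom({"recipe": "single_rod", "shape": (8, 8, 8)})
    geom = geometry_for_phantom(ph, tomo_rotations(6, [0.0, 45.0]), q_edges=[0.5, 0.6])
    proj = Projector(ph.shape, ph.voxel_size, geom)
    rng = np.random.default_rng(0)
    for _ in range(3):
        x = rng.standard_normal((proj.n_voxels, N_COEFFS))
        y = rng.standard_normal((geom.n_rotations, geom.n_slow, geom.n_fast, 8))
        lhs = float(np.sum(forward_operator(x, proj) * y))
        rhs = float(np.sum(x * adjoint_operator(y, proj)))
        assert abs(lhs - rhs) <= 1e-8 * abs(lhs)


# ---------------------------------------------------------------------------
# CG reconstruction


def test_reconstruct_isotropic_preserves_isotropy():
    ph = make_phantom({"recipe": "cylinder", "shape": (12, 12, 12)})
    geom = geometry_for_phantom(ph, tomo_rotations(12, [0.0, 22.5, 45.0]),
                                q_edges=[0.5, 0.6])
    scans = simulate_tomogram(ph, geom, noiseless=True)
    field = reconstruct_field(scans, geom, ph.shape,
                              config=ReconConfig(lambda_rel=1e-5, max_iter=200))
    e0 = np.sum(field.coeffs[..., 0] ** 2)
    e2 = np.sum(field.coeffs[..., 1:] ** 2)
    assert e2 < 0.01 * e0


def test_reconstruct_large_lambda_limit():
    """With overwhelming smoothing the solution becomes spatially flat."""
    ph = make_phantom({"recipe": "single_rod", "shape": (8, 8, 8)})
    geom = geometry_for_phantom(ph, tomo_rotations(8, [0.0, 45.0]), q_edges=[0.5, 0.6])
    scans = simulate_tomogram(ph, geom, noiseless=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        field = reconstruct_field(scans, geom, ph.shape,
                                  config=ReconConfig(lambda_rel=1e4, max_iter=300))
    c00 = field.coeffs[..., 0]
    assert c00.std() < 0.05 * abs(c00.mean())


def test_reconstruct_field_noiseless_recovery(rod_phantom, rod_geometry, rod_scans):
    field = reconstruct_field(rod_scans, rod_geometry, rod_phantom.shape,
                              config=ReconConfig(lambda_rel=1e-6, max_iter=400,
                                                 tol=1e-10))
    true = rod_phantom.sh_coeffs().reshape(rod_phantom.shape + (N_COEFFS,))
    sup = rod_phantom.ground_truth["body_mask"]
    err = np.linalg.norm((field.coeffs - true)[sup], axis=-1)
    ref = np.linalg.norm(true[sup], axis=-1)
    assert np.median(err / ref) < 0.05
    assert field.residuals[-1] < field.residuals[0]


def test_reconstruct_qbins_matches_mean_density():
    ph = make_phantom({"recipe": "cylinder", "shape": (12, 12, 12)})
    geom = geometry_for_phantom(ph, tomo_rotations(12, [0.0, 45.0]),
                                q_edges=[0.4, 0.5, 0.6])
    scans = simulate_tomogram(ph, geom, noiseless=True)
    vols = reconstruct_qbins(scans, geom, ph.shape,
                             config=ReconConfig(lambda_rel=1e-6, max_iter=200))
    sup = ndimage.binary_erosion(ph.ground_truth["body_mask"], iterations=1)
    rel = np.abs(vols[sup] - 1.0)
    assert np.median(rel) < 0.05


def test_missing_tilt_degrades_recovery(rod_phantom):
    """Single-axis data (chi = 0 only) recovers orientation worse than
    two-tilt data on the same phantom — the known limitation."""
    errs = {}
    for tilts in ([0.0], [0.0, 45.0]):
        geom = geometry_for_phantom(rod_phantom, tomo_rotations(12, tilts),
                                    q_edges=[0.5, 0.6])
        scans = simulate_tomogram(rod_phantom, geom, noiseless=True)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            field = reconstruct_field(scans, geom, rod_phantom.shape,
                                      config=ReconConfig(lambda_rel=1e-6,
                                                         max_iter=250))
        orient = extract_orientation(field)
        truth = rod_phantom.ground_truth["fibril_axis"]
        sup = rod_phantom.anisotropy > 0
        dot = np.abs(np.sum(orient.main_axis * truth, axis=-1))
        errs[len(tilts)] = np.nanmedian(np.degrees(np.arccos(np.clip(dot[sup], 0, 1))))
    assert errs[1] >= errs[2]


# ---------------------------------------------------------------------------
# orientation readout


def test_extract_orientation_isotropic_voxel():
    coeffs = np.zeros((1, 1, 1, N_COEFFS))
    coeffs[..., 0] = 2.0
    orient = extract_orientation(SphericalFieldVolume(coeffs, 1.0, (0.5, 0.6)))
    assert orient.doo[0, 0, 0] == 0.0
    assert np.all(np.isnan(orient.main_axis[0, 0, 0]))


def test_extract_orientation_uniaxial_axis():
    from saxstt.harmonics import uniaxial_coeffs

    coeffs = uniaxial_coeffs(np.array([0.0, 0.0, 1.0]), 0.7, 2.0).reshape(1, 1, 1, -1)
    orient = extract_orientation(SphericalFieldVolume(coeffs, 1.0, (0.5, 0.6)))
    assert abs(abs(orient.main_axis[0, 0, 0, 2]) - 1.0) < 1e-10
    expected_doo = 0.7 * np.sqrt(4.0 / 45.0) / (1.0)
    assert orient.doo[0, 0, 0] == pytest.approx(expected_doo, rel=1e-10)


def test_extract_orientation_random_vs_quadrature():
    """DoO and eigen-decomposition match brute-force spherical quadrature to
    1e-4 on random coefficient sets."""
    pts, wts = sphere_quadrature(50, 200)
    basis = sh_basis(pts)
    rng = np.random.default_rng(99)
    c = rng.standard_normal((40, N_COEFFS))
    c[:, 0] = np.abs(c[:, 0]) + 2.0
    orient = extract_orientation(
        SphericalFieldVolume(c.reshape(40, 1, 1, N_COEFFS), 1.0, (0.5, 0.6)))
    for i in range(40):
        vals = basis @ c[i]
        mean_q = np.sum(vals * wts) / (4 * np.pi)
        std_q = np.sqrt(np.sum(wts * (vals - mean_q) ** 2) / (4 * np.pi))
        assert abs(orient.doo[i, 0, 0] - std_q / mean_q) < 1e-4
        m = np.einsum("n,ni,nj->ij", vals * wts, pts, pts)
        evals = np.linalg.eigvalsh(m)
        assert np.allclose(orient.eigenvalues[i, 0, 0], evals, atol=1e-8)


def test_extract_orientation_nonpositive_mean_flagged():
    coeffs = np.zeros((2, 1, 1, N_COEFFS))
    coeffs[1, ..., 3] = 0.5  # zero mean, nonzero degree-2
    orient = extract_orientation(SphericalFieldVolume(coeffs, 1.0, (0.5, 0.6)))
    assert np.all(np.isnan(orient.doo))
    assert np.all(np.isnan(orient.main_axis))


# ---------------------------------------------------------------------------
# glyphs


def test_export_glyphs_single_voxel(tmp_path):
    from saxstt.harmonics import uniaxial_coeffs
    from saxstt.recon import FibrilOrientationField

    axis = np.full((1, 1, 1, 3), np.nan)
    axis[0, 0, 0] = [0.0, 0.0, 1.0]
    orient = FibrilOrientationField(
        main_axis=axis, doo=np.full((1, 1, 1), 0.5),
        mean_intensity=np.ones((1, 1, 1)),
        eigenvalues=np.zeros((1, 1, 1, 3)), voxel_size=20.0)
    path = tmp_path / "one.vtk"
    n = export_glyphs(orient, path)
    assert n == 1
    data = read_glyphs(path)
    seg = data["points"][1] - data["points"][0]
    assert np.allclose(np.abs(seg / np.linalg.norm(seg)), [0, 0, 1])


def test_export_glyphs_doo_threshold_transparency(tmp_path):
    rng = np.random.default_rng(0)
    axis = rng.standard_normal((3, 3, 3, 3))
    axis /= np.linalg.norm(axis, axis=-1, keepdims=True)
    orient = FibrilOrientationFieldFactory(axis, doo=0.2)
    path = tmp_path / "dim.vtk"
    export_glyphs(orient, path, doo_min=0.4)
    data = read_glyphs(path)
    assert np.all(data["opacity"] == 0.0)


def FibrilOrientationFieldFactory(axis, doo):
    from saxstt.recon import FibrilOrientationField

    shape = axis.shape[:3]
    return FibrilOrientationField(
        main_axis=axis, doo=np.full(shape, doo),
        mean_intensity=np.ones(shape), eigenvalues=np.zeros(shape + (3,)),
        voxel_size=20.0)


def test_export_glyphs_empty_mask_raises(tmp_path):
    rng = np.random.default_rng(0)
    axis = rng.standard_normal((2, 2, 2, 3))
    axis /= np.linalg.norm(axis, axis=-1, keepdims=True)
    orient = FibrilOrientationFieldFactory(axis, doo=0.5)
    with pytest.raises(ValueError):
        export_glyphs(orient, tmp_path / "x.vtk", mask=np.zeros((2, 2, 2), bool))
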