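"""Frame reduction, cosine fits, colour maps and similarity metrics."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from saxstt.geometry import geometry_for_phantom, segment_azimuths
from saxstt.phantom import make_phantom
from saxstt.simulate import rasterize_frame, simulate_framerate_series, simulate_scan
from saxstt.scanning import (
    build_orientation_map,
    fit_orientation,
    framerate_study,
    normalize_transmission,
    orientation_dissimilarity,
    reduce_frame,
    render_colormap,
    similarity_error,
)

FRAME = dict(beam_center=(64.0, 64.0), pixel_size_um=75.0, distance_mm=300.0,
             wavelength_nm=0.1)


def test_reduce_frame_uniform():
    counts = np.full((128, 128), 3.7)
    means, npix = reduce_frame(counts, np.ones_like(counts, bool),
                               q_edges=[0.3, 0.6, 0.9], n_segments=16, **FRAME)
    assert means.shape == (8, 2)
    assert np.allclose(means[npix > 0], 3.7)


def test_reduce_frame_cosine_against_wedge_integral():
    """A painted frame 5 + 2 cos(2 (psi - 30 deg)) reduces to the per-wedge
    mean of that function to < 0.5% (numeric wedge-integration oracle)."""
    psi0 = np.deg2rad(30.0)

    def intensity(q, psi):
        return 5.0 + 2.0 * np.cos(2.0 * (psi - psi0))

    counts = rasterize_frame((256, 256), (128.0, 128.0), 75.0, 300.0, 0.1,
                             intensity)
    means, npix = reduce_frame(counts, np.ones_like(counts, bool),
                               beam_center=(128.0, 128.0), pixel_size_um=75.0,
                               distance_mm=300.0, wavelength_nm=0.1,
                               q_edges=[0.3, 0.9], n_segments=16)
    width = np.pi / 8
    for k in range(8):
        lo = k * np.pi / 8 - width / 2
        grid = np.linspace(lo, lo + width, 2001)
        oracle = np.mean(5.0 + 2.0 * np.cos(2.0 * (grid - psi0)))
        assert abs(means[k, 0] - oracle) / oracle < 0.005


def test_reduce_frame_masked_half_uses_valid_segment():
    counts = np.full((128, 128), 2.0)
    mask = np.ones_like(counts, bool)
    rows, cols = np.indices(counts.shape)
    # mask everything below the horizontal centre line: half the segments
    counts[rows > 64] = 999.0
    mask[rows > 64] = False
    means, npix = reduce_frame(counts, mask, q_edges=[0.3, 0.9],
                               n_segments=16, **FRAME)
    assert np.allclose(means[npix > 0], 2.0)


def test_reduce_frame_conserves_photons():
    rng = np.random.default_rng(0)
    counts = rng.poisson(20.0, (128, 128)).astype(float)
    mask = rng.random((128, 128)) > 0.1
    q_edges = np.array([0.2, 0.5, 0.8, 1.1])
    means, npix = reduce_frame(counts, mask, q_edges=q_edges, n_segments=16,
                               **FRAME)
    total_binned = np.nansum(np.where(npix > 0, means * npix, 0.0))
    # recompute the in-domain pixel sum independently
    rows, cols = np.indices(counts.shape)
    dr, dc = rows - 64.0, cols - 64.0
    r_mm = np.hypot(dr, dc) * 75.0 * 1e-3
    q = 4 * np.pi / 0.1 * np.sin(0.5 * np.arctan2(r_mm, 300.0))
    in_domain = mask & (q >= q_edges[0]) & (q < q_edges[-1])
    assert np.isclose(total_binned, counts[in_domain].sum(), rtol=1e-10)


def test_reduce_frame_all_masked_is_flagged_not_raised():
    counts = np.ones((64, 64))
    means, npix = reduce_frame(counts, np.zeros_like(counts, bool),
                               q_edges=[0.3, 0.9], n_segments=16,
                               beam_center=(32.0, 32.0), pixel_size_um=75.0,
                               distance_mm=300.0, wavelength_nm=0.1)
    assert np.all(np.isnan(means)) and np.all(npix == 0)


def test_normalize_transmission():
    seg = np.ones((4, 4, 8))
    t = np.ones((4, 4))
    assert np.array_equal(normalize_transmission(seg, t), seg)
    t[1, 2] = 0.5
    out = normalize_transmission(seg, t)
    assert np.allclose(out[1, 2], 2.0)
    assert np.allclose(out[0, 0], 1.0)
    with pytest.raises(ValueError):
        normalize_transmission(seg, t * 0.0)


def test_normalized_signal_independent_of_attenuation():
    """Beer-Lambert check: transmission-normalised noiseless signal does not
    depend on the attenuation map."""
    a = make_phantom({"recipe": "single_rod", "shape": (8, 8, 8)})
    import copy

    b = copy.deepcopy(a)
    b.attenuation = 3.0 * a.attenuation
    geom = geometry_for_phantom(a, [(25.0, 10.0)], q_edges=[0.5, 0.6])
    sa = simulate_scan(a, geom, 0, noiseless=True)
    sb = simulate_scan(b, geom, 0, noiseless=True)
    na = normalize_transmission(sa.segments, sa.transmission)
    nb = normalize_transmission(sb.segments, sb.transmission)
    assert np.allclose(na, nb, rtol=1e-10)


@given(
    a0=st.floats(0.5, 100.0),
    ratio=st.floats(0.0, 1.0),
    theta=st.floats(0.0, np.pi, exclude_max=True),
)
def test_fit_orientation_exact_on_model_span(a0, ratio, theta):
    """On 8 complete equispaced segments the fit is exact (machine
    precision) for any a0 + a1 cos(2(psi - theta0)) with a1 <= a0."""
    a1 = ratio * a0
    psi = segment_azimuths(8)
    y = a0 + a1 * np.cos(2 * (psi - theta))
    f0, f1, ft = fit_orientation(y)
    assert abs(f0 - a0) < 1e-9 * a0
    assert abs(f1 - a1) < 1e-9 * a0
    if a1 > 1e-6 * a0:
        d = abs(ft - theta)
        assert min(d, np.pi - d) < 1e-7


def test_fit_orientation_constant_and_missing():
    f0, f1, ft = fit_orientation(np.full(8, 4.2))
    assert f0 == pytest.approx(4.2) and f1 == pytest.approx(0.0)
    assert np.isnan(ft)
    y = np.full(8, np.nan)
    y[:2] = 1.0
    f0, f1, ft = fit_orientation(y)  # fewer than 3 segments -> undefined
    assert np.isnan(f0) and np.isnan(ft)


def test_fit_orientation_doo_bounded_for_nonnegative_data():
    rng = np.random.default_rng(1)
    y = rng.uniform(0.0, 5.0, (500, 8))
    a0, a1, _ = fit_orientation(y)
    doo = a1 / np.where(a0 > 0, a0, 1.0)
    assert np.all(doo >= 0) and np.all(doo <= 1.0 + 1e-12)


def test_fit_orientation_poisson_phase_accuracy():
    """Mean recovered theta0 over 10^4 Poisson trials lies within 1 degree
    of the truth for a0 = 100, a1 = 40."""
    rng = np.random.default_rng(123)
    psi = segment_azimuths(8)
    theta_true = np.deg2rad(72.0)
    lam = 100.0 + 40.0 * np.cos(2 * (psi - theta_true))
    y = rng.poisson(lam, size=(10_000, 8)).astype(float)
    _, _, theta = fit_orientation(y)
    # circular mean on the doubled angle
    mean_theta = 0.5 * np.arctan2(np.mean(np.sin(2 * theta)), np.mean(np.cos(2 * theta)))
    d = abs(np.mod(mean_theta, np.pi) - theta_true)
    assert min(d, np.pi - d) < np.deg2rad(1.0)


def test_build_orientation_map_rod_constant_theta(rod_phantom, rod_geometry, rod_scans):
    omap = build_orientation_map(rod_scans[0], (0.5, 0.6))
    strong = omap.a1 > 0.25 * np.nanmax(omap.a1)
    thetas = omap.theta0[strong]
    spread = np.ptp(np.mod(2 * thetas, 2 * np.pi))
    assert spread < 1e-6  # constant orientation across the rod footprint


def test_build_orientation_map_isotropic_zero_doo():
    ph = make_phantom({"recipe": "uniform_isotropic", "shape": (8, 8, 8)})
    geom = geometry_for_phantom(ph, [(10.0, 5.0)], q_edges=[0.5, 0.6])
    omap = build_orientation_map(simulate_scan(ph, geom, 0, noiseless=True), (0.5, 0.6))
    inside = omap.a0 > 0
    assert np.allclose(omap.degree_of_orientation[inside], 0.0, atol=1e-9)


def test_orientation_map_identical_across_disjoint_q_ranges(rod_phantom):
    """The anisotropy model is q-independent, so disjoint q ranges give the
    same orientation map."""
    geom = geometry_for_phantom(rod_phantom, [(15.0, 0.0)],
                                q_edges=[0.1, 0.2, 1.0, 1.1])
    scan = simulate_scan(rod_phantom, geom, 0, noiseless=True)
    m1 = build_orientation_map(scan, (0.1, 0.2))
    m2 = build_orientation_map(scan, (1.0, 1.1))
    ok = np.isfinite(m1.theta0)
    assert np.allclose(m1.theta0[ok], m2.theta0[ok], atol=1e-9)


def test_render_colormap_conventions():
    a0 = np.ones((2, 2))
    from saxstt.scanning import OrientationMap

    iso_map = OrientationMap(a0=a0, a1=np.zeros_like(a0),
                             theta0=np.full_like(a0, np.nan), q_range=(0.5, 0.6))
    rgb = render_colormap(iso_map)
    assert np.allclose(rgb[..., 0], rgb[..., 1]) and np.allclose(rgb[..., 1], rgb[..., 2])
    sat_map = OrientationMap(a0=a0, a1=a0.copy(),
                             theta0=np.zeros_like(a0), q_range=(0.5, 0.6))
    rgb = render_colormap(sat_map)
    assert rgb[..., 0].max() > 0.99 and np.allclose(rgb[..., 1:], 0.0, atol=1e-9)
    # theta and theta + pi give the same hue
    m_a = OrientationMap(a0=a0, a1=0.5 * a0, theta0=np.full_like(a0, 0.3),
                         q_range=(0.5, 0.6))
    m_b = OrientationMap(a0=a0, a1=0.5 * a0,
                         theta0=np.full_like(a0, np.mod(0.3 + np.pi, np.pi)),
                         q_range=(0.5, 0.6))
    assert np.allclose(render_colormap(m_a), render_colormap(m_b))


def test_similarity_error_examples():
    r = np.array([[1.0, 2.0], [3.0, 5.0]])
    assert similarity_error(r, r) == 0.0
    assert similarity_error(1.1 * r, r) == pytest.approx(0.1)
    i = np.array([[1.0, 2.0], [3.0, 4.0]])
    expected = np.sqrt(1.0 / (1 + 4 + 9 + 25))  # direct evaluation
    assert similarity_error(i, r) == pytest.approx(expected)
    with pytest.raises(ValueError):
        similarity_error(i, np.zeros_like(i))


@given(c=st.floats(0.01, 100.0), seed=st.integers(0, 10_000))
def test_similarity_error_scale_invariant(c, seed):
    rng = np.random.default_rng(seed)
    i = rng.random((6, 6)) + 0.1
    r = rng.random((6, 6)) + 0.1
    assert similarity_error(c * i, c * r) == pytest.approx(similarity_error(i, r))


def test_orientation_dissimilarity_examples():
    t = np.full((5, 5), 0.4)
    assert orientation_dissimilarity(t, t) == 0.0
    assert orientation_dissimilarity(t, t + np.pi / 2) == pytest.approx(1.0)
    assert orientation_dissimilarity(t, t + np.pi / 4) == pytest.approx(np.sqrt(0.5))
    # adding pi to every angle changes nothing (half-turn quantity)
    rng = np.random.default_rng(2)
    a = rng.uniform(0, np.pi, (5, 5))
    b = rng.uniform(0, np.pi, (5, 5))
    assert orientation_dissimilarity(a + np.pi, b) == pytest.approx(
        orientation_dissimilarity(a, b))
    assert 0.0 <= orientation_dissimilarity(a, b) <= 1.0


def test_framerate_study_noiseless_all_zero():
    ph = make_phantom({"recipe": "single_rod", "shape": (8, 8, 8)})
    geom = geometry_for_phantom(ph, [(0.0, 0.0)], q_edges=[0.45, 0.55, 0.65])
    series = simulate_framerate_series(ph, geom, [10.0, 100.0, 500.0],
                                       noiseless=True)
    table = framerate_study(series, [(0.45, 0.55)])
    assert np.allclose(table[["E_mean", "E_aniso", "E_angle"]].values, 0.0,
                       atol=1e-9)
    assert np.allclose(table.iloc[0][["E_mean", "E_aniso", "E_angle"]], 0.0)
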