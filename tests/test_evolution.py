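import numpy as np
import pytest
from dataclasses import replace
from scipy.ndimage import binary_dilation

from vesselsnake import (
    EnergyParams,
    PhantomSpec,
    ScaleParams,
    evolve,
    fit_histogram_gmm,
    initialize_phi,
    local_stats,
    make_phantom,
    overlap_metrics,
    reinitialize,
    speed_field,
)
from vesselsnake.evolution import (
    LocalRegionStats,
    baseline_params,
    curvature,
    dirac_eps,
    _log_bayes_integral,
)
from vesselsnake.grid import ImageGrid
from vesselsnake.phantoms import default_seed_mask
from skimage import measure


def _disk(shape, center, radius):
    yy, xx = np.mgrid[: shape[0], : shape[1]].astype(float)
    return np.hypot(yy - center[0], xx - center[1]) <= radius


class TestInitializePhi:
    def test_disk_center_distance(self):
        mask = _disk((64, 64), (32, 32), 10)
        phi = initialize_phi(mask).phi
        assert phi[32, 32] == pytest.approx(10.0, abs=0.5)

    def test_positive_exactly_on_seed(self):
        mask = _disk((48, 48), (20, 25), 7)
        phi = initialize_phi(mask).phi
        np.testing.assert_array_equal(phi > 0, mask)

    def test_empty_and_full_rejected(self):
        with pytest.raises(ValueError):
            initialize_phi(np.zeros((8, 8), dtype=bool))
        with pytest.raises(ValueError):
            initialize_phi(np.ones((8, 8), dtype=bool))


class TestReinitialize:
    def _fresh(self):
        return initialize_phi(_disk((64, 64), (32, 32), 12)).phi

    def test_fixed_point_on_fresh_sdf(self):
        phi = self._fresh()
        out = reinitialize(phi)
        band = np.abs(phi) <= 5
        assert np.abs(out - phi)[band].max() < 0.1

    def test_recovers_sdf_from_rescaled(self):
        phi = self._fresh()
        out = reinitialize(3.0 * phi)
        band = np.abs(phi) <= 5
        assert np.abs(out - phi)[band].max() < 0.1

    def test_sign_pattern_preserved(self):
        rng = np.random.default_rng(0)
        phi = self._fresh() + rng.normal(0, 0.2, (64, 64))
        out = reinitialize(phi)
        np.testing.assert_array_equal(out > 0, phi > 0)

    def test_gradient_magnitude_restored(self):
        # smooth analytic interface (an ellipse level function, not an SDF)
        yy, xx = np.mgrid[:80, :80].astype(float)
        phi0 = 1.0 - ((xx - 39.5) ** 2 / 20 ** 2 + (yy - 39.5) ** 2 / 12 ** 2)
        out = reinitialize(phi0)
        gy, gx = np.gradient(out)
        gmag = np.hypot(gy, gx)
        # pointwise away from the interface row (central differences kink
        # right at the contour), robustly over the whole narrowband
        off = (np.abs(out) >= 1.5) & (np.abs(out) <= 5)
        assert np.abs(gmag[off] - 1.0).max() <= 0.1
        band = np.abs(out) <= 5
        assert np.quantile(np.abs(gmag[band] - 1.0), 0.95) <= 0.1

    def test_zero_set_moves_less_than_half_voxel(self):
        phi = self._fresh()
        out = reinitialize(1.7 * phi + 0.05)
        c0 = np.vstack(measure.find_contours(phi, 0))
        c1 = np.vstack(measure.find_contours(out, 0))
        from scipy.spatial import cKDTree

        d = cKDTree(c0).query(c1)[0]
        assert d.max() < 0.5

    def test_no_zero_crossing_rejected(self):
        with pytest.raises(ValueError):
            reinitialize(np.full((16, 16), 2.0))


class TestLocalStats:
    def test_matches_bruteforce_window_loop(self):
        rng = np.random.default_rng(3)
        img = rng.uniform(0, 10, (11, 11))
        inside = np.zeros((11, 11), dtype=bool)
        inside[4:9, 3:8] = True
        phi = np.where(inside, 1.0, -1.0)
        r = 3
        st = local_stats(phi, ImageGrid(img), np.full((11, 11), r), shrink_n=0,
                        sigma2_floor=1e-12, points=np.ones((11, 11), bool))
        cy, cx = 5, 5
        vals_in, vals_out = [], []
        for y in range(11):
            for x in range(11):
                if (y - cy) ** 2 + (x - cx) ** 2 <= r * r:
                    (vals_in if inside[y, x] else vals_out).append(img[y, x])
        assert st.mu1[cy, cx] == pytest.approx(np.mean(vals_in), abs=1e-8)
        assert st.var1[cy, cx] == pytest.approx(np.var(vals_in), abs=1e-8)
        assert st.mu2[cy, cx] == pytest.approx(np.mean(vals_out), abs=1e-8)
        assert st.var2[cy, cx] == pytest.approx(np.var(vals_out), abs=1e-8)
        assert st.n1[cy, cx] == pytest.approx(len(vals_in), abs=1e-6)

    def test_piecewise_constant_regions_recovered(self, clean_tube):
        _, img, truth = clean_tube
        phi = initialize_phi(truth).phi
        st = local_stats(phi, img, np.full(img.shape, 6))
        band = np.abs(phi) <= 4
        np.testing.assert_allclose(st.mu1[band], 100.0, atol=1.0)
        np.testing.assert_allclose(st.mu2[band], 0.0, atol=1.0)

    def test_empty_side_falls_back_to_global(self):
        img = ImageGrid(np.linspace(0, 1, 400).reshape(20, 20))
        inside = np.zeros((20, 20), dtype=bool)
        inside[2:4, 2:4] = True
        phi = np.where(inside, 1.0, -1.0)
        st = local_stats(phi, img, np.full((20, 20), 3),
                         points=np.ones((20, 20), bool))
        # far corner window holds no interior voxels -> global interior stats
        assert st.n1[18, 18] == pytest.approx(0.0, abs=1e-9)
        assert st.mu1[18, 18] == pytest.approx(img.data[inside].mean())


class TestSpeedField:
    def test_circle_curvature_speed(self):
        shape = (96, 96)
        yy, xx = np.mgrid[: shape[0], : shape[1]].astype(float)
        R = 25.0
        phi = R - np.hypot(yy - 47.5, xx - 47.5)  # analytic SDF, positive inside
        img = ImageGrid(np.full(shape, 5.0))
        params = EnergyParams(lambda_shape=0.0, mu_smooth=0.2, data_smooth=0.0)
        floor = 1e-6
        stats = LocalRegionStats(*[np.full(shape, v) for v in
                                   (5.0, floor, 10, 5.0, floor, 10)])
        dphidt = speed_field(phi, img, stats, None, params)
        theta = np.linspace(0, 2 * np.pi, 20, endpoint=False)
        expected = dirac_eps(0.0, params.epsilon_heaviside) * params.mu_smooth / R
        for t in theta:
            y = int(round(47.5 + R * np.sin(t)))
            x = int(round(47.5 + R * np.cos(t)))
            assert abs(dphidt[y, x]) == pytest.approx(expected, rel=0.25)
            assert dphidt[y, x] < 0  # length term shrinks a circle

    def test_stationary_on_true_edge_lambda0(self, clean_tube, clean_tube_model):
        _, img, truth = clean_tube
        params = replace(EnergyParams(lambda_shape=0.0, mu_smooth=0.0), max_iters=40)
        res = evolve(img, truth, model=clean_tube_model, params=params)
        tp, fp, om = overlap_metrics(res.mask, truth)
        assert om >= 0.99

    def test_blob_interior_erodes(self):
        # bright disk, contour strictly inside it: intensity force ~0, the
        # hinged shape term must shrink the contour
        shape = (96, 96)
        img_arr = np.where(_disk(shape, (48, 48), 20), 100.0, 0.0)
        img = ImageGrid(img_arr)
        model = fit_histogram_gmm(img, n_components=2, seed=0)
        seed = _disk(shape, (48, 48), 12)
        res = evolve(img, seed, model=model,
                     params=EnergyParams(max_iters=30, adaptive_scale=False))
        assert res.mask.sum() < seed.sum()

    def test_integral_force_zero_at_perfect_partition(self):
        rng = np.random.default_rng(0)
        img_arr = np.where(_disk((24, 24), (12, 12), 6), 10.0, 0.0)
        img = ImageGrid(img_arr)
        inside = img_arr > 5
        phi = initialize_phi(inside).phi
        radii = np.full((24, 24), 4)
        band = np.abs(phi) <= 2
        st = local_stats(phi, img, radii, points=band, sigma2_floor=0.01)
        out = _log_bayes_integral(img.data, phi, radii, st, band)
        assert np.abs(out[band]).max() < 0.3

    def test_nonfinite_input_raises(self, clean_tube):
        _, img, truth = clean_tube
        phi = initialize_phi(truth).phi
        shape = phi.shape
        bad = LocalRegionStats(*[np.full(shape, v) for v in
                                 (np.nan, 1.0, 5, 0.0, 1.0, 5)])
        with pytest.raises(FloatingPointError):
            speed_field(phi, img, bad, None, EnergyParams(lambda_shape=0.0))


class TestEvolve:
    def test_clean_tube_high_dice(self, clean_tube, clean_tube_model, scale):
        spec, img, truth = clean_tube
        res = evolve(img, default_seed_mask(spec), model=clean_tube_model,
                     params=EnergyParams(max_iters=400), scale=scale)
        _, _, om = overlap_metrics(res.mask, truth)
        assert om >= 0.95

    def test_deterministic_bit_identical(self, noisy_tube, noisy_tube_model, scale):
        spec, img, truth = noisy_tube
        params = EnergyParams(max_iters=80)
        a = evolve(img, default_seed_mask(spec), model=noisy_tube_model,
                   params=params, scale=scale)
        b = evolve(img, default_seed_mask(spec), model=noisy_tube_model,
                   params=params, scale=scale)
        np.testing.assert_array_equal(a.mask, b.mask)
        np.testing.assert_array_equal(a.phi, b.phi)
        np.testing.assert_array_equal(a.energy_trace, b.energy_trace)

    def test_energy_trace_decreases_on_clean_refinement(self, clean_tube,
                                                        clean_tube_model):
        _, img, truth = clean_tube
        seed = binary_dilation(truth, iterations=3)
        params = replace(EnergyParams(max_iters=80), full_domain=True)
        res = evolve(img, seed, model=clean_tube_model, params=params)
        E = res.energy_trace
        assert E[-1] < E[0]
        rng_E = E.max() - E.min()
        assert np.diff(E).max() <= 0.01 * rng_E + 1e-9

    def test_contour_vanishes_reported_not_raised(self):
        img = ImageGrid(np.zeros((48, 48)))
        seed = _disk((48, 48), (24, 24), 4)
        params = EnergyParams(lambda_shape=0.0, mu_smooth=2.0, max_iters=400,
                              adaptive_scale=False, data_smooth=0.0)
        res = evolve(img, seed, model=None, params=params)
        assert res.mask.sum() == 0
        assert not res.converged

    def test_adaptive_requires_model(self, clean_tube):
        spec, img, _ = clean_tube
        with pytest.raises(ValueError, match="BloodPoolModel"):
            evolve(img, default_seed_mask(spec), model=None, params=EnergyParams())

    def test_baseline_params_disable_shape_and_adaptivity(self):
        p = baseline_params(EnergyParams())
        assert p.lambda_shape == 0.0
        assert not p.adaptive_scale


def test_curvature_of_circle_sdf():
    yy, xx = np.mgrid[:80, :80].astype(float)
    R = 20.0
    phi = R - np.hypot(yy - 39.5, xx - 39.5)
    kappa = curvature(phi)
    theta = np.linspace(0, 2 * np.pi, 16, endpoint=False)
    for t in theta:
        y = int(round(39.5 + R * np.sin(t)))
        x = int(round(39.5 + R * np.cos(t)))
        assert kappa[y, x] == pytest.approx(-1.0 / R, rel=0.2)


def test_3d_volume_segmentation_smoke():
    """The whole stack (phantom, GMM, profiles on a sphere, windowed stats,
    reinit via marching cubes) operates on 3D volumes."""
    spec = PhantomSpec(shape=(32, 32, 32), noise_sigma=15.0, intensity_vessel=60.0,
                       vessel_radius=2.5, geometry="straight", rng_seed=0)
    img, truth = make_phantom(spec)
    model = fit_histogram_gmm(img, n_components=3, seed=0)
    seed = default_seed_mask(spec)
    res = evolve(img, seed, model=model,
                 params=EnergyParams(max_iters=40),
                 scale=ScaleParams(min_scale=2, max_scale=4))
    assert res.mask.ndim == 3
    assert res.mask.sum() > seed.sum()
    tp, _, _ = overlap_metrics(res.mask, truth)
    assert tp > 0.2
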