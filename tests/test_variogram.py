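"""Semivariogram estimation, subsampling, rebalancing, model fitting."""

import numpy as np
import pytest

from laiscape import (
    SceneConfig,
    effective_ranges,
    empirical_variogram,
    fit_variogram_ladder,
    gaussian_random_field,
    generate_mosaic,
    rebalance_abundance,
    simulate_lai,
    subsample_points,
    subsample_stability,
)
from laiscape.raster import Raster
from laiscape.variogram import EmpiricalVariogram, VariogramModel, failed_fit


def brute_force_variogram(points, lag_width, max_lag):
    n_bins = int(np.ceil(max_lag / lag_width))
    sums = np.zeros(n_bins)
    counts = np.zeros(n_bins, np.int64)
    for i in range(len(points)):
        for j in range(i + 1, len(points)):
            d = np.hypot(points[i, 0] - points[j, 0], points[i, 1] - points[j, 1])
            if 0 < d < max_lag:
                b = int(d // lag_width)
                sums[b] += (points[i, 2] - points[j, 2]) ** 2
                counts[b] += 1
    gamma = np.where(counts > 0, sums / (2 * np.maximum(counts, 1)), 0.0)
    return gamma, counts


class TestSubsample:
    def test_count_and_determinism(self, rng):
        r = Raster(rng.random((100, 100)), 5.0)
        a = subsample_points(r, 0.005, 3)
        assert a.shape == (50, 3)
        b = subsample_points(r, 0.005, 3)
        assert np.array_equal(a, b)

    def test_fraction_one_returns_all_valid(self, rng):
        r = Raster(rng.random((20, 20)), 5.0)
        assert subsample_points(r, 1.0, 0).shape[0] == 400

    def test_coordinates_are_pixel_centers(self, rng):
        r = Raster(rng.random((4, 4)), 10.0)
        pts = subsample_points(r, 1.0, 0)
        assert set(np.unique(pts[:, 0])) == {5.0, 15.0, 25.0, 35.0}

    @pytest.mark.parametrize("frac", [0.0, 1.5])
    def test_bad_fraction_raises(self, frac, rng):
        with pytest.raises(ValueError):
            subsample_points(Raster(rng.random((5, 5)), 5.0), frac, 0)


class TestRebalance:
    def test_already_balanced_unchanged(self):
        codes = np.array([1] * 50 + [2] * 50)
        kept = rebalance_abundance(codes, {1: 0.5, 2: 0.5}, 0)
        assert len(kept) == 100

    def test_closed_form_removal(self):
        codes = np.array([1] * 60 + [2] * 40)
        kept = rebalance_abundance(codes, {1: 0.5, 2: 0.5}, 0)
        assert (codes[kept] == 1).sum() == 40
        assert (codes[kept] == 2).sum() == 40

    def test_deterministic_under_seed(self):
        codes = np.tile([1, 1, 1, 2], 30)
        a = rebalance_abundance(codes, {1: 0.5, 2: 0.5}, 9)
        b = rebalance_abundance(codes, {1: 0.5, 2: 0.5}, 9)
        assert np.array_equal(a, b)

    def test_absent_target_class_raises(self):
        with pytest.raises(ValueError, match="absent"):
            rebalance_abundance(np.array([1, 1]), {1: 0.5, 2: 0.5}, 0)


class TestEmpiricalVariogram:
    def test_constant_values_zero_everywhere(self):
        pts = np.column_stack([np.arange(10.0), np.zeros(10), np.full(10, 2.0)])
        ev = empirical_variogram(pts, 2.0, 12.0)
        assert not ev.semivariance.any()

    def test_two_point_estimator_formula(self):
        pts = np.array([[0.0, 0.0, 1.0], [30.0, 40.0, 4.0]])  # distance 50, diff 3
        ev = empirical_variogram(pts, 20.0, 100.0)
        assert ev.pair_counts[2] == 1
        assert ev.semivariance[2] == pytest.approx(4.5)  # 3^2 / 2

    @pytest.mark.parametrize("n", [50, 300, 500])
    def test_matches_brute_force_oracle(self, n, rng):
        pts = np.column_stack(
            [rng.uniform(0, 1000, n), rng.uniform(0, 1000, n), rng.normal(0, 1, n)]
        )
        ev = empirical_variogram(pts, 100.0, 800.0, chunk=37)
        gamma, counts = brute_force_variogram(pts, 100.0, 800.0)
        assert np.array_equal(ev.pair_counts, counts)
        assert np.allclose(ev.semivariance, gamma)

    def test_iid_noise_is_flat_at_value_variance(self, rng):
        r = Raster(rng.normal(0, 2.0, (150, 150)), 10.0)
        pts = subsample_points(r, 0.3, 1)
        ev = empirical_variogram(pts, 100.0, 1000.0)
        good = ev.pair_counts > 100
        assert np.allclose(ev.semivariance[good], 4.0, rtol=0.1)

    def test_too_few_points_raise(self):
        with pytest.raises(ValueError, match="2 points"):
            empirical_variogram(np.array([[0.0, 0.0, 1.0]]), 10.0, 100.0)


class TestSubsampleStability:
    def test_full_fraction_gives_zero_deviation(self, rng):
        r = Raster(rng.random((40, 40)), 10.0)
        dev = subsample_stability(r, 1.0, 3, 0, lag_width=50.0, max_lag=300.0)
        assert dev == 0.0

    def test_constant_raster_reports_zero_with_warning(self):
        r = Raster(np.full((40, 40), 1.5), 10.0)
        with pytest.warns(UserWarning, match="stability"):
            assert subsample_stability(r, 0.5, 3, 0, 50.0, 300.0) == 0.0

    def test_deviation_shrinks_with_larger_fraction(self, rng):
        r = Raster(rng.normal(0, 1, (120, 120)), 10.0)
        small = subsample_stability(r, 0.05, 8, 0, 100.0, 800.0)
        large = subsample_stability(r, 0.4, 8, 0, 100.0, 800.0)
        assert large < small

    def test_reps_below_two_raise(self, rng):
        with pytest.raises(ValueError):
            subsample_stability(Raster(rng.random((10, 10)), 5.0), 0.5, 1, 0)


class TestFitLadder:
    def synthetic_ev(self, model, lags, n=500):
        gamma = model(lags)
        return EmpiricalVariogram(
            lags, gamma, np.full(len(lags), n), lags[1] - lags[0], lags[-1] + 25
        )

    def test_recovers_simple_exponential(self):
        truth = VariogramModel(0.0, [(1.0, 100.0)], True)
        lags = np.arange(25.0, 1000.0, 50.0)
        fit = fit_variogram_ladder(self.synthetic_ev(truth, lags))
        assert fit.converged
        (sill, a) = max(fit.components, key=lambda c: c[0])
        assert abs(sill - 1.0) / 1.0 < 0.05 and abs(a - 100.0) / 100.0 < 0.05

    def test_recovers_nested_model(self):
        truth = VariogramModel(0.0, [(0.5, 60.0), (0.5, 1000.0)], True)
        lags = np.arange(15.0, 6000.0, 30.0)
        fit = fit_variogram_ladder(self.synthetic_ev(truth, lags))
        short, long = effective_ranges(fit)
        assert abs(short - 180.0) / 180.0 < 0.3
        assert abs(long - 3000.0) / 3000.0 < 0.3

    def test_pure_nugget_flagged(self):
        lags = np.arange(25.0, 2000.0, 50.0)
        ev = EmpiricalVariogram(
            lags, np.full(len(lags), 2.0), np.full(len(lags), 400), 50.0, 2000.0
        )
        fit = fit_variogram_ladder(ev)
        # flat input: either unfittable or all structure collapses into
        # nugget/zero-range components with no meaningful long range
        if fit.converged:
            short, long = effective_ranges(fit)
            total = fit.total_sill
            structured = sum(s for s, a in fit.components if 3 * a > lags[0])
            assert structured < 0.2 * total or (short is not None and short < 200)

    def test_empty_variogram_fails_explicitly(self):
        ev = EmpiricalVariogram(
            np.array([100.0, 300.0]), np.zeros(2), np.zeros(2, int), 200.0, 400.0
        )
        fit = fit_variogram_ladder(ev)
        assert not fit.converged and effective_ranges(fit) == (None, None)


class TestEffectiveRanges:
    def test_three_a_rule(self):
        m = VariogramModel(0.0, [(1.0, 100.0)], True)
        short, long = effective_ranges(m)
        assert short == pytest.approx(300.0) and long is None
        # exact 95% point of the exponential is a ln 20 ~ 299.6 m
        assert abs(100.0 * np.log(20.0) - short) < 1.0

    def test_nested_components_sorted(self):
        m = VariogramModel(0.1, [(0.5, 1000.0), (0.5, 50.0)], True)
        assert effective_ranges(m) == (pytest.approx(150.0), pytest.approx(3000.0))

    def test_zero_sill_component_ignored(self):
        m = VariogramModel(0.0, [(1.0, 100.0), (0.0, 5000.0)], True)
        short, long = effective_ranges(m)
        assert short == pytest.approx(300.0) and long is None

    def test_failed_fit_has_no_ranges(self):
        assert effective_ranges(failed_fit()) == (None, None)


class TestParameterRecoveryOnScenes:
    def test_field_scale_range_from_mosaic(self):
        # single-crop mosaic: fitted short range reflects field dimensions
        cfg = SceneConfig(
            rows=700, cols=700, resolution=5.0, seed=10,
            crop_proportions={"winter_wheat": 1.0},
            forest_fraction=0.0, bare_fraction=0.0,
        )
        truth = generate_mosaic(cfg)
        lai = simulate_lai(truth, cfg, 140)
        pts = subsample_points(lai, 0.02, 10, mask=truth.landuse.data == 1)
        ev = empirical_variogram(pts, 50.0, 2500.0)
        fit = fit_variogram_ladder(ev)
        short, _ = effective_ranges(fit)
        # mean field 2.06 ha -> dimension ~143 m; range within a field scale
        assert fit.converged and 80.0 < short < 450.0

    def test_long_range_background_detected(self, rng):
        z = gaussian_random_field(500, 500, 20.0, 1.0, 800.0, rng)
        pts = subsample_points(Raster(z, 20.0), 0.02, 5)
        ev = empirical_variogram(pts, 100.0, 6000.0)
        fit = fit_variogram_ladder(ev)
        short, long = effective_ranges(fit)
        best = long if long is not None else short
        assert fit.converged and abs(best - 2400.0) / 2400.0 < 0.5
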