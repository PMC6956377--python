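"""Parameter estimation: RSS, R^2, GA fit, replicate aggregation."""

import numpy as np
import pytest
from dataclasses import replace

from spherekin.fitting import (
    FitConfig,
    UndefinedStatisticError,
    UnfittableDataError,
    _batched_rss,
    fit_release,
    fit_replicates,
    r_squared,
    residual_sum_of_squares,
)
from spherekin.sphere_model import (
    DEFAULT_RADIUS_M,
    InvalidParameterError,
    ModelParams,
    ReleaseCurve,
    fractional_release,
)
from spherekin.synthetic_data import builtin_scenarios, generate_release_curve

FAST = FitConfig(population_size=40, generations=60, seed=7)


def shifted(curve, delta):
    return ReleaseCurve(
        times=curve.times, fractions=np.clip(curve.fractions + delta, 0, 1.5)
    )


class TestResidualSumOfSquares:
    def test_zero_for_generating_parameters(self, scenarios, noiseless_curves):
        for name, curve in noiseless_curves.items():
            p = scenarios[name].true_params
            assert residual_sum_of_squares(curve, p) == pytest.approx(0.0, abs=1e-16)

    def test_constant_offset_arithmetic(self):
        p = ModelParams(d_eff=5.58e-16, h=4.01e-10)
        times = np.array([1.0, 2.0, 4.0, 8.0]) * 86400
        pred = fractional_release(p, times)
        curve = ReleaseCurve(times=times, fractions=pred + 0.1)
        assert residual_sum_of_squares(curve, p) == pytest.approx(0.04, rel=1e-12)

    def test_any_perturbation_increases_rss_on_noiseless_curve(
        self, scenarios, noiseless_curves
    ):
        name = "sls"
        p = scenarios[name].true_params
        curve = noiseless_curves[name]
        x0 = np.array([np.log10(p.d_eff), np.log10(p.h)])
        base = _batched_rss(x0[None, :], curve, p.radius, "full_eq3", 120)[0]
        grid = [
            x0 + np.array([dd, dh])
            for dd in (-0.1, -0.02, 0.02, 0.1)
            for dh in (-0.1, -0.02, 0.02, 0.1)
        ]
        rss = _batched_rss(np.array(grid), curve, p.radius, "full_eq3", 120)
        assert np.all(rss > base)

    def test_too_few_points_rejected(self):
        p = ModelParams(d_eff=1e-15, h=1e-10)
        curve = ReleaseCurve(times=[1.0, 2.0], fractions=[0.1, 0.2])
        with pytest.raises(UnfittableDataError):
            residual_sum_of_squares(curve, p)


class TestRSquared:
    def test_perfect_fit_is_100(self, scenarios, noiseless_curves):
        assert r_squared(
            noiseless_curves["sls"], scenarios["sls"].true_params
        ) == pytest.approx(100.0, abs=1e-9)

    def test_predicting_the_mean_is_0(self):
        # exhausted release (tau >> 1) predicts 1 everywhere; observations
        # with mean 1 then make the prediction equal mean(observed), so
        # SSres = SStot and R^2 = 0 by definition
        p = ModelParams(d_eff=1.0, h=1e6, radius=1.0)
        curve = ReleaseCurve(times=[10.0, 20.0, 30.0], fractions=[0.9, 1.0, 1.1])
        assert r_squared(curve, p) == pytest.approx(0.0, abs=1e-6)

    def test_zero_variance_is_undefined(self):
        p = ModelParams(d_eff=1e-15, h=1e-10)
        curve = ReleaseCurve(times=[1.0, 2.0, 3.0], fractions=[0.5, 0.5, 0.5])
        with pytest.raises(UndefinedStatisticError):
            r_squared(curve, p)

    def test_noisy_fit_r_squared_tracks_noise_level(self, scenarios):
        sc = replace(scenarios["sls"], noise_sd=0.02, n_replicates=1, seed=11)
        curve = generate_release_curve(sc)[0]
        fit = fit_release(curve, sc.true_params.radius, FAST)
        # SStot ~ 1.2, noise SSres ~ 12 * 0.0004: R^2 should sit near 99-100%
        assert 95.0 < fit.r_squared <= 100.0


class TestFitRelease:
    def test_recovers_slow_regime_constants(self, scenarios, noiseless_curves):
        p = scenarios["sls"].true_params
        fit = fit_release(noiseless_curves["sls"], p.radius, FitConfig(seed=1))
        assert fit.params.d_eff == pytest.approx(p.d_eff, rel=0.05)
        assert fit.params.h == pytest.approx(p.h, rel=0.10)

    def test_recovers_fast_regime_constants(self, scenarios, noiseless_curves):
        p = scenarios["meoh_water"].true_params
        fit = fit_release(noiseless_curves["meoh_water"], p.radius, FitConfig(seed=1))
        assert fit.params.d_eff == pytest.approx(p.d_eff, rel=0.05)

    def test_log_space_recovery_low_biot(self, scenarios, noiseless_curves):
        # informative sampling at L = 1: both parameters within 0.05 log10 units
        p = scenarios["low_biot"].true_params
        fit = fit_release(noiseless_curves["low_biot"], p.radius, FitConfig(seed=2))
        assert abs(np.log10(fit.params.d_eff / p.d_eff)) < 0.05
        assert abs(np.log10(fit.params.h / p.h)) < 0.05

    def test_seeded_determinism_is_bitwise(self, noiseless_curves):
        a = fit_release(noiseless_curves["sls"], DEFAULT_RADIUS_M, FAST)
        b = fit_release(noiseless_curves["sls"], DEFAULT_RADIUS_M, FAST)
        assert a.params.d_eff == b.params.d_eff
        assert a.params.h == b.params.h
        assert a.rss == b.rss

    def test_beats_exhaustive_grid_search(self, noiseless_curves):
        # oracle: 200 x 200 log-space grid over the same bounds
        curve = noiseless_curves["low_biot"]
        cfg = FitConfig(seed=3)
        fit = fit_release(curve, DEFAULT_RADIUS_M, cfg)
        d_grid = np.linspace(*cfg.log10_d_eff_bounds, 200)
        h_grid = np.linspace(*cfg.log10_h_bounds, 200)
        dd, hh = np.meshgrid(d_grid, h_grid, indexing="ij")
        pop = np.column_stack([dd.ravel(), hh.ravel()])
        best_grid = np.inf
        for chunk in np.array_split(pop, 20):
            best_grid = min(
                best_grid,
                _batched_rss(chunk, curve, DEFAULT_RADIUS_M, "full_eq3", 120).min(),
            )
        assert fit.rss <= best_grid

    def test_degenerate_curve_rejected(self):
        flat = ReleaseCurve(times=[1.0, 2.0, 3.0], fractions=[0.4, 0.4, 0.4])
        with pytest.raises(UnfittableDataError):
            fit_release(flat, DEFAULT_RADIUS_M, FAST)
        nan = ReleaseCurve(times=[1.0, 2.0, 3.0], fractions=[0.1, np.nan, 0.3])
        with pytest.raises(UnfittableDataError):
            fit_release(nan, DEFAULT_RADIUS_M, FAST)

    def test_h_flagged_when_film_resistance_negligible(self, scenarios):
        # at L >> 1e3 the curve is insensitive to h: the fit must not report
        # a precise h; it lands at a bound or fails the sensitivity probe
        p = ModelParams(d_eff=5.58e-16, h=1e-6, radius=DEFAULT_RADIUS_M)  # L ~ 9e4
        sc = replace(
            scenarios["sls"], true_params=p, noise_sd=0.0, n_replicates=1
        )
        curve = generate_release_curve(sc)[0]
        fit = fit_release(curve, p.radius, FitConfig(seed=5))
        assert fit.params.d_eff == pytest.approx(p.d_eff, rel=0.05)
        assert fit.h_weakly_identified

    def test_simplified_variant_ignores_h(self, noiseless_curves):
        cfg = replace(FAST, model_variant="simplified_eq6")
        fit = fit_release(noiseless_curves["meoh_water"], DEFAULT_RADIUS_M, cfg)
        assert fit.h_weakly_identified
        assert fit.model_variant == "simplified_eq6"


class TestFitReplicates:
    def test_identical_replicates_have_zero_spread(self, noiseless_curves):
        curves = [noiseless_curves["sls"]] * 3
        summary = fit_replicates(curves, DEFAULT_RADIUS_M, FAST)
        assert summary.n_replicates == 3
        assert summary.d_eff_sd <= 0.02 * summary.d_eff_mean

    def test_noisy_replicates_mean_near_truth(self, scenarios):
        sc = replace(scenarios["sls"], noise_sd=0.02, n_replicates=3, seed=21)
        curves = generate_release_curve(sc)
        summary = fit_replicates(curves, sc.true_params.radius, FitConfig(seed=21))
        assert summary.d_eff_mean == pytest.approx(sc.true_params.d_eff, rel=0.15)
        assert summary.sd_defined

    def test_single_replicate_sd_undefined(self, noiseless_curves):
        summary = fit_replicates([noiseless_curves["sls"]], DEFAULT_RADIUS_M, FAST)
        assert not summary.sd_defined
        assert np.isnan(summary.d_eff_sd)

    def test_unfittable_replicate_excluded_not_fatal(self, noiseless_curves):
        flat = ReleaseCurve(
            times=[1.0, 2.0, 3.0], fractions=[0.4, 0.4, 0.4], replicate_id="flat"
        )
        summary = fit_replicates(
            [noiseless_curves["sls"], flat], DEFAULT_RADIUS_M, FAST
        )
        assert summary.excluded == ("flat",)
        assert summary.n_replicates == 1

    def test_invalid_config_rejected(self):
        with pytest.raises(InvalidParameterError):
            FitConfig(population_size=2)
        with pytest.raises(InvalidParameterError):
            FitConfig(model_variant="nope")
        with pytest.raises(InvalidParameterError):
            FitConfig(log10_d_eff_bounds=(-10, -20))
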