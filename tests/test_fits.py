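"""Unit and property tests for the experiment curve fits."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import brentq

from parvodyn.fits import (
    fit_four_param_logistic,
    fit_four_param_logistic_per_replicate,
    fit_holling_type2,
    fit_yield_regression,
    fit_zoospore_mortality,
    growth_rate,
    growth_rate_series,
    holling2,
    infectivity_half_time,
    logistic4,
)
from parvodyn.types import DecayObservation, FitFailure

AGES = np.arange(0.0, 20.5, 1.0)


class TestFourParamLogistic:
    def test_noise_free_curve_recovered_to_machine_precision(self):
        y = logistic4(AGES, 100.0, 1.0, 5.0, 0.0)
        fit = fit_four_param_logistic(x=AGES, y=y)
        assert fit.upper_asymptote_a == pytest.approx(100.0, rel=1e-8)
        assert fit.slope_b == pytest.approx(1.0, rel=1e-8)
        assert fit.midpoint_c == pytest.approx(5.0, rel=1e-8)
        assert fit.lower_asymptote_d == pytest.approx(0.0, abs=1e-8)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_curve_at_midpoint_is_halfway_between_asymptotes(self):
        y = logistic4(AGES, 80.0, 1.2, 7.0, 5.0)
        fit = fit_four_param_logistic(x=AGES, y=y)
        mid = fit.predict(fit.midpoint_c)
        assert mid == pytest.approx(
            (fit.upper_asymptote_a + fit.lower_asymptote_d) / 2, rel=1e-9
        )

    @pytest.mark.parametrize("c_true", [5.31, 7.03, 8.93])
    def test_midpoint_recovered_from_noisy_replicates(self, c_true, rng):
        ages = np.tile(AGES, 3)
        y = np.clip(
            logistic4(ages, 80.0, 1.2, c_true, 0.0) + rng.normal(0, 4, ages.size),
            0, 100,
        )
        fit = fit_four_param_logistic(x=ages, y=y)
        assert fit.midpoint_c == pytest.approx(c_true, rel=0.10)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        a=st.floats(40, 100),
        b=st.floats(0.5, 3.0),
        c=st.floats(3.0, 15.0),
        d=st.floats(0.0, 10.0),
    )
    def test_half_time_matches_root_finder_oracle(self, a, b, c, d):
        """c is exactly the age where the fitted curve crosses (a+d)/2."""
        y = logistic4(AGES, a, b, c, d)
        fit = fit_four_param_logistic(x=AGES, y=y)
        half = (fit.upper_asymptote_a + fit.lower_asymptote_d) / 2
        root = brentq(lambda t: fit.predict(t) - half, 1e-6, 100.0)
        assert infectivity_half_time(fit) == pytest.approx(root, rel=1e-6)

    def test_accepts_observation_dataclasses(self):
        obs = [
            DecayObservation(zoospore_age=t, infection_pct=v, replicate=1)
            for t, v in zip(AGES, logistic4(AGES, 90.0, 1.0, 6.0, 0.0))
        ]
        fit = fit_four_param_logistic(obs)
        assert fit.midpoint_c == pytest.approx(6.0, rel=1e-6)

    def test_flat_data_fails_instead_of_inventing_a_midpoint(self):
        with pytest.raises(FitFailure):
            fit_four_param_logistic(x=AGES, y=np.full(AGES.size, 50.0))

    def test_too_few_distinct_ages_fails(self):
        with pytest.raises(FitFailure):
            fit_four_param_logistic(x=[0, 1, 2, 3], y=[90, 80, 40, 10])

    def test_per_replicate_fits_give_spread_of_midpoints(self, rng):
        obs = []
        for rep in (1, 2, 3):
            y = np.clip(
                logistic4(AGES, 80, 1.2, 7.0, 0.0) + rng.normal(0, 3, AGES.size),
                0, 100,
            )
            obs += [
                DecayObservation(zoospore_age=t, infection_pct=v, replicate=rep)
                for t, v in zip(AGES, y)
            ]
        fits = fit_four_param_logistic_per_replicate(obs)
        assert set(fits) == {1, 2, 3}
        cs = [f.midpoint_c for f in fits.values()]
        assert np.std(cs) < 1.0 and abs(np.mean(cs) - 7.0) < 0.5


class TestMortality:
    @pytest.mark.parametrize("m_true", [2.7, 4.68])
    def test_noise_free_rate_recovered_exactly(self, m_true):
        ages_h = np.arange(0.0, 20.1, 2.0)
        y = 100.0 * np.exp(-m_true * ages_h / 24.0)
        fit = fit_zoospore_mortality(x=ages_h, y=y)
        assert fit.mortality_m == pytest.approx(m_true, rel=1e-8)
        assert fit.initial_level == pytest.approx(100.0, rel=1e-8)

    def test_constant_series_gives_zero_mortality(self):
        fit = fit_zoospore_mortality(x=[0, 4, 8, 12], y=[70.0] * 4)
        assert fit.mortality_m == pytest.approx(0.0, abs=1e-8)

    def test_log_linear_oracle_agrees_on_noise_free_data(self):
        """OLS on log-percentages is the closed-form answer for exact data."""
        ages_h = np.arange(0.0, 20.1, 2.0)
        y = 85.0 * np.exp(-3.3 * ages_h / 24.0)
        fit = fit_zoospore_mortality(x=ages_h, y=y)
        slope, _ = np.polyfit(ages_h / 24.0, np.log(y), 1)
        assert fit.mortality_m == pytest.approx(-slope, abs=1e-8)

    def test_all_zero_series_fails(self):
        with pytest.raises(FitFailure):
            fit_zoospore_mortality(x=[0, 2, 4], y=[0.0, 0.0, 0.0])

    def test_increasing_series_fails(self):
        with pytest.raises(FitFailure):
            fit_zoospore_mortality(x=[0, 4, 8, 12, 16], y=[10, 20, 40, 60, 80])


class TestGrowthRate:
    def test_doubling_in_one_day_is_ln_two(self):
        assert growth_rate(500, 1000, 0, 1).mu == pytest.approx(np.log(2))

    def test_no_change_is_zero(self):
        assert growth_rate(500, 500, 0, 1).mu == 0.0

    def test_round_trip_of_configured_rate(self):
        assert growth_rate(500, 500 * np.exp(0.26), 2, 3).mu == pytest.approx(0.26)

    @pytest.mark.parametrize(
        "args", [(0, 100, 0, 1), (100, -5, 0, 1), (100, 100, 1, 1), (100, 100, 2, 1)]
    )
    def test_invalid_arguments_raise(self, args):
        with pytest.raises(ValueError):
            growth_rate(*args)

    def test_series_estimates_are_constant_for_exact_exponential(self):
        t = np.arange(8.0)
        n = 500 * np.exp(0.26 * t)
        mus = [g.mu for g in growth_rate_series(t, n)]
        assert np.allclose(mus, 0.26)


class TestHolling:
    RATIOS = np.array([1.0, 2.0, 3.5, 5.0, 10.0, 20.0, 50.0, 100.0])

    def test_noise_free_curve_recovered_exactly(self):
        y = holling2(self.RATIOS, 2.5, 0.38)
        fit = fit_holling_type2(x=self.RATIOS, y=y)
        assert fit.slope_a == pytest.approx(2.5, rel=1e-8)
        assert fit.handling_b == pytest.approx(0.38, rel=1e-8)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_attack_rate_conversion_to_daily(self):
        y = holling2(self.RATIOS, 50.0, 0.001)
        fit = fit_holling_type2(x=self.RATIOS, y=y, search_window_T=15.0)
        # a' = (a/100) * 24/T
        assert fit.attack_daily == pytest.approx(
            (fit.slope_a / 100.0) * 24.0 / 15.0, rel=1e-12
        )
        assert fit.attack_daily == pytest.approx(0.8, rel=1e-6)

    def test_attack_daily_scales_with_inverse_search_window(self):
        y = holling2(self.RATIOS, 10.0, 0.01)
        f15 = fit_holling_type2(x=self.RATIOS, y=y, search_window_T=15.0)
        f30 = fit_holling_type2(x=self.RATIOS, y=y, search_window_T=30.0)
        assert f30.attack_daily == pytest.approx(f15.attack_daily / 2, rel=1e-9)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(a=st.floats(0.5, 30.0), b=st.floats(1e-4, 0.05))
    def test_fitted_curve_monotone_and_bounded_by_inverse_b(self, a, b):
        y = holling2(self.RATIOS, a, b)
        fit = fit_holling_type2(x=self.RATIOS, y=y)
        grid = np.linspace(0.1, 1e4, 500)
        pred = fit.predict(grid)
        assert np.all(np.diff(pred) >= -1e-9)
        assert np.all(pred <= 1.0 / fit.handling_b + 1e-9)

    def test_too_few_ratios_fails(self):
        with pytest.raises(FitFailure):
            fit_holling_type2(x=[1, 2, 5], y=[2, 4, 9])

    def test_denominator_coefficient_exposes_other_convention(self):
        y = holling2(self.RATIOS, 4.0, 0.02)
        fit = fit_holling_type2(x=self.RATIOS, y=y)
        assert fit.denominator_coef == pytest.approx(4.0 * 0.02, rel=1e-8)


class TestYieldRegression:
    def test_collinear_points_recovered_exactly(self):
        d = np.array([10.0, 11.0, 12.5, 14.0])
        fit = fit_yield_regression(np.column_stack([d, 5.0 * d - 100.0]))
        assert fit.slope == pytest.approx(5.0, rel=1e-12)
        assert fit.intercept == pytest.approx(-100.0, rel=1e-9)
        assert fit.r_squared == pytest.approx(1.0)

    def test_predictions_clipped_at_zero_only_for_reporting(self):
        d = np.array([10.0, 11.0, 12.5, 14.0])
        fit = fit_yield_regression(np.column_stack([d, 5.0 * d - 100.0]))
        assert fit.predict(1.0) == 0.0
        assert fit.predict(1.0, clip=False) < 0.0

    def test_identical_diameters_fail(self):
        with pytest.raises(FitFailure):
            fit_yield_regression([(12.0, 100), (12.0, 110), (12.0, 90)])

    def test_too_few_points_fail(self):
        with pytest.raises(FitFailure):
            fit_yield_regression([(12.0, 100), (13.0, 110)])
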