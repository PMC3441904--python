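"""Control-limit constructions: worked values, oracle equivalence, invariants."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import poisson

from smrfunnel import (
    NominalLevel,
    TailRule,
    exact_limits,
    interpolated_prediction_limits,
    limits,
    prediction_limits,
    wald_limits,
)

LEVELS = (0.95, 0.998)


class TestNominalLevel:
    @pytest.mark.parametrize("level", LEVELS)
    def test_round_trip(self, level):
        lv = NominalLevel(level)
        assert lv.tail_prob == (1 - level) / 2
        assert 1 - lv.alpha == pytest.approx(level, abs=1e-15)

    @pytest.mark.parametrize("bad", [0.0, 1.0, -0.1, 1.5])
    def test_rejects_out_of_range(self, bad):
        with pytest.raises(ValueError):
            NominalLevel(bad)


class TestWald:
    def test_worked_value(self):
        pair = wald_limits(10, 0.95)
        assert pair.lower == pytest.approx(3.8020, abs=5e-5)
        assert pair.upper == pytest.approx(16.1980, abs=5e-5)

    def test_small_lam_lower_is_negative(self):
        assert wald_limits(1, 0.95).lower < 0

    def test_symmetric_about_lam(self):
        pair = wald_limits(100, 0.95)
        assert (pair.lower + pair.upper) / 2 == pytest.approx(100.0, abs=1e-10)

    def test_rejects_nonpositive_lam(self):
        for bad in (0.0, -3.0):
            with pytest.raises(ValueError):
                wald_limits(bad, 0.95)


class TestExact:
    def test_worked_value_lam_1(self):
        # chi-square with 2 df is Exp(2): quantile(0.025) = -2 ln(0.975)
        pair = exact_limits(1, 0.95)
        assert pair.lower == pytest.approx(-math.log(0.975), abs=1e-12)
        assert pair.lower == pytest.approx(0.02532, abs=5e-5)

    def test_lower_tail_mass_at_lam_1(self):
        # below the (positive) lower limit only X=0 fits: P = e^{-1}
        pair = exact_limits(1, 0.95)
        assert poisson.cdf(math.ceil(pair.lower) - 1, 1) == pytest.approx(
            math.exp(-1), abs=1e-12
        )

    @pytest.mark.parametrize("lam", [0.3, 1, 2.5, 10, 50, 1000])
    def test_lower_strictly_positive(self, lam):
        assert exact_limits(lam, 0.998).lower > 0

    def test_wider_than_wald(self):
        # both exact limits sit above the Wald ones at moderate lam
        e, w = exact_limits(50, 0.95), wald_limits(50, 0.95)
        assert e.lower > w.lower and e.upper > w.upper

    def test_non_integer_df_supported(self):
        pair = exact_limits(3.7, 0.95)
        assert 0 < pair.lower < 3.7 < pair.upper


def brute_force_prediction(lam, tail_prob):
    """Independent integer-scan oracle for the conservative limits."""
    xs = np.arange(0, int(np.ceil(lam + 20 * np.sqrt(lam))) + 2)
    cdf = poisson.cdf(xs, lam)
    lower = xs[np.argmax(cdf >= tail_prob)]
    sf_ge = poisson.sf(xs - 1, lam)  # P(X >= x)
    upper = xs[sf_ge >= tail_prob].max()
    return int(lower), int(upper)


class TestPrediction:
    def test_worked_values_lam_10(self):
        pair = prediction_limits(10, 0.95)
        assert (pair.lower, pair.upper) == (4, 17)
        # defining tail inequalities at the boundary integers
        assert poisson.sf(16, 10) == pytest.approx(0.027, abs=5e-4)
        assert poisson.sf(17, 10) == pytest.approx(0.014, abs=5e-4)

    def test_liberal_one_step_inward(self):
        # upper candidates at lam=10: 16 (tail 0.027 >= 0.025) vs 17 (0.014)
        cons = prediction_limits(10, 0.95, TailRule.CONSERVATIVE)
        lib = prediction_limits(10, 0.95, TailRule.LIBERAL)
        assert (lib.lower, lib.upper) == (cons.lower + 1, cons.upper - 1) == (5, 16)

    def test_asymmetric_rule(self):
        # FUNNELCOMPAR style: conservative below, liberal above
        asym = prediction_limits(10, 0.95, TailRule.ASYMMETRIC_FUNNELCOMPAR)
        assert (asym.lower, asym.upper) == (4, 16)

    @pytest.mark.parametrize("level", LEVELS)
    def test_liberal_tails_at_least_nominal(self, level):
        tail = (1 - level) / 2
        for lam in np.arange(2.0, 120.0, 3.7):
            pair = prediction_limits(lam, level, TailRule.LIBERAL)
            assert poisson.cdf(pair.lower - 1, lam) >= tail
            assert poisson.sf(pair.upper, lam) >= tail

    def test_liberal_empty_interval_rejected(self):
        # at lam=0.1 both inward steps cross: no liberal interval exists
        with pytest.raises(ValueError):
            prediction_limits(0.1, 0.95, TailRule.LIBERAL)

    @pytest.mark.parametrize("level", LEVELS)
    def test_matches_brute_force_oracle(self, level, lam_grid_small):
        tail = (1 - level) / 2
        grid = np.concatenate([lam_grid_small, np.arange(1.0, 201.0)])
        for lam in grid:
            pair = prediction_limits(lam, level)
            assert (pair.lower, pair.upper) == brute_force_prediction(lam, tail), lam

    @pytest.mark.parametrize("level", LEVELS)
    def test_conservative_tails_bounded(self, level, lam_grid_small):
        tail = (1 - level) / 2
        for lam in lam_grid_small:
            pair = prediction_limits(lam, level)
            assert poisson.cdf(pair.lower - 1, lam) <= tail
            assert poisson.sf(pair.upper, lam) <= tail


class TestInterpolated:
    def test_brackets_integer_limits(self):
        cons = prediction_limits(10, 0.95)
        smooth = interpolated_prediction_limits(10, 0.95)
        assert cons.upper <= smooth.upper < cons.upper + 1
        assert cons.lower - 1 < smooth.lower <= cons.lower

    def test_affine_in_tail_probability(self):
        smooth = interpolated_prediction_limits(10, 0.95)
        t17, t18 = poisson.sf(16, 10), poisson.sf(17, 10)  # P(X>=17), P(X>=18)
        weight = (0.025 - t18) / (t17 - t18)
        assert smooth.upper == pytest.approx(17 + weight, abs=1e-12)

    def test_monotone_in_lam(self):
        u10 = interpolated_prediction_limits(10, 0.95).upper
        u11 = interpolated_prediction_limits(11, 0.95).upper
        assert u10 < u11


class TestCrossMethod:
    @pytest.mark.parametrize("method", ["wald", "exact", "prediction"])
    @pytest.mark.parametrize("lam", [1, 7, 50, 300])
    def test_action_limits_wider_than_alarm(self, method, lam):
        alarm = limits(lam, method, 0.95)
        action = limits(lam, method, 0.998)
        assert action.lower <= alarm.lower and action.upper >= alarm.upper
        assert (action.upper - action.lower) > (alarm.upper - alarm.lower)

    @pytest.mark.parametrize("lam", range(1, 51))
    def test_exact_upper_dominates_others(self, lam):
        e = exact_limits(lam, 0.95).upper
        assert e >= prediction_limits(lam, 0.95).upper
        assert e >= wald_limits(lam, 0.95).upper

    def test_methods_converge_at_large_lam(self):
        lam = 10_000
        for level in LEVELS:
            w = wald_limits(lam, level)
            e = exact_limits(lam, level)
            p = prediction_limits(lam, level)
            for other in (e, p):
                assert abs(w.lower - other.lower) < 1e-3 * lam
                assert abs(w.upper - other.upper) < 1e-3 * lam

    @given(
        lam=st.floats(min_value=0.1, max_value=500.0),
        level=st.sampled_from(LEVELS),
    )
    @settings(max_examples=150, deadline=None, derandomize=True)
    def test_limit_pair_sanity(self, lam, level):
        tail = (1 - level) / 2
        pair = prediction_limits(lam, level)
        assert pair.lower == int(pair.lower) and pair.upper == int(pair.upper)
        assert 0 <= pair.lower <= pair.upper
        assert poisson.cdf(pair.lower, lam) >= tail          # defining property of L
        assert poisson.sf(pair.upper - 1, lam) >= tail       # defining property of U
        assert exact_limits(lam, level).lower > 0
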