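"""Time-course construction, rate-law linearization, and kinetic fitting."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from stabkin import (
    KineticModel,
    KineticTruth,
    TimeCourse,
    fit_kinetics,
    half_life,
    linearize,
    percent_remaining,
    rate_constant_from_slope,
    select_order,
    simulate_timecourse,
)
from stabkin.exceptions import InsufficientDesignError, InvalidInputError

T_GRID = np.array([0.0, 12.0, 24.0, 48.0, 72.0])


def exp_course(k, times=T_GRID, c0=100.0, **kw):
    return TimeCourse("test", 90.0, np.asarray(times, float),
                      c0 * np.exp(-k * np.asarray(times, float)), **kw)


class TestPercentRemaining:
    def test_constant_areas_give_100(self):
        tc = percent_remaining([(0, 500.0), (1, 500.0), (2, 500.0)], 500.0)
        assert np.allclose(tc.percent_remaining, 100.0)

    def test_scale_invariance(self):
        pairs = [(0, 400.0), (2, 300.0), (4, 220.0)]
        halved = [(t, a / 2) for t, a in pairs]
        tc1 = percent_remaining(pairs, 400.0)
        tc2 = percent_remaining(halved, 200.0)
        assert np.allclose(tc1.percent_remaining, tc2.percent_remaining)

    def test_c0_is_100_by_construction(self):
        tc = percent_remaining([(0, 412.0), (5, 300.0)], 412.0)
        assert tc.percent_remaining[0] == pytest.approx(100.0)

    def test_nonpositive_reference_rejected(self):
        with pytest.raises(InvalidInputError):
            percent_remaining([(0, 1.0)], 0.0)

    def test_nonpositive_area_excluded_with_warning(self, caplog):
        with caplog.at_level("WARNING", logger="stabkin.kinetics"):
            tc = percent_remaining([(0, 400.0), (2, -1.0), (4, 200.0)], 400.0)
        assert len(tc) == 2
        assert "excluded 1" in caplog.text

    def test_nonzero_first_time_rejected(self):
        with pytest.raises(InvalidInputError):
            percent_remaining([(1.0, 400.0), (2.0, 300.0)], 400.0)


class TestTimeCourse:
    def test_times_must_increase(self):
        with pytest.raises(InvalidInputError):
            TimeCourse("x", 70.0, np.array([0.0, 2.0, 2.0]), np.array([100.0, 90, 80]))

    def test_negative_times_rejected(self):
        with pytest.raises(InvalidInputError):
            TimeCourse("x", 70.0, np.array([-1.0, 0.0]), np.array([100.0, 90]))


class TestLinearize:
    def test_log10_values(self):
        tc = TimeCourse("x", 70.0, np.array([0.0, 1.0]), np.array([100.0, 50.0]))
        _, y = linearize(tc, "first")
        assert y[0] == pytest.approx(2.0, abs=1e-14)
        assert y[1] == pytest.approx(math.log10(50.0), abs=1e-14)  # ~1.69897

    def test_second_order_is_reciprocal(self):
        tc = TimeCourse("x", 70.0, np.array([0.0, 1.0]), np.array([100.0, 40.0]))
        _, y = linearize(tc, "second")
        assert np.allclose(y, [0.01, 0.025])

    def test_exact_decay_is_exactly_linear(self):
        tc = exp_course(0.0622)
        t, y = linearize(tc, "first")
        resid = y - np.polyval(np.polyfit(t, y, 1), t)
        assert np.max(np.abs(resid)) <= 1e-12

    def test_points_below_floor_excluded(self, caplog):
        tc = exp_course(0.2, times=[0, 10, 20, 30, 40])  # last points < 1%
        with caplog.at_level("WARNING", logger="stabkin.kinetics"):
            t, _ = linearize(tc, "first", min_percent=1.0)
        assert t.size == 3
        assert "excluded 2" in caplog.text


class TestRateConstantAndHalfLife:
    @pytest.mark.parametrize(
        "slope,expected",
        [(-0.027, 0.0622), (-0.301, 0.6931), (0.0, 0.0)],
    )
    def test_first_order_slope_conversion(self, slope, expected):
        assert rate_constant_from_slope(slope, "first") == pytest.approx(
            expected, abs=5e-5)

    def test_other_orders(self):
        assert rate_constant_from_slope(-0.5, "zero") == 0.5
        assert rate_constant_from_slope(0.5, "second") == 0.5

    @pytest.mark.parametrize("k,expected", [(0.005, 138.6), (0.942, 44.1 / 60.0)])
    def test_first_order_half_life(self, k, expected):
        assert half_life(k, "first") == pytest.approx(expected, abs=0.05)

    def test_half_life_definitions(self):
        assert half_life(math.log(2.0), "first") == pytest.approx(1.0, rel=1e-12)
        assert half_life(1.0, "zero", c0=100.0) == pytest.approx(50.0)
        assert half_life(0.01, "second", c0=100.0) == pytest.approx(1.0)

    def test_nonpositive_k_gives_nan(self):
        assert math.isnan(half_life(0.0, "first"))
        assert math.isnan(half_life(-0.1, "first"))


class TestKineticFit:
    def test_noise_free_reconstruction_of_hot_acid_row(self):
        res = fit_kinetics(exp_course(0.0622))
        assert res.slope == pytest.approx(-0.0622 / math.log(10), rel=1e-10)  # -0.02701
        assert res.intercept == pytest.approx(2.0, abs=1e-12)
        assert res.r_squared == pytest.approx(1.0, abs=1e-12)
        assert res.k == pytest.approx(0.0622, rel=1e-10)
        assert res.t_half == pytest.approx(11.14, abs=0.01)
        # display rounding matches the reporting convention
        assert round(res.k, 3) == 0.062
        assert round(res.t_half, 1) == 11.1
        assert res.equation() == "y = -0.027x + 2.000"

    @given(st.floats(min_value=1e-3, max_value=2.0))
    def test_round_trip_recovers_rate_exactly(self, k):
        times = np.linspace(0.0, 2.0 * math.log(2.0) / k, 6)
        tc = simulate_timecourse(KineticTruth(model="first", k=k), times)
        res = fit_kinetics(tc)
        assert res.k == pytest.approx(k, rel=1e-9)
        assert res.r_squared == pytest.approx(1.0, abs=1e-9)

    def test_k_times_half_life_is_ln2(self):
        for k in (0.005, 0.062, 0.942):
            res = fit_kinetics(exp_course(k, times=np.linspace(0, math.log(2) / k, 5)))
            assert res.k * res.t_half == pytest.approx(math.log(2.0), rel=1e-12)

    def test_k_invariant_to_percent_rescaling(self):
        tc = exp_course(0.03)
        r1 = fit_kinetics(tc)
        r2 = fit_kinetics(tc.rescaled(0.5))
        assert r2.k == pytest.approx(r1.k, rel=1e-12)
        assert r2.intercept == pytest.approx(r1.intercept + math.log10(0.5), abs=1e-12)

    def test_constant_series_flagged_non_degrading(self):
        tc = TimeCourse("x", 70.0, T_GRID, np.full(5, 100.0))
        res = fit_kinetics(tc)
        assert not res.degrading
        assert res.k == 0.0
        assert math.isnan(res.t_half)

    def test_noisy_series_recovers_k_within_tolerance(self):
        k = 0.0622
        times = np.linspace(0.0, 2.0 * math.log(2.0) / k, 10)
        errs = []
        for seed in range(40):
            tc = simulate_timecourse(KineticTruth(model="first", k=k), times,
                                     noise_cv=0.01, seed=seed)
            errs.append(abs(fit_kinetics(tc).k - k) / k)
        assert np.median(errs) <= 0.03

    def test_too_few_points_rejected(self):
        tc = TimeCourse("x", 70.0, np.array([0.0, 1.0]), np.array([100.0, 90.0]))
        with pytest.raises(InsufficientDesignError):
            fit_kinetics(tc)

    def test_low_percent_points_excluded_from_fit(self):
        tc = exp_course(0.2, times=[0, 5, 10, 15, 30, 45])
        res = fit_kinetics(tc)
        assert res.n_excluded == 2
        assert res.n_points == 4
        assert res.k == pytest.approx(0.2, rel=1e-9)

    def test_half_life_display_units(self):
        res = fit_kinetics(exp_course(math.log(2.0), times=[0.0, 0.5, 1.0, 1.5, 2.0]))
        assert res.t_half_display("h") == pytest.approx(1.0, rel=1e-9)
        assert res.t_half_display("min") == pytest.approx(60.0, rel=1e-9)


class TestOrderSelection:
    def test_exact_exponential_selects_first(self):
        tc = exp_course(0.0622)  # spans ~4.5 half-lives
        best, fits = select_order(tc)
        assert best == "first"
        assert set(fits) == {"zero", "first", "second"}

    def test_exact_linear_selects_zero(self):
        t = np.array([0.0, 10, 20, 30, 40])
        tc = TimeCourse("x", 70.0, t, 100.0 - 1.5 * t)
        best, _ = select_order(tc)
        assert best == "zero"

    def test_exact_second_order_selects_second(self):
        t = np.array([0.0, 10, 20, 40, 80])
        tc = TimeCourse("x", 70.0, t, 1.0 / (0.01 + 0.002 * t))
        best, _ = select_order(tc)
        assert best == "second"

    def test_needs_four_points(self):
        tc = TimeCourse("x", 70.0, np.array([0.0, 1, 2]), np.array([100.0, 90, 81]))
        with pytest.raises(InsufficientDesignError):
            select_order(tc)

    def test_non_degrading_series_yields_no_model(self):
        tc = TimeCourse("x", 70.0, T_GRID, np.full(5, 100.0))
        best, _ = select_order(tc)
        assert best is None
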