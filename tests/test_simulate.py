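"""Synthetic-data generator: determinism, exactness at zero noise, clamping."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from stabkin import (
    KineticTruth,
    PeakShape,
    ResponseTruth,
    simulate_calibration,
    simulate_peak,
    simulate_stress_panel,
    simulate_timecourse,
)
from stabkin.arrhenius import R_GAS
from stabkin.exceptions import InvalidInputError
from stabkin.simulate import CLAMP_FLOOR_PCT

LEVELS = [1.0, 2.0, 5.0, 10.0, 15.0, 20.0]


class TestCalibrationTables:
    def test_noise_free_areas_lie_on_the_line(self):
        table = simulate_calibration(ResponseTruth(noise_cv=0.0), LEVELS)
        on_line = 39.49 * table["conc_ugml"] - 8.39
        assert np.allclose(table["area"], on_line, atol=1e-12)
        assert float(table.loc[table["conc_ugml"] == 10.0, "area"].iloc[0]) == pytest.approx(386.51)

    def test_identity_response(self):
        table = simulate_calibration(ResponseTruth(1.0, 0.0, 0.0), [5.0])
        assert float(table["area"].iloc[0]) == pytest.approx(5.0)

    def test_fixed_seed_reproduces_table_bitwise(self):
        t1 = simulate_calibration(ResponseTruth(seed=42), LEVELS, replicates=6, days=3)
        t2 = simulate_calibration(ResponseTruth(seed=42), LEVELS, replicates=6, days=3)
        pd.testing.assert_frame_equal(t1, t2)
        t3 = simulate_calibration(ResponseTruth(seed=43), LEVELS, replicates=6, days=3)
        assert not np.allclose(t1["area"], t3["area"])

    def test_design_shape(self):
        table = simulate_calibration(ResponseTruth(), LEVELS, replicates=2, days=3)
        assert len(table) == 6 * 2 * 3
        assert list(table.columns) == ["day", "replicate", "conc_ugml", "area"]

    def test_nonpositive_level_rejected(self):
        with pytest.raises(InvalidInputError):
            simulate_calibration(ResponseTruth(), [1.0, -2.0])

    def test_truth_invariants(self):
        with pytest.raises(InvalidInputError):
            ResponseTruth(slope=-1.0)
        with pytest.raises(InvalidInputError):
            ResponseTruth(noise_cv=-0.1)


class TestTimecourses:
    def test_one_half_life_reaches_50_percent(self):
        # k = 0.0622/h puts one half-life at ln2/k = 11.14 h
        t_half = math.log(2.0) / 0.0622
        assert t_half == pytest.approx(11.14, abs=5e-3)
        tc = simulate_timecourse(KineticTruth(model="first", k=0.0622),
                                 [0.0, t_half], noise_cv=0.0)
        assert tc.percent_remaining[1] == pytest.approx(50.0, abs=1e-9)

    def test_zero_rate_stays_at_100(self):
        tc = simulate_timecourse(KineticTruth(model="first", k=0.0), [0.0, 10.0, 100.0])
        assert np.all(tc.percent_remaining == 100.0)

    def test_zero_order_is_linear_and_floored(self):
        tc = simulate_timecourse(KineticTruth(model="zero", k=2.0), [0.0, 10.0, 60.0])
        assert tc.percent_remaining[1] == pytest.approx(80.0)
        assert tc.percent_remaining[2] == CLAMP_FLOOR_PCT  # 100 - 120 floored, then clamped
        assert tc.n_clamped == 1

    def test_second_order_reciprocal_is_linear(self):
        tc = simulate_timecourse(KineticTruth(model="second", k=0.001), [0.0, 5.0, 10.0])
        recip = 1.0 / tc.percent_remaining
        assert np.allclose(np.diff(recip, 2), 0.0, atol=1e-15)

    @given(st.floats(min_value=0.01, max_value=1.0))
    def test_noise_free_log_is_exactly_linear(self, k):
        tc = simulate_timecourse(KineticTruth(model="first", k=k),
                                 np.linspace(0, math.log(2) / k, 8))
        y = np.log10(tc.percent_remaining)
        resid = y - np.polyval(np.polyfit(tc.times_h, y, 1), tc.times_h)
        assert np.max(np.abs(resid)) <= 1e-12

    def test_deep_decay_clamped_and_counted(self):
        tc = simulate_timecourse(KineticTruth(model="first", k=1.0), [0.0, 5.0, 20.0])
        assert tc.percent_remaining[2] == CLAMP_FLOOR_PCT
        assert tc.n_clamped >= 1

    def test_arrhenius_form_resolves_rate(self):
        ea, lna, temp = 50_000.0, 12.0, 80.0
        truth = KineticTruth(model="first", Ea=ea, lnA=lna, temperature_c=temp)
        expected = math.exp(lna - ea / (R_GAS * (temp + 273.15)))
        assert truth.rate == pytest.approx(expected, rel=1e-15)

    def test_exactly_one_rate_source_required(self):
        with pytest.raises(InvalidInputError):
            KineticTruth(model="first", k=0.1, Ea=1.0, lnA=1.0, temperature_c=70.0)
        with pytest.raises(InvalidInputError):
            KineticTruth(model="first", Ea=1.0, lnA=1.0)  # temperature missing
        with pytest.raises(InvalidInputError):
            KineticTruth(model="first")

    def test_negative_time_rejected(self):
        with pytest.raises(InvalidInputError):
            simulate_timecourse(KineticTruth(model="first", k=0.1), [-1.0, 0.0])

    def test_seeded_noise_is_reproducible(self):
        kw = dict(noise_cv=0.01, seed=9)
        a = simulate_timecourse(KineticTruth(model="first", k=0.1), [0, 1, 2, 4], **kw)
        b = simulate_timecourse(KineticTruth(model="first", k=0.1), [0, 1, 2, 4], **kw)
        assert np.array_equal(a.percent_remaining, b.percent_remaining)


class TestStressPanels:
    TRUTHS = {t: KineticTruth(model="first", k=k)
              for t, k in {70.0: 0.005, 80.0: 0.014, 85.0: 0.030, 90.0: 0.062}.items()}

    def test_panel_is_deterministic_and_tagged(self):
        times = {t: list(np.linspace(0, 2 * math.log(2) / tr.k, 6))
                 for t, tr in self.TRUTHS.items()}
        p1 = simulate_stress_panel(self.TRUTHS, times, noise_cv=0.01, seed=5,
                                   condition="2 M HCl")
        p2 = simulate_stress_panel(self.TRUTHS, times, noise_cv=0.01, seed=5,
                                   condition="2 M HCl")
        assert [tc.temperature_c for tc in p1] == [70.0, 80.0, 85.0, 90.0]
        assert all(tc.condition == "2 M HCl" for tc in p1)
        for a, b in zip(p1, p2):
            assert np.array_equal(a.percent_remaining, b.percent_remaining)

    def test_single_temperature_rejected(self):
        with pytest.raises(InvalidInputError):
            simulate_stress_panel({70.0: self.TRUTHS[70.0]}, [0, 1, 2])

    def test_temperature_streams_are_independent(self):
        # same seed, different temperature subsets: shared temps keep their draws
        times = [0.0, 10.0, 20.0, 40.0]
        full = simulate_stress_panel(self.TRUTHS, times, noise_cv=0.01, seed=11)
        sub = simulate_stress_panel(
            {70.0: self.TRUTHS[70.0], 80.0: self.TRUTHS[80.0]},
            times, noise_cv=0.01, seed=11)
        assert np.array_equal(full[0].percent_remaining, sub[0].percent_remaining)
        assert np.array_equal(full[1].percent_remaining, sub[1].percent_remaining)


class TestPeaks:
    def test_gaussian_widths_closed_form(self):
        sigma = 0.0845
        d = simulate_peak(PeakShape(5.0, sigma, 1.0))
        assert d.width_at_half_height == pytest.approx(2 * math.sqrt(2 * math.log(2)) * sigma)
        assert d.width_at_5pct_height == pytest.approx(2 * math.sqrt(2 * math.log(20)) * sigma)
        assert d.leading_half_width_at_5pct == pytest.approx(d.width_at_5pct_height / 2)

    def test_invalid_shape_rejected(self):
        with pytest.raises(InvalidInputError):
            PeakShape(sigma=-0.1)
        with pytest.raises(InvalidInputError):
            PeakShape(retention_time=0.0)
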