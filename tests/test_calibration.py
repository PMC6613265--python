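"""Calibration curves, linearity diagnostics, matrix inhibition, inference."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from lucikit import (
    DilutionSeries,
    NoiseModel,
    fit_calibration,
    fraction_remaining,
    generate_dilution_series,
    infer_amount,
    linearity_report,
    matrix_inhibition,
)


def ideal_ladder(n=6, fold=10.0, top=0.1, gain=1e8, slope=1.0):
    return generate_dilution_series(top, fold, n, response_slope=slope, gain_cps=gain)


class TestFitCalibration:
    def test_ideal_ladder_has_unit_slope_and_perfect_fit(self):
        curve = fit_calibration(ideal_ladder())
        assert curve.log10_slope == pytest.approx(1.0, abs=1e-12)
        assert curve.r_squared == pytest.approx(1.0, abs=1e-12)
        assert curve.n_points_used == 6
        assert not curve.low_n

    def test_two_points_fit_exactly_and_flag_low_n(self):
        curve = fit_calibration(ideal_ladder(n=2))
        assert curve.r_squared == pytest.approx(1.0)
        assert curve.low_n

    def test_saturated_top_point_excluded_then_slope_recovered(self):
        clean = ideal_ladder(slope=0.95)
        ceiling = clean.signal[0] * 0.5  # clips only the top point
        clipped = generate_dilution_series(
            0.1, 10, 6, response_slope=0.95, saturation_ceiling=ceiling
        )
        curve = fit_calibration(clipped)
        assert curve.n_points_used == 5
        assert curve.log10_slope == pytest.approx(0.95, abs=1e-10)
        assert curve.linear_range[1] == pytest.approx(clean.dilution_factors[1])

    def test_all_points_unusable_raises_with_cause(self):
        series = DilutionSeries(np.array([0.1, 0.01]), np.array([0.0, 0.0]))
        with pytest.raises(ValueError, match="zero-signal"):
            fit_calibration(series)
        sat = DilutionSeries(np.array([0.1, 0.01]), np.array([5e6, 5e6]), saturation_ceiling=1e6)
        with pytest.raises(ValueError, match="saturated"):
            fit_calibration(sat)


class TestLinearityReport:
    def test_ideal_ladder_has_zero_deviation(self):
        rep = linearity_report(ideal_ladder())
        assert np.allclose(rep["signal_ratio"], 10.0)
        assert np.nanmax(rep["deviation"].to_numpy()) == pytest.approx(0.0, abs=1e-12)

    def test_sub_linear_ladder_deviation_is_closed_form(self):
        rep = linearity_report(ideal_ladder(slope=0.9))
        assert np.allclose(rep["signal_ratio"], 10.0**0.9)
        assert np.allclose(rep["deviation"], abs(10.0**0.9 - 10.0) / 10.0)

    def test_single_outlier_flags_exactly_two_steps(self):
        series = ideal_ladder()
        signal = series.signal.copy()
        signal[2] *= 1.5
        rep = linearity_report(DilutionSeries(series.dilution_factors, signal))
        flagged = rep["deviation"] > 1e-9
        assert flagged.sum() == 2
        assert list(rep.loc[flagged, "step"]) == [2, 3]

    def test_zero_denominator_marked_undefined_not_fatal(self):
        series = DilutionSeries(np.array([0.1, 0.01, 0.001]), np.array([100.0, 0.0, 1.0]))
        rep = linearity_report(series)
        assert bool(rep["undefined"].iloc[0])
        assert np.isnan(rep["signal_ratio"].iloc[0])
        assert not rep["undefined"].iloc[1]


class TestMatrixInhibition:
    def test_identical_series_ratio_one(self):
        s = ideal_ladder()
        assert matrix_inhibition(s, s) == pytest.approx(1.0)

    def test_ten_percent_lower_extract(self):
        buf = ideal_ladder()
        ext = DilutionSeries(buf.dilution_factors, buf.signal * 0.9, matrix_label="plant_extract")
        assert matrix_inhibition(ext, buf) == pytest.approx(0.9)

    def test_no_matched_dilution_raises(self):
        buf = ideal_ladder()
        ext = DilutionSeries(np.array([0.05, 0.005]), np.array([1e6, 1e5]))
        with pytest.raises(ValueError, match="matched"):
            matrix_inhibition(ext, buf)

    def test_monte_carlo_recovers_generating_inhibition(self):
        """Inhibition 0.85 generated with cv = 0.02: mean ratio in [0.83, 0.87]."""
        noise = NoiseModel(multiplicative_cv=0.02, counting=False)
        ratios = []
        for seed in range(100):
            buf = generate_dilution_series(0.1, 10, 6, noise=noise, seed=2 * seed)
            ext = generate_dilution_series(
                0.1, 10, 6, noise=noise, seed=2 * seed + 1,
                matrix_label="plant_extract", inhibition=0.85,
            )
            ratios.append(matrix_inhibition(ext, buf))
        assert 0.83 < np.mean(ratios) < 0.87


class TestInferAmount:
    def test_inverting_a_calibration_point_returns_its_concentration(self):
        series = ideal_ladder()
        curve = fit_calibration(series)
        for f, s in zip(series.dilution_factors, series.signal):
            got = infer_amount(s, curve)
            assert got.concentration == pytest.approx(f, rel=1e-10)
            assert not got.extrapolated

    def test_tenfold_signal_means_tenfold_concentration(self):
        curve = fit_calibration(ideal_ladder())
        c1 = infer_amount(1e5, curve).concentration
        c10 = infer_amount(1e6, curve).concentration
        assert c10 / c1 == pytest.approx(10.0, rel=1e-10)

    def test_aged_calibrator_scales_inference_down(self):
        curve = fit_calibration(ideal_ladder())
        rate = 0.01
        age = math.log(2) / rate  # one half-life
        fresh = infer_amount(1e5, curve).concentration
        aged = infer_amount(1e5, curve, calibrator_age_h=age, calibrator_decay_rate=rate)
        assert aged.concentration == pytest.approx(fresh / 2.0, rel=1e-10)

    def test_end_to_end_aged_calibrator_recovery(self):
        """Ladder measured with a week-old calibrator still recovers the truth.

        The calibrator has lost activity, so every ladder signal is reduced
        by the remaining fraction; a fresh unknown read against that curve
        over-reports until the age correction is applied.
        """
        rate = math.log(2) / 892.8
        age = 168.0
        f = fraction_remaining(rate, age)
        gain = 1e8
        aged_ladder = generate_dilution_series(0.1, 10, 6, gain_cps=gain * f)
        curve = fit_calibration(aged_ladder)
        true_conc = 0.004
        unknown_signal = gain * true_conc  # fresh extract, full activity
        uncorrected = infer_amount(unknown_signal, curve).concentration
        corrected = infer_amount(
            unknown_signal, curve, calibrator_age_h=age, calibrator_decay_rate=rate
        ).concentration
        assert uncorrected > true_conc  # over-estimation without correction
        assert corrected == pytest.approx(true_conc, rel=1e-10)

    def test_extrapolation_flagged_and_bad_signal_rejected(self):
        curve = fit_calibration(ideal_ladder())
        assert infer_amount(curve.signal_range[1] * 100, curve).extrapolated
        with pytest.raises(ValueError):
            infer_amount(0.0, curve)

    @given(s1=st.floats(1e2, 1e7), s2=st.floats(1e2, 1e7))
    def test_inference_is_monotone_in_signal(self, s1, s2):
        curve = fit_calibration(ideal_ladder())
        c1 = infer_amount(s1, curve).concentration
        c2 = infer_amount(s2, curve).concentration
        assert (s1 <= s2) == (c1 <= c2)
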