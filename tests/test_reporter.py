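"""Forced linear ODE reporter model: forcing, simulation, steady state, fitting."""

import math
from dataclasses import replace

import numpy as np
import pytest
from scipy.special import i0

from lucikit import (
    NoiseModel,
    ReporterParams,
    derived_half_lives,
    fit_model,
    forcing,
    periodic_steady_state,
    simulate,
    table1_params,
)
from ._oracles import integrating_factor_solution

OMEGA = 2 * math.pi / 25.0


class TestForcing:
    def test_value_at_forcing_maximum_is_k1_times_e(self, table1):
        # sin(.) = 1 at t with 2*pi*t/25 + 10 = pi/2 (mod 2*pi)
        t_max = (math.pi / 2 - 10 + 4 * math.pi) * 25 / (2 * math.pi)
        assert forcing(t_max, table1) == pytest.approx(50 * math.e, rel=1e-12)  # 135.91

    def test_value_at_time_zero(self, table1):
        assert forcing(0.0, table1) == pytest.approx(50 * math.exp(math.sin(10.0)), rel=1e-12)  # 29.02

    def test_periodic_with_forcing_period(self, table1):
        t = np.linspace(0, 50, 101)
        assert np.allclose(forcing(t, table1), forcing(t + 25.0, table1), rtol=1e-12)
        assert np.all(forcing(t, table1) > 0)


class TestSimulate:
    def test_homogeneous_solution_without_translation(self):
        p = ReporterParams(k1=0.0, k2=0.08, k3=0.0121, k4=0.15)
        t = np.linspace(0, 50, 26)
        tr = simulate(p, t, initial_cBNL=100.0, initial_cBFLUC=100.0)
        assert np.allclose(tr.cBNL, 100 * np.exp(-(0.08 + 0.0121) * t), rtol=1e-7)
        assert np.allclose(tr.cBFLUC, 100 * np.exp(-(0.08 + 0.15) * t), rtol=1e-7)

    def test_constant_forcing_reaches_fixed_point(self, table1):
        f0 = 40.0
        t = np.linspace(0, 400, 81)
        tr = simulate(table1, t, initial_cBNL=0.0, initial_cBFLUC=0.0, forcing_fn=lambda s: f0)
        assert tr.cBFLUC[-1] == pytest.approx(f0 / table1.delta("FLUC"), rel=1e-6)
        assert tr.cBNL[-1] == pytest.approx(f0 / table1.delta("NL"), rel=1e-4)

    def test_period_average_matches_bessel_identity(self, table1):
        """Mean of the periodic FLUC state is k1 I0(1) / (k2 + k4) = 275.2."""
        ps = periodic_steady_state(table1, "FLUC")
        assert ps.mean == pytest.approx(50 * i0(1.0) / 0.23, rel=1e-6)
        assert ps.mean == pytest.approx(275.2, abs=0.1)

    def test_matches_integrating_factor_quadrature_oracle(self, table1):
        times = np.linspace(0, 100, 41)
        tr = simulate(table1, times, initial_cBNL=0.0, initial_cBFLUC=0.0)
        for reporter, got in (("NL", tr.cBNL), ("FLUC", tr.cBFLUC)):
            want = integrating_factor_solution(table1, reporter, times)
            rel = np.abs(got[1:] - want[1:]) / np.abs(want[1:])
            assert rel.max() < 1e-6

    def test_zero_start_response_is_linear_in_k1(self, table1):
        t = np.linspace(0, 60, 31)
        a = simulate(table1, t, initial_cBNL=0.0, initial_cBFLUC=0.0)
        b = simulate(replace(table1, k1=100.0), t, initial_cBNL=0.0, initial_cBFLUC=0.0)
        assert np.allclose(b.cBNL, 2 * a.cBNL, rtol=1e-7)

    def test_equal_reporter_decay_rates_give_identical_channels(self):
        p = ReporterParams(k3=0.05, k4=0.05, a=0.0)
        t = np.linspace(0, 75, 151)
        tr = simulate(p, t)
        assert np.allclose(tr.cBNL, tr.cBFLUC, rtol=1e-9)
        assert np.allclose(tr.observed_NL, tr.observed_FLUC, rtol=1e-9)

    def test_substrate_depletion_damps_only_observed_nl(self, table1, half_hour_grid):
        tr = simulate(table1, half_hour_grid)
        assert np.allclose(tr.observed_NL, tr.cBNL * np.exp(-0.004 * half_hour_grid))
        assert np.array_equal(tr.observed_FLUC, tr.cBFLUC)

    def test_decreasing_grid_rejected(self, table1):
        with pytest.raises(ValueError):
            simulate(table1, np.array([0.0, 2.0, 1.0]))


class TestPeriodicSteadyState:
    def test_trace_repeats_with_forcing_period(self, table1):
        ps = periodic_steady_state(table1, "NL")
        tr = simulate(table1, ps.times_h + 25.0, initial_cBNL=ps.values[0], initial_cBFLUC=0.0)
        assert np.allclose(tr.cBNL, ps.values, rtol=1e-6)

    def test_first_harmonic_gain_is_first_order_filter(self, table1):
        """Relative amplitude transfer equals delta / sqrt(delta^2 + omega^2)."""
        forcing_relamp = None
        for reporter, delta in (("FLUC", 0.23), ("NL", 0.0921)):
            ps = periodic_steady_state(table1, reporter)
            v = ps.values[:-1]  # drop duplicated endpoint of the period
            coef = np.fft.rfft(v) / v.size
            relamp = 2 * abs(coef[1]) / coef[0].real
            if forcing_relamp is None:
                f = forcing(ps.times_h[:-1], table1)
                cf = np.fft.rfft(f) / f.size
                forcing_relamp = 2 * abs(cf[1]) / cf[0].real
            gain = delta / math.hypot(delta, OMEGA)
            assert relamp / forcing_relamp == pytest.approx(gain, rel=1e-6)
        assert 0.23 / math.hypot(0.23, OMEGA) == pytest.approx(0.675, abs=5e-4)
        assert 0.0921 / math.hypot(0.0921, OMEGA) == pytest.approx(0.344, abs=5e-4)

    def test_zero_decay_has_no_attractor(self):
        p = ReporterParams(k2=0.0, k3=0.0)
        with pytest.raises(ValueError):
            periodic_steady_state(p, "NL")


class TestFitModel:
    def test_noiseless_recovery_from_doubled_start(self, table1, half_hour_grid):
        truth = simulate(table1, half_hour_grid)
        start = replace(table1, k1=100.0, k2=0.16, k4=0.30)  # x2 perturbation, k3 fixed
        fit = fit_model(half_hour_grid, truth.observed_NL, truth.observed_FLUC, start)
        assert fit.converged
        assert fit.params.k1 == pytest.approx(50.0, rel=0.01)
        assert fit.params.k2 == pytest.approx(0.08, rel=0.01)
        assert fit.params.k4 == pytest.approx(0.15, rel=0.01)
        assert not fit.degenerate

    def test_single_channel_flags_decay_rate_degeneracy(self, table1, half_hour_grid):
        truth = simulate(table1, half_hour_grid)
        start = replace(table1, k2=0.1, k3=0.02)
        fit = fit_model(half_hour_grid, truth.observed_NL, None, start, free=("k2", "k3"))
        assert ("k2", "k3") in fit.degenerate_pairs
        start2 = replace(table1, k2=0.1, k4=0.2)
        fit2 = fit_model(half_hour_grid, None, truth.observed_FLUC, start2, free=("k2", "k4"))
        assert ("k2", "k4") in fit2.degenerate_pairs
        # the identifiable sum is still recovered
        assert fit2.params.k2 + fit2.params.k4 == pytest.approx(0.23, rel=1e-3)

    def test_non_finite_signal_rejected(self, table1, half_hour_grid):
        bad = np.full_like(half_hour_grid, np.nan)
        with pytest.raises(ValueError, match="non-finite"):
            fit_model(half_hour_grid, bad, None, table1)


class TestDerivedHalfLives:
    def test_reference_rates_map_to_reported_half_lives(self, table1):
        hl = derived_half_lives(table1)
        assert hl["BOA"] == pytest.approx(8.66, abs=0.01)
        assert hl["NL_activity"] == pytest.approx(57.3, abs=0.05)
        assert hl["FLUC_activity"] == pytest.approx(4.62, abs=0.01)

    def test_zero_rate_reports_infinite_half_life(self):
        hl = derived_half_lives(ReporterParams(k2=0.0))
        assert math.isinf(hl["BOA"])


def test_table1_loader_logs_k2_discrepancy(caplog):
    import logging

    with caplog.at_level(logging.INFO, logger="lucikit.reporter"):
        p = table1_params()
        q = table1_params(use_printed_k2=True)
    assert p.k2 == 0.08 and q.k2 == 0.8
    assert any("0.08" in r.message or "0.8" in r.getMessage() for r in caplog.records)
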