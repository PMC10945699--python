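"""Single-cell membrane model: analytic oracles and firing modes."""

import numpy as np
import pytest

from ubcsim.cells import (MeasurementError, ProtocolError, f_I_curve,
                          membrane_area, measure_input_resistance,
                          measure_sag_ratio, simulate_cell, total_capacitance)
from ubcsim.circuits import detect_spikes
from ubcsim.engine import IntegrationError


class TestGeometry:
    @pytest.mark.parametrize("cell,area,cap", [
        ("on", 1256.64, 12.57), ("off", 2290.22, 22.90),
    ])
    def test_area_and_capacitance(self, cell, area, cap, on_cell, off_cell):
        p = on_cell if cell == "on" else off_cell
        assert membrane_area(p) == pytest.approx(area, abs=0.01)
        assert total_capacitance(p) == pytest.approx(cap, abs=0.01)

    def test_zero_specific_capacitance_gives_zero(self, on_cell):
        import dataclasses
        p = dataclasses.replace(on_cell, specific_capacitance=0.0)
        assert total_capacitance(p) == 0.0


class TestPassiveOracles:
    """Leak-only variants against the closed-form RC membrane."""

    def test_input_resistance_on(self, leak_only_on):
        # 1/(2e-4 S/cm² × 1.2566e-5 cm²) = 0.3979 GΩ
        assert measure_input_resistance(leak_only_on) == pytest.approx(
            0.3979, rel=0.01)

    def test_input_resistance_off(self, leak_only_off):
        assert measure_input_resistance(leak_only_off) == pytest.approx(
            0.6239, rel=0.01)

    @pytest.mark.parametrize("cell,tau", [("on", 5.0), ("off", 14.286)])
    def test_rc_step_response(self, cell, tau, leak_only_on, leak_only_off):
        """Voltage relaxation matches V(t) = E + IR·(1−exp(−t/τ)) to 1%."""
        p = leak_only_on if cell == "on" else leak_only_off
        dt = 0.005
        tr = simulate_cell(p, -5.0, dt=dt, duration=120.0, settle_ms=1000.0)
        e_pas = p.conductance("pas").erev
        r_gohm = measure_input_resistance(p)
        expected = e_pas - 5.0 * r_gohm * (1 - np.exp(-tr.t / tau))
        err = np.max(np.abs(tr.vm - expected))
        assert err < 0.01 * abs(5.0 * r_gohm)

    def test_leak_only_step_deflection(self, leak_only_on):
        """−5 pA on the ON leak gives ΔV = −1.99 mV at steady state."""
        tr = simulate_cell(leak_only_on, -5.0, duration=200.0,
                           settle_ms=1000.0)
        assert tr.vm[-1] - tr.vm[0] == pytest.approx(-1.99, abs=0.02)

    def test_quiescence_conservation(self, leak_only_on):
        dead = leak_only_on.with_gmax(pas=0.0)
        tr = simulate_cell(dead, duration=100.0, settle_ms=0.0)
        np.testing.assert_allclose(tr.vm, dead.v_init, atol=1e-12)


class TestFiringModes:
    def test_on_cell_quiescent_at_rest(self, on_cell):
        tr = simulate_cell(on_cell, duration=5000.0, settle_ms=500.0)
        assert len(detect_spikes(tr)) == 0

    def test_off_cell_tonic_and_regular(self, off_cell):
        tr = simulate_cell(off_cell, duration=5000.0, settle_ms=3000.0)
        st = detect_spikes(tr).spike_times
        rate = 1000.0 * len(st) / 5000.0
        assert 4.0 < rate < 25.0
        isi = np.diff(st)
        assert np.std(isi) / np.mean(isi) < 0.1  # clock-like

    def test_dt_convergence_of_driven_spikes(self, on_cell):
        """Halving dt leaves the spike count unchanged and moves driven
        spike times by less than 0.1 ms."""
        stim_amp = 60.0
        times = {}
        for dt in (0.005, 0.0025):
            tr = simulate_cell(on_cell, stim_amp, dt=dt, duration=500.0,
                               settle_ms=500.0)
            times[dt] = detect_spikes(tr).spike_times
        assert len(times[0.005]) == len(times[0.0025])
        assert len(times[0.005]) > 3
        assert np.max(np.abs(times[0.005] - times[0.0025])) < 0.1

    def test_gating_variables_bounded(self, on_cell):
        from ubcsim import engine
        cell_vec = engine.pack_cell(on_cell)
        gates = engine.initial_gates(on_cell)
        n = 40000
        rng = np.random.default_rng(7)
        stim = np.repeat(rng.uniform(-120, 160, n // 400), 400)
        glu = np.zeros(n)
        engine.integrate(cell_vec, on_cell.v_init, gates, None,
                         engine.REC_NONE, None, glu, stim, 0.025)
        assert np.all(gates >= 0.0) and np.all(gates <= 1.0)

    def test_integration_failure_names_time(self, on_cell):
        with pytest.raises(IntegrationError, match="ms"):
            simulate_cell(on_cell, np.inf, duration=10.0, settle_ms=0.0)


class TestMeasurements:
    def test_sag_requires_hyperpolarizing_step(self, on_cell):
        with pytest.raises(ProtocolError):
            measure_sag_ratio(on_cell, step_pA=50.0)

    def test_no_sag_without_h_current(self, leak_only_on):
        assert measure_sag_ratio(leak_only_on) == pytest.approx(0.0, abs=1e-6)

    def test_off_sag_exceeds_on_sag(self, on_cell, off_cell):
        """The OFF cell's much larger gH makes its sag more prominent."""
        assert measure_sag_ratio(off_cell) > measure_sag_ratio(on_cell)

    def test_synthetic_deflections_arithmetic(self):
        # (peak − steady)/peak with deflections −20 and −15 mV
        peak, steady = -20.0, -15.0
        assert (peak - steady) / peak == pytest.approx(0.25)

    def test_spiking_cell_invalidates_rin_measurement(self, off_cell):
        with pytest.raises(MeasurementError):
            measure_input_resistance(off_cell)

    def test_full_on_model_rin_near_leak_prediction(self, on_cell):
        """Resting channels only mildly reduce the ON input resistance
        below the pure-leak prediction (0.398 GΩ from the table)."""
        rin = measure_input_resistance(on_cell)
        assert 0.398 * 0.7 < rin <= 0.398 * 1.05

    def test_full_off_model_rin_with_holding(self, off_cell):
        """OFF model (held silent) within ±30% of the 0.64 GΩ reference."""
        rin = measure_input_resistance(off_cell, hold_pA=-20.0)
        assert 0.64 * 0.7 < rin < 0.64 * 1.3


class TestFICurve:
    def test_short_step_rejected(self, on_cell):
        with pytest.raises(ProtocolError):
            f_I_curve(on_cell, [20.0], step_duration=200.0)

    def test_on_silent_at_zero_current(self, on_cell):
        ((_, rate),) = f_I_curve(on_cell, [0.0])
        assert rate == 0.0

    def test_rate_monotone_above_rheobase(self, on_cell):
        steps = [20.0, 40.0, 60.0, 80.0, 120.0]
        rates = [r for _, r in f_I_curve(on_cell, steps)]
        assert all(b >= a for a, b in zip(rates, rates[1:]))
        assert rates[-1] > 0
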