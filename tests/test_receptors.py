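"""Receptor schemes: conservation, fixed points, engine consistency."""

import numpy as np
import pytest

from ubcsim import engine
from ubcsim.params import AMPAParams, MGluR2Params, ampa_diffusion_params
from ubcsim.diffusion import concentration_waveform
from ubcsim.receptors import (AMPAState, MGluR2State, NormalizationError,
                              ampa_equilibrium, ampa_rate_matrix, ampa_step,
                              mglur2_equilibrium, mglur2_step)


def _random_glu(rng, n, dt):
    """Piecewise-constant glutamate waveform with mM-range excursions."""
    levels = rng.uniform(0.0, 2.0, n // 200 + 1) * rng.random(n // 200 + 1)
    return np.repeat(levels, 200)[:n]


class TestAMPAScheme:
    def test_rest_is_absorbing_without_glutamate(self, ampa):
        state = AMPAState()
        for _ in range(1000):
            state, i = ampa_step(state, 0.0, -60.0, 0.05, ampa)
        assert i == 0.0
        assert state.closed == pytest.approx(1.0, abs=1e-12)

    def test_occupancy_conserved_on_random_waveform(self, ampa, rng):
        dt = 0.05
        glu = _random_glu(rng, 20000, dt)
        state = AMPAState()
        for g in glu[::10]:
            state, _ = ampa_step(state, g, -55.0, dt, ampa)
            assert state.total == pytest.approx(1.0, abs=1e-9)
            assert min(state.as_array()) >= 0.0

    def test_drifted_occupancy_rejected(self, ampa):
        bad = AMPAState(closed=0.7, open=0.5)
        with pytest.raises(NormalizationError):
            ampa_step(bad, 0.0, -60.0, 0.05, ampa)

    def test_equilibrium_matches_rate_matrix_nullspace(self, ampa):
        """Long constant-glutamate integration lands on the analytic
        stationary distribution (linear-algebra oracle) within 0.1%."""
        glu = 0.05
        eq = ampa_equilibrium(ampa, glu)
        state = AMPAState()
        dt = 0.5
        for _ in range(40000):
            state, _ = ampa_step(state, glu, -60.0, dt, ampa)
        np.testing.assert_allclose(state.as_array(), eq, atol=1e-3)
        # null-space sanity: Q @ eq = 0
        np.testing.assert_allclose(ampa_rate_matrix(ampa, glu) @ eq, 0,
                                   atol=1e-12)

    def test_engine_kernel_matches_reference_steps(self, ampa, rng):
        """The compiled kernel and the pure-Python step updates agree to
        machine precision on the same waveform."""
        dt = 0.025
        n = 4000
        glu = _random_glu(rng, n, dt)
        cell = engine.pack_cell(_passive_probe())
        gates = engine.initial_gates(_passive_probe())
        rec = np.array([1.0, 0.0, 0.0, 0.0])
        vm, isyn = engine.integrate(cell, -60.0, gates, rec, engine.REC_AMPA,
                                    engine.pack_ampa(ampa), glu,
                                    np.zeros(n), dt)
        state = AMPAState()
        ref = np.empty(n)
        for i, g in enumerate(glu):
            state, ref[i] = ampa_step(state, g, vm[i], dt, ampa)
        np.testing.assert_allclose(isyn, ref, rtol=1e-12, atol=1e-12)
        np.testing.assert_allclose(state.as_array(), rec, rtol=1e-9)

    def test_determinism_bitwise(self, ampa, rng):
        dt = 0.025
        glu = _random_glu(rng, 2000, dt)

        def run():
            s = AMPAState()
            out = []
            for g in glu:
                s, i = ampa_step(s, g, -55.0, dt, ampa)
                out.append(i)
            return np.asarray(out)

        np.testing.assert_array_equal(run(), run())


class TestAMPARebound:
    """Slow rebound current: grows with train duration and saturates."""

    def _rebound_charge(self, ampa, n_events, dt=0.05):
        p = ampa_diffusion_params()
        t = np.arange(0, 3000.0, dt)
        events = 100.0 + 20.0 * np.arange(n_events)
        glu = concentration_waveform(events, p, t)
        state = AMPAState()
        current = np.empty_like(t)
        for i, g in enumerate(glu):
            state, current[i] = ampa_step(state, g, -60.0, dt, ampa)
        off = int((events[-1] + 20.0) / dt)
        return -np.sum(current[off:]) * dt, current, t, off

    def test_rebound_charge_grows_and_decelerates(self, ampa):
        """Rebound charge rises with train duration with saturating
        (decelerating) increments as the slow pool fills."""
        q20, *_ = self._rebound_charge(ampa, 2)  # 20 ms of stimulation
        q100, *_ = self._rebound_charge(ampa, 6)  # 100 ms
        q200, *_ = self._rebound_charge(ampa, 11)  # 200 ms
        assert q20 < q100 < q200
        assert q200 - q100 < q100 - q20

    def test_slow_decay_time_constant_in_range(self, ampa):
        """Post-train rebound decays with a fitted τ of hundreds of ms."""
        _, current, t, off = self._rebound_charge(ampa, 10)
        seg = -current[off + 2000:off + 14000]
        tt = t[off + 2000:off + 14000] - t[off + 2000]
        mask = seg > 0
        coef = np.polyfit(tt[mask], np.log(seg[mask]), 1)
        tau = -1.0 / coef[0]
        assert 150.0 < tau < 600.0


class TestMGluR2Cascade:
    def test_no_activation_no_current(self, mglur2):
        state = MGluR2State()
        for v in (-120.0, -60.0, 0.0):
            _, i = mglur2_step(state, 0.0, v, 0.05, mglur2)
            assert i == 0.0

    def test_current_zero_at_reversal(self, mglur2):
        state = MGluR2State(R=0.5, G=10.0)
        _, i = mglur2_step(state, 0.0, -90.0, 0.05, mglur2)
        assert i == 0.0

    def test_current_outward_above_reversal(self, mglur2):
        state = MGluR2State(R=0.5, G=10.0)
        _, i = mglur2_step(state, 0.0, -60.0, 0.05, mglur2)
        assert i > 0.0

    def test_half_occupancy_fixed_point(self, mglur2):
        """When binding flux equals the unbinding rate, R settles at 1/2."""
        import dataclasses
        p = dataclasses.replace(mglur2, hill_bind=1.0, k1=mglur2.k2 / 0.1)
        state = MGluR2State()
        for _ in range(20000):
            state, _ = mglur2_step(state, 0.1, -60.0, 1.0, p)
        assert state.R == pytest.approx(0.5, abs=1e-4)
        assert mglur2_equilibrium(p, 0.1).R == pytest.approx(0.5, abs=1e-12)

    def test_unbinding_time_constant(self, mglur2):
        """After glutamate is removed, R decays with τ = 1/k2 = 46.51 ms."""
        state = MGluR2State(R=0.8, G=0.0)
        dt = 0.01
        n = int(46.512 / dt)  # one time constant
        for _ in range(n):
            state, _ = mglur2_step(state, 0.0, -60.0, dt, mglur2)
        assert state.R == pytest.approx(0.8 * np.exp(-1.0), rel=1e-3)

    def test_equilibrium_reached_within_tolerance(self, mglur2):
        glu = 0.02
        eq = mglur2_equilibrium(mglur2, glu)
        state = MGluR2State()
        for _ in range(30000):
            state, _ = mglur2_step(state, glu, -60.0, 1.0, mglur2)
        assert state.R == pytest.approx(eq.R, rel=1e-3)
        assert state.G == pytest.approx(eq.G, rel=1e-3)

    def test_current_monotone_in_g(self, mglur2):
        currents = [mglur2_step(MGluR2State(R=0.0, G=g), 0.0, -60.0, 0.05,
                                mglur2)[1] for g in np.linspace(0, 30, 50)]
        assert all(b >= a for a, b in zip(currents, currents[1:]))

    def test_engine_kernel_matches_reference_steps(self, mglur2, rng):
        dt = 0.025
        n = 4000
        glu = 0.05 * _random_glu(rng, n, dt)
        cell = engine.pack_cell(_passive_probe())
        gates = engine.initial_gates(_passive_probe())
        rec = np.zeros(4)
        vm, isyn = engine.integrate(cell, -60.0, gates, rec,
                                    engine.REC_MGLUR2,
                                    engine.pack_mglur2(mglur2), glu,
                                    np.zeros(n), dt)
        state = MGluR2State()
        ref = np.empty(n)
        for i, g in enumerate(glu):
            state, ref[i] = mglur2_step(state, g, vm[i], dt, mglur2)
        np.testing.assert_allclose(isyn, ref, rtol=1e-12, atol=1e-12)


def _passive_probe():
    """Leak-only cell used to exercise receptor updates in the kernel."""
    from ubcsim.params import on_cell_params
    return on_cell_params().with_gmax(Na=0.0, K=0.0, K_slow=0.0, H=0.0)
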