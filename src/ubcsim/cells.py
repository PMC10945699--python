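"""Single-cell simulation and passive/excitability measurements.

The measurement operations mirror standard current-clamp protocols:
input resistance from a −5 pA pulse, sag ratio from a −100 pA step,
frequency–intensity curves from 500 ms depolarizing steps.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from . import engine
from .engine import membrane_area_um2
from .params import CellParams

__all__ = [
    "VoltageTrace", "membrane_area", "total_capacitance", "simulate_cell",
    "measure_input_resistance", "measure_sag_ratio", "f_I_curve",
    "MeasurementError", "ProtocolError", "DEFAULT_DT", "DEFAULT_SETTLE_MS",
]

DEFAULT_DT = 0.005  # ms
DEFAULT_SETTLE_MS = 500.0  # discarded before any measurement


class MeasurementError(RuntimeError):
    """A measurement protocol's validity condition was violated."""


class ProtocolError(ValueError):
    """The requested stimulus protocol is invalid for the measurement."""


@dataclass
class VoltageTrace:
    """Uniformly sampled membrane-potential record."""

    t: np.ndarray  # ms
    vm: np.ndarray  # mV
    injected: np.ndarray  # pA
    meta: Mapping = field(default_factory=dict)

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.vm = np.asarray(self.vm, dtype=float)
        self.injected = np.asarray(self.injected, dtype=float)
        if len(self.vm) != len(self.t) or len(self.injected) != len(self.t):
            raise ValueError("t, vm and injected must have equal length")
        if len(self.t) > 1:
            dts = np.diff(self.t)
            if np.any(dts <= 0) or not np.allclose(dts, dts[0], rtol=1e-9,
                                                   atol=1e-12):
                raise ValueError("t must be strictly increasing and uniform")

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0]) if len(self.t) > 1 else float("nan")

    def to_csv(self, path):
        """Two-column CSV (t_ms, vm_mV) with header."""
        arr = np.column_stack([self.t, self.vm])
        np.savetxt(path, arr, delimiter=",", header="t_ms,vm_mV", comments="",
                   fmt="%.6f")


def membrane_area(params: CellParams) -> float:
    """Membrane area in µm² (cylinder with length = diameter, π·d²)."""
    return membrane_area_um2(params.diameter)


def total_capacitance(params: CellParams) -> float:
    """Whole-cell capacitance in pF (specific capacitance × area)."""
    area_cm2 = membrane_area(params) * 1e-8
    return params.specific_capacitance * area_cm2 * 1e6  # µF → pF


def _as_waveform(stimulus, n, dt):
    if stimulus is None:
        return np.zeros(n)
    if callable(stimulus):
        return np.asarray([stimulus(i * dt) for i in range(n)], dtype=float)
    stim = np.asarray(stimulus, dtype=float)
    if stim.ndim == 0:
        return np.full(n, float(stim))
    if len(stim) != n:
        raise ValueError(f"stimulus length {len(stim)} != grid length {n}")
    return stim


def simulate_cell(params: CellParams, stimulus=None, synaptic_current=None,
                  dt: float = DEFAULT_DT, duration: float = 1000.0,
                  settle_ms: float = DEFAULT_SETTLE_MS) -> VoltageTrace:
    """Integrate the membrane equation under a current-clamp stimulus.

    ``stimulus`` is a pA waveform on the [0, duration) grid (array,
    scalar, or callable of t); ``synaptic_current`` an optional extra
    pA waveform added to it.  A settling period of ``settle_ms`` at
    zero injected current precedes t = 0 and is discarded.
    """
    if not dt > 0:
        raise ValueError("dt must be > 0")
    if duration < dt:
        raise ValueError("duration must be >= dt")
    n_settle = int(round(settle_ms / dt))
    n = int(round(duration / dt))
    i_inj = _as_waveform(stimulus, n, dt)
    if synaptic_current is not None:
        i_inj = i_inj + _as_waveform(synaptic_current, n, dt)
    full = np.concatenate([np.zeros(n_settle), i_inj])
    cell_vec = engine.pack_cell(params)
    gates = engine.initial_gates(params)
    glu = np.zeros(len(full))
    vm, _ = engine.integrate(cell_vec, params.v_init, gates, None,
                             engine.REC_NONE, None, glu, full, dt,
                             t_offset_ms=-settle_ms)
    t = np.arange(n) * dt
    return VoltageTrace(t=t, vm=vm[n_settle:], injected=i_inj,
                        meta={"dt": dt, "duration": duration,
                              "subtype": params.subtype,
                              "settle_ms": settle_ms})


def _spikes_in(vm, threshold=0.0):
    return np.any((vm[1:] >= threshold) & (vm[:-1] < threshold))


def measure_input_resistance(params: CellParams, pulse_pA: float = -5.0,
                             hold_pA: float = 0.0, dt: float = DEFAULT_DT,
                             baseline_ms: float = 1000.0,
                             pulse_ms: float = 1000.0) -> float:
    """Input resistance (GΩ) from a small hyperpolarizing pulse.

    ``hold_pA`` can silence a spontaneously active cell; the pulse is
    superimposed on it.  Raises :class:`MeasurementError` if the cell
    spikes during the measurement window.
    """
    duration = baseline_ms + pulse_ms
    n = int(round(duration / dt))
    stim = np.full(n, hold_pA)
    i0 = int(round(baseline_ms / dt))
    stim[i0:] += pulse_pA
    tr = simulate_cell(params, stim, dt=dt, duration=duration,
                       settle_ms=max(DEFAULT_SETTLE_MS, 1000.0))
    if _spikes_in(tr.vm):
        raise MeasurementError(
            "cell spiked during the input-resistance measurement; "
            "use hold_pA to silence it")
    win = int(round(200.0 / dt))
    v_base = tr.vm[i0 - win:i0].mean()
    v_steady = tr.vm[-win:].mean()
    return float((v_steady - v_base) / pulse_pA)  # mV/pA = GΩ


def measure_sag_ratio(params: CellParams, step_pA: float = -100.0,
                      dt: float = DEFAULT_DT, baseline_ms: float = 1000.0,
                      step_ms: float = 1000.0) -> float:
    """Sag ratio (peak − steady state)/peak from a hyperpolarizing step.

    Deflections are measured from the pre-step baseline (median, robust
    to spontaneous spiking before the step).  The cell must be silent
    during the step itself.
    """
    if step_pA >= 0:
        raise ProtocolError("sag requires a hyperpolarizing (negative) step")
    duration = baseline_ms + step_ms + 200.0
    n = int(round(duration / dt))
    stim = np.zeros(n)
    i0 = int(round(baseline_ms / dt))
    i1 = int(round((baseline_ms + step_ms) / dt))
    stim[i0:i1] = step_pA
    tr = simulate_cell(params, stim, dt=dt, duration=duration,
                       settle_ms=max(DEFAULT_SETTLE_MS, 1000.0))
    if _spikes_in(tr.vm[i0:i1]):
        raise MeasurementError("cell spiked during the sag step")
    v_base = float(np.median(tr.vm[i0 - int(round(500.0 / dt)):i0]))
    seg = tr.vm[i0:i1]
    peak_defl = float(seg.min() - v_base)  # negative
    win = int(round(200.0 / dt))
    steady_defl = float(seg[-win:].mean() - v_base)
    if peak_defl >= 0:
        return 0.0
    ratio = (peak_defl - steady_defl) / peak_defl
    return float(max(ratio, 0.0))


def f_I_curve(params: CellParams, steps: Sequence[float],
              step_duration: float = 500.0, dt: float = DEFAULT_DT,
              threshold_mV: float = 0.0):
    """Firing rate (Hz) versus injected current (pA), 500 ms steps.

    Returns a list of (pA, Hz) tuples; rate = spike count / duration.
    """
    if step_duration < 500.0:
        raise ProtocolError("step_duration must be >= 500 ms")
    from .circuits import detect_spikes

    out = []
    for amp in steps:
        tr = simulate_cell(params, float(amp), dt=dt,
                           duration=step_duration,
                           settle_ms=max(DEFAULT_SETTLE_MS, 1000.0))
        st = detect_spikes(tr, threshold_mV=threshold_mV)
        out.append((float(amp), 1000.0 * len(st.spike_times) / step_duration))
    return out
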