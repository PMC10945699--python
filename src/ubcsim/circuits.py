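"""Feed-forward UBC circuits: wiring, co-integration and spike detection.

A circuit is a chain: one stimulus source followed by one or two UBC
nodes.  Every presynaptic spike (from the stimulus or from a UBC)
schedules one glutamate release event on each outgoing edge after the
synaptic delay; the receptor type on an edge is forced by the
postsynaptic cell's subtype (ON ⇒ AMPA, OFF ⇒ mGluR2).  Because the
graph is feed-forward, integrating nodes in topological order on a
shared grid is exact co-integration.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

from . import engine
from .cells import VoltageTrace, DEFAULT_DT
from .diffusion import concentration_waveform, transient_template
from .params import (AMPAParams, CellParams, DiffusionParams, MGluR2Params,
                     ampa_diffusion_params, ampa_receptor_params,
                     mglur2_diffusion_params, mglur2_receptor_params,
                     off_cell_params, on_cell_params)
from .receptors import ampa_equilibrium

__all__ = [
    "SpikeTrain", "SynapseSpec", "CircuitSpec", "CircuitResult",
    "detect_spikes", "run_circuit", "motif_circuit", "MOTIFS",
    "DEFAULT_SYNAPTIC_DELAY_MS",
]

#: measured mossy-fiber → UBC latency used as the model synaptic delay
DEFAULT_SYNAPTIC_DELAY_MS = 1.24

MOTIFS = ("on", "off", "on-on", "on-off", "off-on", "off-off")

SPIKE_THRESHOLD_MV = 0.0
SPIKE_REFRACTORY_MS = 1.0


@dataclass(frozen=True)
class SpikeTrain:
    """Sorted spike times (ms) from one source within a recording window."""

    spike_times: np.ndarray
    source: str = ""
    window: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self):
        times = np.asarray(self.spike_times, dtype=float)
        if times.ndim != 1:
            raise ValueError("spike_times must be 1-D")
        if np.any(np.diff(times) <= 0):
            raise ValueError("spike_times must be strictly increasing")
        lo, hi = self.window
        if times.size and (times[0] < lo or times[-1] >= hi):
            raise ValueError("spike times outside recording window")
        object.__setattr__(self, "spike_times", times)

    def __len__(self):
        return len(self.spike_times)

    def shifted(self, offset_ms: float) -> "SpikeTrain":
        lo, hi = self.window
        return SpikeTrain(self.spike_times + offset_ms, self.source,
                          (lo + offset_ms, hi + offset_ms))


@dataclass(frozen=True)
class SynapseSpec:
    """One edge: delay plus diffusion and receptor parameterization."""

    delay_ms: float = DEFAULT_SYNAPTIC_DELAY_MS
    diffusion: DiffusionParams = field(default_factory=ampa_diffusion_params)
    receptor: AMPAParams | MGluR2Params = field(
        default_factory=ampa_receptor_params)

    def __post_init__(self):
        if self.delay_ms < 0:
            raise ValueError("synaptic delay must be >= 0")


@dataclass(frozen=True)
class CircuitSpec:
    """Chain of a stimulus source and 1–2 UBC nodes with typed synapses.

    ``cells[i]`` receives from ``cells[i-1]`` (or the stimulus for
    i = 0) through ``synapses[i]``.
    """

    motif: str
    cells: tuple[CellParams, ...]
    synapses: tuple[SynapseSpec, ...]

    def __post_init__(self):
        if len(self.cells) != len(self.synapses):
            raise ValueError("need exactly one synapse per cell")
        if not 1 <= len(self.cells) <= 2:
            raise ValueError("circuits support 1 or 2 UBC nodes")
        for cell, syn in zip(self.cells, self.synapses):
            want = AMPAParams if cell.subtype == "ON" else MGluR2Params
            if not isinstance(syn.receptor, want):
                raise ValueError(
                    f"{cell.subtype} cell requires {want.__name__} synapse")
        object.__setattr__(self, "cells", tuple(self.cells))
        object.__setattr__(self, "synapses", tuple(self.synapses))

    @property
    def node_ids(self) -> tuple[str, ...]:
        return tuple(f"{c.subtype.lower()}{i + 1}"
                     for i, c in enumerate(self.cells))


@dataclass
class CircuitResult:
    """Per-node traces, spike trains and synaptic currents."""

    traces: Mapping[str, VoltageTrace]
    spikes: Mapping[str, SpikeTrain]
    syn_currents: Mapping[str, np.ndarray]  # pA, on the trace grid
    glu_waveforms: Mapping[str, np.ndarray]  # mM, on the trace grid
    release_events: Mapping[str, np.ndarray]  # ms, per postsynaptic node
    stimulus: SpikeTrain
    meta: Mapping = field(default_factory=dict)


def detect_spikes(trace: VoltageTrace, threshold_mV: float = SPIKE_THRESHOLD_MV,
                  refractory_ms: float = SPIKE_REFRACTORY_MS) -> SpikeTrain:
    """Upward threshold crossings separated by at least the refractory."""
    times = _detect(trace.vm, trace.dt, float(trace.t[0]), threshold_mV,
                    refractory_ms)
    window = (float(trace.t[0]), float(trace.t[-1]) + trace.dt)
    return SpikeTrain(times, source=str(trace.meta.get("node", "")),
                      window=window)


def _detect(vm, dt, t0, threshold, refractory):
    idx = np.flatnonzero((vm[1:] >= threshold) & (vm[:-1] < threshold)) + 1
    times = t0 + idx * dt
    if len(times) == 0:
        return times
    kept = [times[0]]
    for t in times[1:]:
        if t - kept[-1] >= refractory:
            kept.append(t)
    return np.asarray(kept)


def motif_circuit(motif: str, *, on_params: Optional[CellParams] = None,
                  off_params: Optional[CellParams] = None,
                  ampa: Optional[AMPAParams] = None,
                  mglur2: Optional[MGluR2Params] = None,
                  diffusion_ampa: Optional[DiffusionParams] = None,
                  diffusion_mglur2: Optional[DiffusionParams] = None,
                  delay_ms: float = DEFAULT_SYNAPTIC_DELAY_MS) -> CircuitSpec:
    """Build one of the preset motifs: on, off, on-on, on-off, off-on,
    off-off (hyphen-separated subtypes, presynaptic first)."""
    if motif not in MOTIFS:
        raise ValueError(f"unknown motif {motif!r}; choose from {MOTIFS}")
    on_params = on_params or on_cell_params()
    off_params = off_params or off_cell_params()
    ampa = ampa or ampa_receptor_params()
    mglur2 = mglur2 or mglur2_receptor_params()
    diffusion_ampa = diffusion_ampa or ampa_diffusion_params()
    diffusion_mglur2 = diffusion_mglur2 or mglur2_diffusion_params()

    cells, synapses = [], []
    for sub in motif.split("-"):
        if sub == "on":
            cells.append(on_params)
            synapses.append(SynapseSpec(delay_ms, diffusion_ampa, ampa))
        else:
            cells.append(off_params)
            synapses.append(SynapseSpec(delay_ms, diffusion_mglur2, mglur2))
    return CircuitSpec(motif=motif, cells=tuple(cells),
                       synapses=tuple(synapses))


def run_circuit(spec: CircuitSpec, stimulus: Optional[SpikeTrain] = None,
                dt: float = DEFAULT_DT, duration: float = 3000.0,
                settle_ms: float = 2000.0) -> CircuitResult:
    """Simulate the circuit; returns traces/trains cropped to [0, duration).

    A settling window of ``settle_ms`` precedes t = 0: cells relax,
    spontaneously active presynaptic cells already release transmitter,
    and receptors equilibrate to ambient glutamate, so slow synaptic
    state variables are at their baseline operating point before any
    stimulus.  Stimulus spike times must lie in [0, duration).
    """
    if not dt > 0:
        raise ValueError("dt must be > 0")
    stim_times = (np.asarray(stimulus.spike_times, dtype=float)
                  if stimulus is not None else np.empty(0))
    if stim_times.size and (stim_times[0] < 0 or stim_times[-1] >= duration):
        raise ValueError("stimulus spikes must lie within [0, duration)")

    n_settle = int(round(settle_ms / dt))
    n_rec = int(round(duration / dt))
    n = n_settle + n_rec
    grid = (np.arange(n) - n_settle) * dt

    traces, trains, syn_currents, glu_waveforms, releases = {}, {}, {}, {}, {}
    pre_times = stim_times
    templates: dict[DiffusionParams, np.ndarray] = {}

    for i, (cell, syn) in enumerate(zip(spec.cells, spec.synapses)):
        node = spec.node_ids[i]
        events = pre_times + syn.delay_ms
        releases[node] = events
        dp = syn.diffusion
        if dp not in templates:
            templates[dp] = transient_template(dp, dt, n)
        glu = concentration_waveform(events, dp, grid, template=templates[dp])

        cell_vec = engine.pack_cell(cell)
        gates = engine.initial_gates(cell)
        if isinstance(syn.receptor, AMPAParams):
            rec_kind = engine.REC_AMPA
            recvec = engine.pack_ampa(syn.receptor)
            rec_state = ampa_equilibrium(syn.receptor, dp.ambient_mM).copy()
        else:
            rec_kind = engine.REC_MGLUR2
            recvec = engine.pack_mglur2(syn.receptor)
            rec_state = np.zeros(4)
        i_inj = np.zeros(n)
        try:
            vm, isyn = engine.integrate(cell_vec, cell.v_init, gates,
                                        rec_state, rec_kind, recvec, glu,
                                        i_inj, dt, t_offset_ms=-settle_ms)
        except engine.IntegrationError as err:
            raise engine.IntegrationError(f"node {node}: {err}") from err

        spike_times = _detect(vm, dt, -settle_ms, SPIKE_THRESHOLD_MV,
                              SPIKE_REFRACTORY_MS)
        tr = VoltageTrace(t=np.arange(n_rec) * dt, vm=vm[n_settle:],
                          injected=np.zeros(n_rec),
                          meta={"dt": dt, "duration": duration, "node": node,
                                "subtype": cell.subtype,
                                "settle_ms": settle_ms})
        traces[node] = tr
        rec_spikes = spike_times[(spike_times >= 0) & (spike_times < duration)]
        trains[node] = SpikeTrain(rec_spikes, source=node,
                                  window=(0.0, duration))
        syn_currents[node] = isyn[n_settle:]
        glu_waveforms[node] = glu[n_settle:]
        pre_times = spike_times  # next node is driven by this one

    stim_train = SpikeTrain(stim_times, source="stim", window=(0.0, duration))
    return CircuitResult(traces=traces, spikes=trains,
                         syn_currents=syn_currents,
                         glu_waveforms=glu_waveforms,
                         release_events=releases, stimulus=stim_train,
                         meta={"dt": dt, "duration": duration,
                               "settle_ms": settle_ms, "motif": spec.motif})
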