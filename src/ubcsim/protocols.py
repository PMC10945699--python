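"""Stimulus generation and preset experiments.

The stimuli reproduce the protocols the circuit simulations are built
around: short presynaptic bursts (3 spikes spanning 19.6 ms, i.e.
9.8 ms inter-spike interval), trains of 1–10 spikes, 10-event 50 Hz
trains, and the current-step protocols used for passive validation
(−100 pA / −5 pA, 0–60 pA × 500 ms).
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Mapping, Optional

import numpy as np

from . import __version__
from .circuits import (SpikeTrain, motif_circuit, run_circuit)
from .metrics import (InvalidBaselineError, burst_duration,
                      delayed_response_latency, pause_duration)
from .params import (ampa_receptor_params, mglur2_receptor_params,
                     off_cell_params, on_cell_params)

__all__ = ["make_presyn_train", "run_experiment", "PRESETS",
           "UnknownPresetError", "ProtocolSpec"]

#: inter-spike interval of the 3-spike presynaptic burst: 19.6 ms span
THREE_SPIKE_ISI_MS = 9.8
#: 50 Hz train interval
TRAIN_ISI_MS = 20.0


class UnknownPresetError(KeyError):
    """Requested preset does not exist; the message lists valid names."""


@dataclasses.dataclass(frozen=True)
class ProtocolSpec:
    """One preset simulation: motif, stimulus and integration grid."""

    motif: str
    n_spikes: int
    isi_ms: float
    onset_ms: float
    dt: float = 0.025
    duration: float = 6000.0
    settle_ms: float = 2000.0
    seed: int = 0  # reserved for optional stimulus jitter (none by default)


PRESETS: dict[str, ProtocolSpec] = {
    # serial ON chain, 3 presynaptic spikes spanning 19.6 ms
    "on-on-3spike": ProtocolSpec("on-on", 3, THREE_SPIKE_ISI_MS, 1000.0,
                                 duration=5000.0, settle_ms=1000.0),
    # single ON UBC, same 3-spike burst
    "on-3spike": ProtocolSpec("on", 3, THREE_SPIKE_ISI_MS, 1000.0,
                              duration=4000.0, settle_ms=1000.0),
    # calibration anchors: 10 release events at 50 Hz
    "on-10ev": ProtocolSpec("on", 10, TRAIN_ISI_MS, 1000.0,
                            duration=4000.0, settle_ms=1000.0),
    "off-10ev": ProtocolSpec("off", 10, TRAIN_ISI_MS, 2000.0,
                             duration=6000.0, settle_ms=2000.0),
    # pause extension with an intermediate ON UBC
    "on-off-10ev": ProtocolSpec("on-off", 10, TRAIN_ISI_MS, 2000.0,
                                duration=7000.0, settle_ms=2000.0),
    # delayed pause in a postsynaptic ON UBC
    "off-on-10ev": ProtocolSpec("off-on", 10, TRAIN_ISI_MS, 2000.0,
                                duration=7000.0, settle_ms=3000.0),
    # delayed burst in a postsynaptic OFF UBC
    "off-off-10ev": ProtocolSpec("off-off", 10, TRAIN_ISI_MS, 2000.0,
                                 duration=8000.0, settle_ms=3000.0),
}


def make_presyn_train(n_spikes: int, isi_ms: float, onset_ms: float = 0.0,
                      window: Optional[tuple[float, float]] = None
                      ) -> SpikeTrain:
    """Regular presynaptic train: spikes at onset + k·isi, k = 0…n−1."""
    if n_spikes < 1:
        raise ValueError("n_spikes must be >= 1")
    if isi_ms <= 0:
        raise ValueError("isi_ms must be > 0")
    times = onset_ms + np.arange(n_spikes) * isi_ms
    if window is None:
        window = (min(0.0, times[0]), times[-1] + 1.0)
    return SpikeTrain(times, source="stim", window=window)


def _metrics_for(preset: ProtocolSpec, spec, result) -> dict:
    onset = preset.onset_ms
    out: dict[str, object] = {}
    for node in spec.node_ids:
        train = result.spikes[node]
        sub = node[:-1].upper()
        m: dict[str, object] = {"n_spikes_total": int(len(train))}
        if sub == "ON" and not preset.motif.startswith("off"):
            dur, count = burst_duration(train, onset)
            m["burst_duration_ms"] = dur
            m["n_spikes_evoked"] = count
        elif sub == "OFF" and preset.motif != "off-off":
            try:
                m["pause_duration_ms"] = pause_duration(train, onset)
            except InvalidBaselineError:
                m["pause_duration_ms"] = None
        out[node] = m
    if preset.motif == "off-on":
        out["delay_to_pause_ms"] = delayed_response_latency(
            result.spikes[spec.node_ids[0]], result.spikes[spec.node_ids[1]],
            "off-on", stim_onset=onset)
    if preset.motif == "off-off":
        out["delayed_burst_latency_ms"] = delayed_response_latency(
            result.spikes[spec.node_ids[0]], result.spikes[spec.node_ids[1]],
            "off-off", stim_onset=onset)
        dur, count = burst_duration(result.spikes[spec.node_ids[1]], onset)
        out[spec.node_ids[1]]["burst_duration_ms"] = dur
        out[spec.node_ids[1]]["n_spikes_evoked"] = count
    return out


def run_experiment(preset_name: str, overrides: Optional[Mapping] = None,
                   out_dir=None, circuit_kwargs: Optional[Mapping] = None):
    """Run a preset end to end; returns (result, metrics dict).

    ``overrides`` replaces ProtocolSpec fields; ``circuit_kwargs`` is
    passed to :func:`ubcsim.circuits.motif_circuit` (cell/receptor
    parameter substitutions).  With ``out_dir`` set, per-node voltage
    CSVs, spike-time CSVs, a metrics JSON and a manifest JSON are
    written; reruns with identical configuration are bitwise identical.
    """
    if preset_name not in PRESETS:
        raise UnknownPresetError(
            f"unknown preset {preset_name!r}; available: "
            f"{', '.join(sorted(PRESETS))}")
    preset = PRESETS[preset_name]
    if overrides:
        preset = dataclasses.replace(preset, **dict(overrides))
    spec = motif_circuit(preset.motif, **(dict(circuit_kwargs or {})))
    stim = make_presyn_train(preset.n_spikes, preset.isi_ms, preset.onset_ms,
                             window=(0.0, preset.duration))
    result = run_circuit(spec, stim, dt=preset.dt, duration=preset.duration,
                         settle_ms=preset.settle_ms)
    metrics = _metrics_for(preset, spec, result)

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for node, tr in result.traces.items():
            tr.to_csv(out / f"{node}_vm.csv")
            np.savetxt(out / f"{node}_spikes.csv",
                       result.spikes[node].spike_times[:, None],
                       delimiter=",", header="spike_time_ms", comments="",
                       fmt="%.6f")
            np.savetxt(out / f"{node}_glu.csv",
                       np.column_stack([tr.t, result.glu_waveforms[node]]),
                       delimiter=",", header="t_ms,glu_mM", comments="",
                       fmt="%.6f")
            np.savetxt(out / f"{node}_isyn.csv",
                       np.column_stack([tr.t, result.syn_currents[node]]),
                       delimiter=",", header="t_ms,i_pA", comments="",
                       fmt="%.6f")
        (out / "metrics.json").write_text(
            json.dumps(metrics, indent=2, sort_keys=True, default=float))
        manifest = {
            "preset": preset_name,
            "protocol": dataclasses.asdict(preset),
            "ubcsim_version": __version__,
            "seed": preset.seed,
        }
        (out / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True))
    return result, metrics
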