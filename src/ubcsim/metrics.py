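"""Burst/pause/delay metrics on spike trains.

Operational definitions (the simulation outputs are deterministic, so
the criteria below are the package's fixed conventions):

* **burst**: for a quiescent-baseline cell, the run of spikes after
  stimulus onset terminated by the first inter-spike interval exceeding
  max(100 ms, 5× the median within-burst ISI so far); duration is
  first-to-last spike.
* **pause**: for a tonically firing cell, the first gap that starts
  within 200 ms of stimulus onset and exceeds 3× the median baseline
  ISI; duration is last-spike-before to first-spike-after.
* **delayed-response latency**: OFF→OFF, from the intermediate cell's
  last spike before its pause to the postsynaptic cell's first spike
  after it; OFF→ON, from stimulus onset to the postsynaptic cell's
  last spike before its pause (pause onset).

Metrics that are undefined for a train (no baseline, firing never
resumes, required spikes absent) are flagged, never silently numeric.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .circuits import SpikeTrain

__all__ = [
    "ResponseMetrics", "burst_duration", "pause_duration", "pause_extension",
    "delayed_response_latency", "sweep_input_duration", "baseline_rate",
    "InvalidBaselineError", "BURST_MAX_ISI_MS", "BURST_ISI_FACTOR",
    "PAUSE_START_WINDOW_MS", "PAUSE_ISI_FACTOR",
]

BURST_MAX_ISI_MS = 100.0
BURST_ISI_FACTOR = 5.0
PAUSE_START_WINDOW_MS = 200.0
PAUSE_ISI_FACTOR = 3.0
#: search window for the delayed pause onset in the OFF→ON motif
DELAYED_PAUSE_SEARCH_MS = 2000.0


class InvalidBaselineError(RuntimeError):
    """The train lacks the baseline firing the metric requires."""


@dataclass
class ResponseMetrics:
    """Container for the per-response metrics; NaN fields carry a flag."""

    n_spikes_evoked: int = 0
    burst_duration: float = float("nan")
    pause_duration: float = float("nan")
    delay_to_pause: float = float("nan")
    delayed_burst_latency: float = float("nan")
    baseline_rate: float = float("nan")
    undefined: set = field(default_factory=set)

    def flag(self, name: str):
        self.undefined.add(name)


def _times(train) -> np.ndarray:
    if isinstance(train, SpikeTrain):
        return np.asarray(train.spike_times, dtype=float)
    return np.asarray(train, dtype=float)


def baseline_rate(train, stim_onset: float, min_window_ms: float = 2000.0):
    """Mean firing rate (Hz) in the window preceding stimulus onset."""
    t = _times(train)
    if isinstance(train, SpikeTrain):
        t0 = max(train.window[0], stim_onset - min_window_ms)
    else:
        t0 = stim_onset - min_window_ms
    span = stim_onset - t0
    if span <= 0:
        return float("nan")
    return 1000.0 * np.sum((t >= t0) & (t < stim_onset)) / span


def burst_duration(train, stim_onset: float,
                   max_isi_ms: float = BURST_MAX_ISI_MS,
                   isi_factor: float = BURST_ISI_FACTOR):
    """Evoked burst duration (ms) and spike count after stimulus onset.

    Returns (duration, n_spikes); (0.0, 0) when no spikes follow onset.
    """
    t = _times(train)
    t = t[t >= stim_onset]
    if t.size == 0:
        return 0.0, 0
    burst = [t[0]]
    isis: list[float] = []
    for ti in t[1:]:
        isi = ti - burst[-1]
        crit = max_isi_ms if not isis else max(max_isi_ms,
                                               isi_factor * float(np.median(isis)))
        if isi > crit:
            break
        isis.append(isi)
        burst.append(ti)
    return float(burst[-1] - burst[0]), len(burst)


def pause_duration(train, stim_onset: float,
                   start_window_ms: float = PAUSE_START_WINDOW_MS,
                   isi_factor: float = PAUSE_ISI_FACTOR,
                   baseline_window_ms: float = 2000.0):
    """Evoked pause duration (ms) in a tonically firing train.

    Returns NaN (flagged via None-like semantics) when no qualifying
    gap exists or firing never resumes; raises
    :class:`InvalidBaselineError` when there are no baseline spikes.
    """
    t = _times(train)
    base = t[t < stim_onset]
    if isinstance(train, SpikeTrain):
        base = base[base >= max(train.window[0],
                                stim_onset - baseline_window_ms)]
    else:
        base = base[base >= stim_onset - baseline_window_ms]
    if base.size < 2:
        raise InvalidBaselineError("no baseline firing before stimulus onset")
    base_isi = float(np.median(np.diff(base)))
    crit = isi_factor * base_isi
    # candidate gap left edges: last spike before onset onward
    start_idx = int(np.searchsorted(t, stim_onset)) - 1
    start_idx = max(start_idx, 0)
    for i in range(start_idx, len(t) - 1):
        left, right = t[i], t[i + 1]
        if left > stim_onset + start_window_ms:
            break
        gap = right - left
        if gap > crit:
            return float(gap)
    # firing may never resume within the window
    if len(t) and t[-1] <= stim_onset + start_window_ms:
        return float("nan")
    return float("nan")


def pause_extension(result_with_intermediate, result_without,
                    node_with: str, node_without: str, stim_onset: float):
    """Pause(ON→OFF) − pause(direct OFF) for one matched stimulus (ms)."""
    p_with = pause_duration(result_with_intermediate.spikes[node_with],
                            stim_onset)
    p_without = pause_duration(result_without.spikes[node_without],
                               stim_onset)
    return float(p_with - p_without)


def delayed_response_latency(pre_train, post_train, motif: str,
                             stim_onset: float = 0.0) -> float:
    """Latency of the delayed transformation (ms); NaN when undefined.

    motif "off-off": interval from the intermediate (pre) cell's last
    spike before its pause to the postsynaptic cell's first spike after
    it.  motif "off-on": interval from stimulus onset to the
    postsynaptic cell's last spike before its pause (pause onset).
    """
    if motif not in ("off-on", "off-off"):
        raise ValueError(f"latency metric applies to off-on/off-off, "
                         f"got {motif!r}")
    if motif == "off-off":
        pre = _times(pre_train)
        base = pre[pre < stim_onset]
        if base.size < 2:
            raise InvalidBaselineError("intermediate cell has no baseline")
        crit = PAUSE_ISI_FACTOR * float(np.median(np.diff(base)))
        last_pre = None
        for i in range(len(pre) - 1):
            if pre[i] >= stim_onset - crit and pre[i + 1] - pre[i] > crit:
                last_pre = pre[i]
                break
        if last_pre is None and len(pre) and pre[-1] >= stim_onset - crit:
            # pause extends past the end of the recording
            last_pre = pre[-1]
        if last_pre is None:
            return float("nan")
        post = _times(post_train)
        post = post[post > last_pre]
        if post.size == 0:
            return float("nan")
        return float(post[0] - last_pre)
    # off-on: postsynaptic pause onset relative to stimulus onset.  The
    # pause is delayed by construction (the slow EPSC outlasts the
    # presynaptic pause), so the gap search window is wide.
    post = _times(post_train)
    base = post[post < stim_onset]
    if base.size < 2:
        raise InvalidBaselineError("postsynaptic cell has no baseline firing")
    crit = PAUSE_ISI_FACTOR * float(np.median(np.diff(base)))
    start_idx = max(int(np.searchsorted(post, stim_onset)) - 1, 0)
    for i in range(start_idx, len(post) - 1):
        if post[i] > stim_onset + DELAYED_PAUSE_SEARCH_MS:
            break
        if post[i + 1] - post[i] > crit:
            return float(post[i] - stim_onset)
    return float("nan")


def sweep_input_duration(motif: str, n_spikes_range: Sequence[int],
                         isi_ms: float = 20.0, stim_onset: float = 2000.0,
                         duration: float = 6000.0, dt: float = 0.005,
                         settle_ms: float = 2000.0,
                         spec=None) -> pd.DataFrame:
    """Run a motif over presynaptic trains of 1–10 spikes; tidy table.

    One row per (input count, node) with burst/pause metrics; input
    duration is the stimulus span (n−1)·isi.
    """
    from .circuits import motif_circuit, run_circuit
    from .protocols import make_presyn_train

    if spec is None:
        spec = motif_circuit(motif)
    rows = []
    for n_sp in n_spikes_range:
        if not 1 <= n_sp <= 10:
            raise ValueError("n_spikes_range must lie within [1, 10]")
        stim = make_presyn_train(n_sp, isi_ms, stim_onset,
                                 window=(0.0, duration))
        res = run_circuit(spec, stim, dt=dt, duration=duration,
                          settle_ms=settle_ms)
        for node in spec.node_ids:
            train = res.spikes[node]
            cell = spec.cells[spec.node_ids.index(node)]
            row = {"motif": motif, "n_input_spikes": n_sp,
                   "input_duration_ms": (n_sp - 1) * isi_ms, "node": node,
                   "subtype": cell.subtype}
            if cell.subtype == "OFF":
                try:
                    row["pause_duration_ms"] = pause_duration(train,
                                                              stim_onset)
                except InvalidBaselineError:
                    # silent-at-baseline OFF cell (off-off motif): report
                    # the evoked (disinhibition) burst instead; firing
                    # resumes at the ~9 Hz pacemaker rate, so the burst
                    # termination floor is raised accordingly
                    dur, count = burst_duration(train, stim_onset,
                                                max_isi_ms=300.0)
                    row["burst_duration_ms"] = dur
                    row["n_spikes_evoked"] = count
            else:
                dur, count = burst_duration(train, stim_onset)
                row["burst_duration_ms"] = dur
                row["n_spikes_evoked"] = count
            rows.append(row)
    return pd.DataFrame(rows)
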