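"""Retrospective cardiac gating from a pulse-oximeter (PMU) trace.

The scanner's physiological monitoring unit records, for every imaging
readout, the time elapsed since the last pulse-oximeter trigger.  Plotted
against the acquisition clock this is a sawtooth: it ramps up during each
heart cycle and resets to ~0 at the next trigger.  This module detects the
resets (cycle starts), discards the pre-steady-state readouts, and bins every
remaining readout into one of ``n_phases`` cardiac phases so that k-space
lines can be sorted and averaged per phase.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError, GatingError

__all__ = [
    "PmuTrace",
    "CycleStats",
    "CardiacPhaseAssignment",
    "detect_pmu_peaks",
    "discard_steady_state",
    "assign_phases",
    "phase_duration",
]


@dataclass(frozen=True)
class PmuTrace:
    """Sampled time-since-last-trigger sawtooth, one sample per readout.

    Parameters
    ----------
    sample_time_ms : ndarray
        Strictly increasing acquisition clock of each readout (ms).
    value_ms : ndarray
        Time since the most recent pulse trigger at each sample (ms), >= 0.
    true_trigger_times_ms : ndarray or None
        Ground-truth trigger times when the trace comes from the simulator;
        ``None`` for traces read from disk.
    """

    sample_time_ms: np.ndarray
    value_ms: np.ndarray
    true_trigger_times_ms: np.ndarray | None = None

    def __post_init__(self):
        t = np.asarray(self.sample_time_ms, dtype=float)
        v = np.asarray(self.value_ms, dtype=float)
        if t.shape != v.shape or t.ndim != 1:
            raise ConfigurationError("sample_time_ms and value_ms must be equal-length 1-D")
        if t.size and np.any(np.diff(t) <= 0):
            raise ConfigurationError("sample_time_ms must be strictly increasing")
        if np.any(v < 0):
            raise ConfigurationError("PMU values must be non-negative")
        object.__setattr__(self, "sample_time_ms", t)
        object.__setattr__(self, "value_ms", v)

    def __len__(self) -> int:
        return self.sample_time_ms.size

    def slice(self, start: int, stop: int | None = None) -> "PmuTrace":
        return PmuTrace(
            self.sample_time_ms[start:stop],
            self.value_ms[start:stop],
            self.true_trigger_times_ms,
        )


@dataclass(frozen=True)
class CycleStats:
    """Detected cardiac cycles: trigger times and R-R statistics."""

    trigger_times_ms: np.ndarray
    rr_intervals_ms: np.ndarray = field(init=False)
    median_rr_ms: float = field(init=False)

    def __post_init__(self):
        trig = np.asarray(self.trigger_times_ms, dtype=float)
        object.__setattr__(self, "trigger_times_ms", trig)
        rr = np.diff(trig)
        if trig.size < 2:
            raise GatingError("need at least 2 triggers to form a cardiac cycle")
        if np.any(rr <= 0):
            raise GatingError("non-positive R-R interval among detected triggers")
        object.__setattr__(self, "rr_intervals_ms", rr)
        object.__setattr__(self, "median_rr_ms", float(np.median(rr)))

    @property
    def n_cycles(self) -> int:
        return self.rr_intervals_ms.size

    def phase_duration_ms(self, n_phases: int = 15) -> float:
        return phase_duration(self, n_phases)


@dataclass(frozen=True)
class CardiacPhaseAssignment:
    """Cardiac phase and cycle index per readout.

    ``phase_index``/``cycle_index`` are -1 where ``retained_mask`` is False
    (readouts before the first or after the last detected trigger).
    """

    phase_index: np.ndarray
    cycle_index: np.ndarray
    retained_mask: np.ndarray
    n_phases: int

    @property
    def phase_fractions(self) -> np.ndarray:
        """Fraction of retained readouts falling in each phase."""
        counts = np.bincount(self.phase_index[self.retained_mask], minlength=self.n_phases)
        return counts / max(counts.sum(), 1)


def detect_pmu_peaks(trace: PmuTrace) -> CycleStats:
    """Detect cardiac triggers at sawtooth resets with a local threshold.

    A reset is a sample whose value drops below its predecessor by more than
    half the running median of the last five cycles' peak values (the
    predecessor itself bootstraps the threshold before any cycle is seen).
    The trigger time is the time of the reset sample; the predecessor is the
    cycle's end-systolic peak.  A trace whose first sample is already within
    one sample interval of a trigger contributes an initial trigger as well.

    Raises
    ------
    GatingError
        If fewer than two triggers are found (no complete cycle).
    """
    if len(trace) < 2:
        raise GatingError("PMU trace too short for peak detection")
    t, v = trace.sample_time_ms, trace.value_ms
    triggers: list[float] = []
    if v[0] <= (t[1] - t[0]):
        # trace starts right at a cycle boundary
        triggers.append(float(t[0]))
    recent_peaks: deque[float] = deque(maxlen=5)
    drop_idx = np.flatnonzero(np.diff(v) < 0) + 1
    for i in drop_idx:
        ref = float(np.median(recent_peaks)) if recent_peaks else float(v[i - 1])
        if v[i - 1] - v[i] > 0.5 * ref:
            triggers.append(float(t[i]))
            recent_peaks.append(float(v[i - 1]))
    if len(triggers) < 2:
        raise GatingError(f"detected {len(triggers)} trigger(s); cannot bin cardiac phases")
    return CycleStats(np.asarray(triggers))


def discard_steady_state(series, trace: PmuTrace, n_discard_repetitions: int = 10):
    """Drop the first repetitions acquired before magnetization steady state.

    Removes ``n_discard_repetitions * n_pe`` readouts from the k-space series
    and the matching PMU samples.

    Returns
    -------
    (KSpaceSeries, PmuTrace, dict)
        Trimmed series, trimmed trace, and counts
        ``{"discarded_readouts", "retained_readouts"}``.
    """
    n_rep = series.n_repetitions
    if not 0 <= n_discard_repetitions < n_rep:
        raise ConfigurationError(
            f"cannot discard {n_discard_repetitions} of {n_rep} repetitions"
        )
    n_pe = series.n_pe
    n_drop = n_discard_repetitions * n_pe
    trimmed = series.drop_repetitions(n_discard_repetitions)
    if len(trace) < n_rep * n_pe:
        raise ConfigurationError("PMU trace shorter than the k-space series")
    new_trace = trace.slice(n_drop, n_rep * n_pe)
    counts = {
        "discarded_readouts": n_drop,
        "retained_readouts": (n_rep - n_discard_repetitions) * n_pe,
    }
    return trimmed, new_trace, counts


def assign_phases(
    trace: PmuTrace,
    stats: CycleStats,
    n_phases: int = 15,
    mode: str = "fraction",
) -> CardiacPhaseAssignment:
    """Bin each readout into one of ``n_phases`` cardiac phases.

    mode "fraction" (default): ``phase = floor(n_phases * value / RR_cycle)``
    using that readout's own cycle length, so all bins are populated in every
    cycle.  mode "absolute": fixed windows of ``median_rr / n_phases`` ms.
    Either way the result is clipped to ``n_phases - 1``.  Readouts before
    the first or after the last trigger are excluded via ``retained_mask``.

    Raises
    ------
    GatingError
        If more than half of the readouts cannot be assigned to a cycle.
    """
    if n_phases < 1:
        raise ConfigurationError("n_phases must be >= 1")
    if mode not in ("fraction", "absolute"):
        raise ConfigurationError(f"unknown gating mode {mode!r}")
    t, v = trace.sample_time_ms, trace.value_ms
    trig = stats.trigger_times_ms
    cyc = np.searchsorted(trig, t, side="right") - 1
    ok = (cyc >= 0) & (cyc < stats.n_cycles)
    if ok.size and np.count_nonzero(~ok) > 0.5 * ok.size:
        raise GatingError("more than 50% of readouts fall outside detected cycles")
    phase = np.full(t.shape, -1, dtype=int)
    cycle = np.where(ok, cyc, -1)
    if mode == "fraction":
        rr = stats.rr_intervals_ms[np.clip(cyc, 0, stats.n_cycles - 1)]
        ph = np.floor(n_phases * v / rr).astype(int)
    else:
        width = stats.median_rr_ms / n_phases
        ph = np.floor(v / width).astype(int)
    phase[ok] = np.clip(ph[ok], 0, n_phases - 1)
    return CardiacPhaseAssignment(phase, cycle, ok, n_phases)


def phase_duration(stats: CycleStats, n_phases: int) -> float:
    """Duration of one cardiac phase in ms: ``median_rr / n_phases``.

    At a heart rate of 1 beat/s and 15 phases this is 1000/15 = 66.7 ms
    (conventionally quoted as 67 ms); use :func:`round` for the integer-ms
    convenience value.
    """
    if n_phases < 1:
        raise ConfigurationError("n_phases must be >= 1")
    return stats.median_rr_ms / n_phases
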