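"""Egg-event-based behavior-state segmentation and state-resolved statistics.

The active state is defined operationally from egg-laying events: one minute
before the first and one minute after the last egg of a cluster; everything
else is inactive.  Transients are assigned to states by peak time (half-open
[start, end) membership) and inter-transient intervals are elapsed times
between successive peaks within one state.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "StateIntervals",
    "define_states",
    "assign_states",
    "inter_transient_intervals",
    "egg_coincidence",
]


@dataclass
class StateIntervals:
    intervals: list  # (start, end, label)
    egg_times: np.ndarray
    pad: float = 60.0
    span: tuple = (0.0, 0.0)

    def active(self) -> list:
        return [(s, e) for s, e, lab in self.intervals if lab == "active"]

    def inactive(self) -> list:
        return [(s, e) for s, e, lab in self.intervals if lab == "inactive"]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.intervals, columns=["start_s", "end_s", "label"])


def define_states(egg_times, recording_span, pad: float = 60.0,
                  merge_gap: float = 0.0) -> StateIntervals:
    """Active = [egg - pad, egg + pad] windows, merged when overlapping or
    within merge_gap, clipped to the recording; the complement is inactive."""
    t0, t1 = float(recording_span[0]), float(recording_span[1])
    if t1 < t0:
        raise ValueError("recording_span end precedes start")
    eggs = np.sort(np.asarray(egg_times, dtype=float))
    if eggs.size and (eggs[0] < t0 or eggs[-1] > t1):
        raise ValueError("egg times outside the recording span")
    windows = []
    for e in eggs:
        lo, hi = max(e - pad, t0), min(e + pad, t1)
        if windows and lo - windows[-1][1] <= merge_gap:
            windows[-1][1] = max(windows[-1][1], hi)
        else:
            windows.append([lo, hi])
    intervals = []
    cursor = t0
    for lo, hi in windows:
        if lo > cursor:
            intervals.append((cursor, lo, "inactive"))
        intervals.append((lo, hi, "active"))
        cursor = hi
    if cursor < t1 or not intervals:
        intervals.append((cursor, t1, "inactive"))
    return StateIntervals(intervals=intervals, egg_times=eggs, pad=pad, span=(t0, t1))


def _interval_index(times: np.ndarray, states: StateIntervals):
    """Index of the containing interval ([start, end) convention) per time."""
    starts = np.array([s for s, _, _ in states.intervals])
    idx = np.searchsorted(starts, times, side="right") - 1
    idx = np.clip(idx, 0, len(states.intervals) - 1)
    return idx


def assign_states(transients: pd.DataFrame, states: StateIntervals) -> pd.DataFrame:
    """Label each transient active/inactive by peak-time membership."""
    out = transients.copy()
    if len(out) == 0:
        out["state"] = pd.Series(dtype=object)
        return out
    times = out["peak_time"].to_numpy()
    idx = _interval_index(times, states)
    labels = np.array([states.intervals[i][2] for i in idx], dtype=object)
    # times before the first interval start are out of the recording span
    before = times < states.intervals[0][0]
    after = times >= states.intervals[-1][1]
    labels[before | after] = "unassigned"
    out["state"] = labels
    return out


def inter_transient_intervals(transients: pd.DataFrame,
                              states: StateIntervals) -> pd.DataFrame:
    """Elapsed times between successive peaks within each state interval.

    Pairs spanning a state boundary are excluded.  When the recording has
    inactive time before the first transient or after the last one, those
    elapsed times are included as inactive-state intervals (the operational
    boundary rule for quiet stretches).
    """
    t0, t1 = states.span
    df = transients.sort_values("peak_time")
    times = df["peak_time"].to_numpy()
    rows = []
    for (s, e, lab) in states.intervals:
        inside = times[(times >= s) & (times < e)]
        for d in np.diff(inside):
            rows.append((lab, float(d)))
    if times.size:
        if times[0] > t0 and _has_inactive_time(states, t0, times[0]):
            rows.append(("inactive", float(times[0] - t0)))
        if times[-1] < t1 and _has_inactive_time(states, times[-1], t1):
            rows.append(("inactive", float(t1 - times[-1])))
    return pd.DataFrame(rows, columns=["state", "interval_s"])


def _has_inactive_time(states: StateIntervals, lo, hi) -> bool:
    return any(max(s, lo) < min(e, hi) for s, e in states.inactive())


def egg_coincidence(transients: pd.DataFrame, egg_times) -> dict:
    """Flag egg-coupled transients and summarize coupling both ways.

    A transient is egg-coupled iff some egg time falls within its half-max
    span [onset, offset]; an egg is covered iff it falls inside some span.
    Returns the flagged table plus the fraction of transients coupled and the
    fraction of eggs covered.
    """
    eggs = np.sort(np.asarray(egg_times, dtype=float))
    out = transients.copy()
    if len(out):
        onset = out["onset"].to_numpy()
        offset = out["offset"].to_numpy()
        coupled = np.array([
            bool(np.any((eggs >= a) & (eggs <= b))) for a, b in zip(onset, offset)
        ]) if eggs.size else np.zeros(len(out), dtype=bool)
        out["egg_coupled"] = coupled
        covered = np.array([
            bool(np.any((egg >= onset) & (egg <= offset))) for egg in eggs
        ]) if eggs.size else np.empty(0, dtype=bool)
    else:
        out["egg_coupled"] = pd.Series(dtype=bool)
        covered = np.zeros(eggs.size, dtype=bool)
    frac_transients = float(out["egg_coupled"].mean()) if len(out) else np.nan
    frac_eggs = float(covered.mean()) if eggs.size else np.nan
    return {
        "transients": out,
        "fraction_transients_egg_coupled": frac_transients,
        "fraction_eggs_covered": frac_eggs,
        "n_transients": int(len(out)),
        "n_eggs": int(eggs.size),
    }
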