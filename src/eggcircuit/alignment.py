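"""Egg-release-triggered trace alignment and peri-event locomotion speed.

Snippets of normalized dR/R (peak scaled to 100%) are synchronized to the
moment of egg release (t = 0); the pointwise median trace and per-event peak
offsets summarize the relative timing of activity across cell types.  The
same machinery aligns object-size (muscle contraction) traces and centroid
speed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "AlignedEnsemble",
    "align_to_eggs",
    "align_size_to_eggs",
    "peri_event_speed",
]


@dataclass
class AlignedEnsemble:
    grid: np.ndarray               # time relative to egg release (s)
    matrix: np.ndarray             # events x samples, normalized
    median_trace: np.ndarray
    peak_offsets: np.ndarray       # s relative to egg release (negative = before)
    event_times: np.ndarray
    n_excluded: int = 0

    @property
    def n_events(self) -> int:
        return self.matrix.shape[0]

    def median_peak_offset(self) -> float:
        return float(np.median(self.peak_offsets)) if self.peak_offsets.size else np.nan


def _snippets(x: np.ndarray, frame_rate: float, egg_times, window: float):
    k = int(round(window * frame_rate))
    grid = np.arange(-k, k + 1) / frame_rate
    rows, kept, excluded = [], [], 0
    for egg in np.asarray(egg_times, dtype=float):
        i0 = int(round(egg * frame_rate))
        if i0 - k < 0 or i0 + k >= x.size:
            excluded += 1
            continue
        rows.append(x[i0 - k: i0 + k + 1].copy())
        kept.append(egg)
    return grid, rows, np.asarray(kept), excluded


def align_to_eggs(trace, egg_times, window: float = 10.0,
                  transient_peaks=None) -> AlignedEnsemble:
    """Align dR/R snippets to egg release, each normalized so its peak = 100%.

    ``transient_peaks`` (detected peak times) sharpen the per-event peak
    offsets; otherwise the snippet argmax is used.  Events without a full
    window inside the recording are excluded (counted).
    """
    if trace.droverr is None:
        raise ValueError("trace has no dR/R; run compute_baseline first")
    grid, rows, kept, excluded = _snippets(trace.droverr, trace.frame_rate,
                                           egg_times, window)
    norm_rows, offsets = [], []
    peaks = np.sort(np.asarray(transient_peaks)) if transient_peaks is not None else None
    for egg, row in zip(kept, rows):
        peak = row.max()
        norm_rows.append(100.0 * row / peak if peak > 0 else row * 0.0)
        if peaks is not None and peaks.size:
            offsets.append(float(peaks[np.argmin(np.abs(peaks - egg))] - egg))
        else:
            offsets.append(float(grid[int(np.argmax(row))]))
    matrix = np.vstack(norm_rows) if norm_rows else np.empty((0, grid.size))
    median = np.median(matrix, axis=0) if matrix.size else np.full(grid.size, np.nan)
    return AlignedEnsemble(grid=grid, matrix=matrix, median_trace=median,
                           peak_offsets=np.asarray(offsets), event_times=kept,
                           n_excluded=excluded)


def align_size_to_eggs(size_trace: np.ndarray, frame_rate: float, egg_times,
                       window: float = 10.0) -> AlignedEnsemble:
    """Align object-size snippets to egg release, normalized to each snippet's
    pre-event mean (= 100%)."""
    x = np.asarray(size_trace, dtype=float)
    grid, rows, kept, excluded = _snippets(x, frame_rate, egg_times, window)
    norm_rows, offsets = [], []
    pre = grid < 0
    for row in rows:
        base = row[pre].mean()
        norm_rows.append(100.0 * row / base if base > 0 else row * 0.0)
        offsets.append(float(grid[int(np.argmin(row))]))  # size dips at egg release
    matrix = np.vstack(norm_rows) if norm_rows else np.empty((0, grid.size))
    median = np.median(matrix, axis=0) if matrix.size else np.full(grid.size, np.nan)
    return AlignedEnsemble(grid=grid, matrix=matrix, median_trace=median,
                           peak_offsets=np.asarray(offsets), event_times=kept,
                           n_excluded=excluded)


def peri_event_speed(track, egg_times, window: float = 10.0,
                     smooth_window: int = 3) -> dict:
    """Mean centroid speed about egg-laying events with a pointwise 95% CI.

    ``track`` is a DataFrame-like with columns time_s, x, y sampled on a
    regular grid.  Speed is centroid displacement per frame divided by the
    frame interval, smoothed by a centered ``smooth_window``-point average.
    Also reports paired t comparisons of speed at 0 s vs -1 s and vs +1 s.
    """
    t = np.asarray(track["time_s"], dtype=float)
    x = np.asarray(track["x"], dtype=float)
    y = np.asarray(track["y"], dtype=float)
    if t.size < 3:
        raise ValueError("track too short")
    dt = np.median(np.diff(t))
    frame_rate = 1.0 / dt
    speed = np.hypot(np.diff(x), np.diff(y)) / dt
    speed = np.concatenate([[speed[0]], speed])  # align to sample times
    if np.isnan(speed).any():
        # exclude snippets touching gaps by leaving NaNs in place
        pass
    if smooth_window > 1:
        import pandas as pd

        speed = (pd.Series(speed).rolling(smooth_window, center=True, min_periods=1)
                 .mean().to_numpy())
    grid, rows, kept, excluded = _snippets(speed, frame_rate, egg_times, window)
    rows = [r for r in rows if not np.isnan(r).any()]
    if not rows:
        raise ValueError("no egg events with a full, gap-free window")
    matrix = np.vstack(rows)
    mean = matrix.mean(axis=0)
    n = matrix.shape[0]
    if n >= 2:
        sem = matrix.std(axis=0, ddof=1) / np.sqrt(n)
        tcrit = stats.t.ppf(0.975, n - 1)
        ci = (mean - tcrit * sem, mean + tcrit * sem)
    else:
        warnings.warn("single event: confidence interval undefined")
        ci = (np.full_like(mean, np.nan), np.full_like(mean, np.nan))
    out = {
        "grid": grid, "mean_speed": mean, "ci_low": ci[0], "ci_high": ci[1],
        "n_events": n, "n_excluded": excluded,
    }
    i0 = int(np.argmin(np.abs(grid)))
    for lag, key in ((-1.0, "p_vs_minus1s"), (1.0, "p_vs_plus1s")):
        j = int(np.argmin(np.abs(grid - lag)))
        if n >= 2 and not np.allclose(matrix[:, i0], matrix[:, j]):
            out[key] = float(stats.ttest_rel(matrix[:, i0], matrix[:, j]).pvalue)
        else:
            out[key] = np.nan if n < 2 else 1.0
    return out
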