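"""Object detection and area-adjusted ratio extraction from image stacks.

Pixels with mCherry intensity about two standard deviations above background
are selected as objects; connected components become per-frame objects, and
the joined ratio is the area-weighted mean of per-object mean pixel ratios.
The total object area doubles as a muscle-size (contraction) readout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .traces import RatioTrace

__all__ = [
    "FrameObjects",
    "estimate_background",
    "detect_objects",
    "join_objects",
    "extract_trace",
]

EIGHT_CONN = np.ones((3, 3), dtype=int)


@dataclass
class FrameObjects:
    objects: list = field(default_factory=list)  # dicts with pixel_count, means
    background_mean: float = np.nan
    background_sd: float = np.nan

    def __len__(self):
        return len(self.objects)


def estimate_background(mcherry_frame: np.ndarray) -> tuple[float, float]:
    """Two-pass robust background estimate.

    Pass 1: mean/SD over all pixels; pass 2: mean/SD over pixels at or below
    pass-1 mean + 2 SD (discarding bright ROIs).  A constant frame returns
    (value, 0).
    """
    x = np.asarray(mcherry_frame, dtype=float).ravel()
    if x.size == 0:
        raise ValueError("empty frame")
    m1, s1 = x.mean(), x.std()
    low = x[x <= m1 + 2.0 * s1]
    if low.size == 0:
        return float(m1), float(s1)
    return float(low.mean()), float(low.std())


def detect_objects(gcamp_frame: np.ndarray, mcherry_frame: np.ndarray,
                   background: tuple[float, float],
                   min_object_px: int = 5) -> FrameObjects:
    """Threshold the mCherry channel at background mean + 2 SD and collect
    8-connected components of at least ``min_object_px`` pixels."""
    g = np.asarray(gcamp_frame, dtype=float)
    m = np.asarray(mcherry_frame, dtype=float)
    if g.shape != m.shape:
        raise ValueError("channel shapes differ")
    bg_mean, bg_sd = background
    mask = m > bg_mean + 2.0 * bg_sd
    labels, n_lab = ndimage.label(mask, structure=EIGHT_CONN)
    objects = []
    if n_lab:
        counts = np.bincount(labels.ravel())
        for lab in range(1, n_lab + 1):
            if counts[lab] < min_object_px:
                continue
            sel = labels == lab
            gm = float(g[sel].mean())
            mm = float(m[sel].mean())
            objects.append({
                "pixel_count": int(counts[lab]),
                "mean_gcamp": gm,
                "mean_mcherry": mm,
                "mean_ratio": float((g[sel] / m[sel]).mean()),
            })
    return FrameObjects(objects=objects, background_mean=bg_mean, background_sd=bg_sd)


def join_objects(frame_objects: FrameObjects) -> tuple[float, int]:
    """Area-adjusted join: ratio = sum(area_i * ratio_i) / sum(area_i)."""
    if len(frame_objects) == 0:
        raise ValueError("no objects to join")
    areas = np.array([o["pixel_count"] for o in frame_objects.objects], dtype=float)
    ratios = np.array([o["mean_ratio"] for o in frame_objects.objects])
    return float(np.sum(areas * ratios) / np.sum(areas)), int(np.sum(areas))


def extract_trace(gcamp_stack: np.ndarray, mcherry_stack: np.ndarray,
                  frame_rate: float, cell_type: str = "unknown",
                  min_object_px: int = 5, max_gap_frames: int = 10,
                  max_missing_fraction: float = 0.5,
                  background: str = "per_frame"):
    """Per-frame background, detection and join over a two-channel stack.

    Returns (RatioTrace, total_area array, qc dict).  Frames with no object
    become missing values; gaps of at most ``max_gap_frames`` are linearly
    interpolated, longer gaps stay missing (NaN).  Aborts when more than
    ``max_missing_fraction`` of frames are missing.
    """
    g = np.asarray(gcamp_stack, dtype=float)
    m = np.asarray(mcherry_stack, dtype=float)
    if g.shape != m.shape:
        raise ValueError("stacks must have identical shapes")
    if background not in ("per_frame", "per_recording"):
        raise ValueError("background must be 'per_frame' or 'per_recording'")
    n = g.shape[0]
    ratio = np.full(n, np.nan)
    area = np.zeros(n)
    flagged = []
    bg_stats = []
    bg_global = estimate_background(m) if background == "per_recording" else None
    for i in range(n):
        bg = bg_global if bg_global is not None else estimate_background(m[i])
        bg_stats.append(bg)
        objs = detect_objects(g[i], m[i], bg, min_object_px=min_object_px)
        if len(objs) == 0:
            flagged.append(i)
            continue
        ratio[i], area[i] = join_objects(objs)
    missing = np.isnan(ratio)
    if missing.mean() > max_missing_fraction:
        raise ValueError(
            f"{missing.mean():.0%} of frames have no detectable object "
            f"(limit {max_missing_fraction:.0%})"
        )
    gap_lengths = _gap_lengths(missing)
    filled = pd.Series(ratio).interpolate(limit=max_gap_frames,
                                          limit_area="inside").to_numpy()
    trace = RatioTrace(
        time=np.arange(n) / frame_rate, ratio=filled,
        frame_rate=frame_rate, cell_type=cell_type,
    )
    qc = {
        "frames_flagged": flagged,
        "n_missing": int(missing.sum()),
        "gap_lengths": gap_lengths,
        "background_mean": float(np.mean([b[0] for b in bg_stats])),
        "background_sd": float(np.mean([b[1] for b in bg_stats])),
    }
    return trace, area, qc


def _gap_lengths(missing: np.ndarray) -> list:
    lengths, run = [], 0
    for flag in missing:
        if flag:
            run += 1
        elif run:
            lengths.append(run)
            run = 0
    if run:
        lengths.append(run)
    return lengths
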