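"""Readers and writers for the pipeline's plain-text interchange formats."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .traces import RatioTrace

__all__ = [
    "write_traces_csv", "read_traces_csv",
    "write_annotations_csv", "read_annotations_csv",
    "write_ground_truth_json", "read_ground_truth_json",
    "write_stack_tiff", "read_stack_tiff",
]

EVENT_TYPES = ("egg", "ventral_contraction", "ventral_relaxation")


def write_traces_csv(path, recordings: dict) -> None:
    """Traces CSV with columns time_s, gcamp, mcherry, cell_type."""
    frames = []
    for cell, rec in recordings.items():
        frames.append(pd.DataFrame({
            "time_s": rec.time, "gcamp": rec.gcamp, "mcherry": rec.mcherry,
            "cell_type": cell,
        }))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_traces_csv(path, frame_rate: float | None = None) -> dict:
    """Returns cell_type -> RatioTrace built from gcamp/mcherry columns."""
    df = pd.read_csv(path)
    out = {}
    for cell, grp in df.groupby("cell_type"):
        t = grp["time_s"].to_numpy()
        fr = frame_rate or (1.0 / np.median(np.diff(t)) if t.size > 1 else 20.0)
        out[cell] = RatioTrace(
            time=t, ratio=grp["gcamp"].to_numpy() / grp["mcherry"].to_numpy(),
            frame_rate=float(fr), cell_type=str(cell),
        )
    return out


def write_annotations_csv(path, egg_times, landmark_times=None,
                          landmark_kinds=None) -> None:
    rows = [(float(t), "egg") for t in np.asarray(egg_times, dtype=float)]
    if landmark_times is not None:
        for t, kind in zip(landmark_times, landmark_kinds):
            rows.append((float(t), f"ventral_{kind}"))
    df = pd.DataFrame(sorted(rows), columns=["time_s", "event_type"])
    df.to_csv(path, index=False)


def read_annotations_csv(path) -> dict:
    df = pd.read_csv(path)
    bad = set(df["event_type"]) - set(EVENT_TYPES)
    if bad:
        raise ValueError(f"unknown event types in annotations: {sorted(bad)}")
    eggs = df.loc[df.event_type == "egg", "time_s"].to_numpy()
    lm = df[df.event_type.str.startswith("ventral_")].sort_values("time_s")
    return {
        "egg_times": np.sort(eggs),
        "landmark_times": lm["time_s"].to_numpy(),
        "landmark_kinds": lm["event_type"].str.removeprefix("ventral_")
                            .to_numpy(dtype=object),
    }


def write_ground_truth_json(path, truth) -> None:
    payload = {
        "duration": truth.duration,
        "state_intervals": [[s, e, lab] for s, e, lab in truth.state_intervals],
        "bend_landmarks": [[float(t), str(k)] for t, k in truth.bend_landmarks],
        "egg_times": truth.egg_times.tolist(),
        "transients": {
            cell: df.to_dict(orient="list") for cell, df in truth.transients.items()
        },
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_ground_truth_json(path) -> dict:
    return json.loads(Path(path).read_text())


def write_stack_tiff(path, gcamp_stack, mcherry_stack, frame_rate: float) -> None:
    """Channel-interleaved 16-bit TIFF: axis order (frame, channel, y, x) with
    channel 0 = GCaMP, 1 = mCherry; frame order in the JSON sidecar."""
    import tifffile

    stack = np.stack([gcamp_stack, mcherry_stack], axis=1)
    stack = np.clip(np.round(stack), 0, 65535).astype(np.uint16)
    tifffile.imwrite(path, stack, metadata=None)
    sidecar = Path(str(path) + ".json")
    sidecar.write_text(json.dumps({
        "axes": "TCYX", "channels": ["gcamp", "mcherry"],
        "frame_rate": frame_rate, "dtype": "uint16",
    }))


def read_stack_tiff(path):
    import tifffile

    stack = tifffile.imread(path).astype(float)
    if stack.ndim == 3 and stack.shape[0] % 2 == 0:
        # pages stored flat: re-interleave into (frames, channel, y, x)
        stack = stack.reshape(-1, 2, *stack.shape[1:])
    if stack.ndim != 4 or stack.shape[1] != 2:
        raise ValueError("expected a (frames, 2, height, width) stack")
    sidecar = Path(str(path) + ".json")
    frame_rate = 20.0
    if sidecar.exists():
        frame_rate = float(json.loads(sidecar.read_text()).get("frame_rate", 20.0))
    return stack[:, 0], stack[:, 1], frame_rate
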