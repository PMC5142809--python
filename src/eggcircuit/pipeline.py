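"""End-to-end orchestration: preprocessing, detection, segmentation, rhythm,
phase and alignment in one reproducible call, plus group comparisons."""

from __future__ import annotations

import hashlib
import json

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from . import phase as phase_mod
from . import rhythm, states, traces

__all__ = ["analyze_recording", "summarize", "compare_groups", "config_hash"]

DEFAULT_PARAMS = {
    "smooth_window_s": 0.150,
    "min_prominence_sigmas": 4.0,
    "min_separation_s": 0.5,
    "state_pad_s": 60.0,
    "merge_gap_s": 0.0,
    "min_segment_s": 30.0,
    "band_mhz": (0.0, 250.0),
    "align_window_s": 10.0,
    "bin_width_deg": 45.0,
}


def analyze_recording(trace: traces.RatioTrace, egg_times,
                      landmark_times=None, landmark_kinds=None,
                      params: dict | None = None) -> dict:
    """Run the full single-recording analysis for one cell type.

    Returns a bundle with the processed trace, the transient table (state
    labels, egg coupling, phases, normalized amplitudes), state intervals,
    interval samples, per-segment periodogram dominant peaks, phase histogram,
    and the egg-aligned ensemble.
    """
    p = dict(DEFAULT_PARAMS)
    if params:
        unknown = set(params) - set(DEFAULT_PARAMS)
        if unknown:
            raise ValueError(f"unknown analysis parameters: {sorted(unknown)}")
        p.update(params)
    egg_times = np.sort(np.asarray(egg_times, dtype=float))
    span = (float(trace.time[0]), float(trace.time[-1]) + 1.0 / trace.frame_rate)
    if egg_times.size and (egg_times[0] < span[0] or egg_times[-1] > span[1]):
        raise ValueError("egg times outside the trace time range")

    proc = traces.process_trace(trace, p["smooth_window_s"])
    tr = traces.detect_transients(proc, p["min_prominence_sigmas"],
                                  p["min_separation_s"])
    st = states.define_states(egg_times, span, pad=p["state_pad_s"],
                              merge_gap=p["merge_gap_s"])
    tr = states.assign_states(tr, st)
    coincidence = states.egg_coincidence(tr, egg_times)
    tr = coincidence.pop("transients")
    if len(tr):
        tr = traces.normalize_amplitudes(tr)
    intervals = states.inter_transient_intervals(tr, st)

    dominant = []
    for s, e, seg in rhythm.active_segments(proc, st, p["min_segment_s"]):
        pg = rhythm.periodogram_fft(seg, proc.frame_rate, span=(s, e))
        f, pw = rhythm.dominant_peak(pg, p["band_mhz"])
        dominant.append({"start_s": s, "end_s": e, "frequency_mhz": f,
                         "power": pw, "grid_mhz": pg.grid_spacing_mhz})
    dominant = pd.DataFrame(dominant)

    if landmark_times is not None and len(landmark_times) >= 2 and len(tr):
        tr["phase_deg"] = phase_mod.assign_phases(
            tr["peak_time"].to_numpy(), landmark_times, landmark_kinds
        )
    elif "phase_deg" not in tr.columns:
        tr["phase_deg"] = np.nan
    phases = tr["phase_deg"].dropna().to_numpy()
    edges, hist_pct = phase_mod.bin_phases(phases, p["bin_width_deg"])

    from .alignment import align_to_eggs

    ensemble = align_to_eggs(proc, egg_times, p["align_window_s"],
                             transient_peaks=tr["peak_time"].to_numpy()
                             if len(tr) else None) if egg_times.size else None

    return {
        "trace": proc,
        "transients": tr,
        "states": st,
        "intervals": intervals,
        "egg_coincidence": coincidence,
        "dominant_peaks": dominant,
        "phase_bin_edges": edges,
        "phase_histogram_pct": hist_pct,
        "aligned": ensemble,
        "params": p,
    }


def summarize(bundle: dict) -> dict:
    """JSON-serializable summary of one analysis bundle."""
    tr = bundle["transients"]
    intervals = bundle["intervals"]
    out = {
        "n_transients": int(len(tr)),
        "n_eggs": bundle["egg_coincidence"]["n_eggs"],
        "fraction_transients_egg_coupled":
            bundle["egg_coincidence"]["fraction_transients_egg_coupled"],
        "fraction_eggs_covered":
            bundle["egg_coincidence"]["fraction_eggs_covered"],
        "phase_histogram_pct": list(map(float, bundle["phase_histogram_pct"])),
        "params": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in bundle["params"].items()},
    }
    for label in ("active", "inactive"):
        vals = intervals.loc[intervals.state == label, "interval_s"]
        out[f"{label}_interval_median_s"] = float(vals.median()) if len(vals) else None
        out[f"{label}_interval_quartiles_s"] = (
            [float(q) for q in vals.quantile([0.25, 0.75])] if len(vals) else None
        )
        out[f"{label}_interval_n"] = int(len(vals))
    dom = bundle["dominant_peaks"]
    out["dominant_frequency_mhz_median"] = (
        float(dom["frequency_mhz"].median()) if len(dom) else None
    )
    out["n_active_segments"] = int(len(dom))
    ens = bundle["aligned"]
    out["median_peak_offset_s"] = ens.median_peak_offset() if ens is not None else None
    return out


def _dunn_pairwise(groups: dict) -> pd.DataFrame:
    """Dunn's rank-sum z tests after Kruskal-Wallis, Bonferroni-adjusted."""
    names = list(groups)
    samples = [np.asarray(groups[g], dtype=float) for g in names]
    all_vals = np.concatenate(samples)
    n_total = all_vals.size
    ranks = sps.rankdata(all_vals)
    # tie correction term
    _, counts = np.unique(all_vals, return_counts=True)
    tie_term = (counts**3 - counts).sum() / (12.0 * (n_total - 1)) if n_total > 1 else 0.0
    mean_ranks, sizes, start = {}, {}, 0
    for g, s in zip(names, samples):
        mean_ranks[g] = ranks[start:start + s.size].mean()
        sizes[g] = s.size
        start += s.size
    rows = []
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            var = (n_total * (n_total + 1) / 12.0 - tie_term) * (
                1.0 / sizes[a] + 1.0 / sizes[b]
            )
            z = (mean_ranks[a] - mean_ranks[b]) / np.sqrt(var)
            p = 2.0 * sps.norm.sf(abs(z))
            rows.append({"group_a": a, "group_b": b, "z": float(z), "p_raw": float(p)})
    df = pd.DataFrame(rows)
    df["p_adjusted"] = multipletests(df["p_raw"], method="bonferroni")[1]
    return df


def compare_groups(groups: dict, measures=("interval_s", "amplitude", "fwhm")) -> dict:
    """Compare pooled transient-level samples across >= 2 groups.

    Each group maps measure name -> 1-D sample.  Two groups: Mann-Whitney;
    more: Kruskal-Wallis plus Dunn-adjusted pairwise table.  Medians and
    quartiles are reported per group; empty samples skip that comparison with
    a note.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    results = {}
    for measure in measures:
        data = {g: np.asarray(v.get(measure, []), dtype=float)
                for g, v in groups.items()}
        data = {g: v[~np.isnan(v)] for g, v in data.items()}
        empty = [g for g, v in data.items() if v.size == 0]
        entry = {
            "medians": {g: float(np.median(v)) if v.size else None
                        for g, v in data.items()},
            "quartiles": {g: [float(q) for q in np.percentile(v, [25, 75])]
                          if v.size else None for g, v in data.items()},
            "n": {g: int(v.size) for g, v in data.items()},
        }
        if empty:
            entry["note"] = f"skipped: empty sample in {empty}"
        elif len(data) == 2:
            a, b = data.values()
            if np.array_equal(a, b):
                entry["test"], entry["p_value"] = "mann-whitney", 1.0
            else:
                entry["test"] = "mann-whitney"
                entry["p_value"] = float(
                    sps.mannwhitneyu(a, b, alternative="two-sided").pvalue
                )
        else:
            entry["test"] = "kruskal-wallis + dunn"
            entry["p_value"] = float(sps.kruskal(*data.values()).pvalue)
            entry["pairwise"] = _dunn_pairwise(data).to_dict(orient="records")
        results[measure] = entry
    return results


def config_hash(payload) -> str:
    """Stable hash of a JSON-serializable configuration for run manifests."""
    return hashlib.sha256(
        json.dumps(payload, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]
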