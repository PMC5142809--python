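"""Canonical study conditions and cohort-level parameter-recovery runs.

The wild-type configuration is the package default: HSN transients ~4 s at
half-max on a 20 s (50 mHz) active-state rhythm with a 17 s mean interval and
41 s inactive intervals; vulval-muscle twitches locked to the ~10 s body-bend
cycle (100 mHz) with 4x egg transients; ~20 min inactive and ~2 min active
states at 20 frames/s.  The tyramine-receptor-mutant condition shortens HSN
intervals to 13 s active / 22 s inactive.

Cohorts pool many hour-long recordings (different spawned seeds, as the
published analyses pool animals) and run the full pipeline on each.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from . import pipeline, synthetic, traces

__all__ = [
    "wildtype_config",
    "lgc55_mutant_config",
    "run_cohort",
    "ground_truth_intervals",
]

COHORT_RECORDINGS = 70
COHORT_DURATION_S = 3600.0


def wildtype_config(seed: int = 1, duration: float = COHORT_DURATION_S,
                    **overrides) -> synthetic.SimConfig:
    """Default wild-type study conditions."""
    return synthetic.default_config(seed=seed, duration=duration, **overrides)


def lgc55_mutant_config(seed: int = 1, duration: float = COHORT_DURATION_S,
                        **overrides) -> synthetic.SimConfig:
    """Condition without tyramine feedback onto HSN: more frequent HSN
    transients (13 s active, 22 s inactive mean intervals)."""
    cfg = wildtype_config(seed=seed, duration=duration, **overrides)
    cells = dict(cfg.cell_params)
    cells["HSN"] = replace(cells["HSN"], active_interval_mean=13.0,
                           inactive_interval_mean=22.0)
    return replace(cfg, cell_params=cells)


def _sub_seeds(seed: int, n: int) -> np.ndarray:
    """Per-recording seeds derived reproducibly from one master seed."""
    return np.random.SeedSequence(seed).generate_state(n) % (2**31)


def run_cohort(seed: int = 1, n_recordings: int = COHORT_RECORDINGS,
               duration: float = COHORT_DURATION_S,
               cells=("HSN", "vm"), config_factory=wildtype_config) -> dict:
    """Simulate, render and analyze a cohort of recordings; pool the results.

    Returns pooled active/inactive interval samples, per-segment dominant
    periodogram frequencies, and egg-coupling fractions per cell type.
    """
    pooled = {c: {"active_intervals": [], "inactive_intervals": [],
                  "dominant_mhz": [], "eggs_covered": [], "n_transients": 0}
              for c in cells}
    n_eggs = 0
    n_segments = 0
    for s in _sub_seeds(seed, n_recordings):
        cfg = config_factory(seed=int(s), duration=duration)
        truth = synthetic.simulate_behavior(cfg)
        n_eggs += truth.egg_times.size
        recs = synthetic.render_traces(truth, cfg, cells=cells)
        for cell in cells:
            raw = traces.RatioTrace.from_recording(recs[cell])
            bundle = pipeline.analyze_recording(raw, truth.egg_times)
            iv = bundle["intervals"]
            p = pooled[cell]
            p["active_intervals"].extend(
                iv.loc[iv.state == "active", "interval_s"].tolist())
            p["inactive_intervals"].extend(
                iv.loc[iv.state == "inactive", "interval_s"].tolist())
            p["dominant_mhz"].extend(
                bundle["dominant_peaks"]["frequency_mhz"].tolist()
                if len(bundle["dominant_peaks"]) else [])
            cov = bundle["egg_coincidence"]["fraction_eggs_covered"]
            if not np.isnan(cov):
                p["eggs_covered"].append(cov)
            p["n_transients"] += len(bundle["transients"])
            if cell == cells[0]:
                n_segments += len(bundle["dominant_peaks"])
    out = {"n_recordings": n_recordings, "n_eggs": int(n_eggs),
           "n_active_segments": int(n_segments), "cells": {}}
    for cell in cells:
        p = pooled[cell]
        act = np.asarray(p["active_intervals"])
        out["cells"][cell] = {
            "active_interval_mean_s": float(act.mean()) if act.size else np.nan,
            "active_interval_n": int(act.size),
            "inactive_interval_n": int(len(p["inactive_intervals"])),
            "median_dominant_mhz": float(np.median(p["dominant_mhz"]))
            if p["dominant_mhz"] else np.nan,
            "n_segments": int(len(p["dominant_mhz"])),
            "n_transients": int(p["n_transients"]),
        }
    return out


def interval_power_study(seed: int = 1, n_runs: int = 100,
                         n_per_group: int = 100, alpha: float = 0.05) -> dict:
    """Fraction of seeded runs where the wild-type vs mutant HSN active-state
    interval samples (17 s vs 13 s means) differ by Mann-Whitney at alpha.

    Works at simulator ground-truth level (only the HSN train and eggs are
    simulated) through the state-definition and interval machinery.
    """
    from scipy.stats import mannwhitneyu

    def only_hsn(factory):
        def f(seed, duration):
            cfg = factory(seed=seed, duration=duration)
            return replace(cfg, cell_params={"HSN": cfg.cell_params["HSN"]})
        return f

    run_seeds = _sub_seeds(seed, n_runs)
    hits = 0
    for s in run_seeds:
        wt = ground_truth_intervals(only_hsn(wildtype_config), int(s),
                                    min_intervals=n_per_group)
        mut = ground_truth_intervals(only_hsn(lgc55_mutant_config), int(s) + 1,
                                     min_intervals=n_per_group)
        p = mannwhitneyu(wt, mut, alternative="two-sided").pvalue
        hits += p < alpha
    return {"fraction_significant": hits / n_runs, "n_runs": n_runs,
            "alpha": alpha}


def ground_truth_intervals(config_factory, seed: int, min_intervals: int = 100,
                           cell: str = "HSN", chunk_s: float = 36000.0,
                           max_chunks: int = 12) -> np.ndarray:
    """Active-state inter-transient intervals computed from simulator ground
    truth through the state-definition machinery (no rendering/detection).

    Used for statistical power studies where only the interval sample matters.
    """
    from . import states as st_mod

    rng_seeds = _sub_seeds(seed, max_chunks)
    samples: list[float] = []
    for s in rng_seeds:
        cfg = config_factory(seed=int(s), duration=chunk_s)
        truth = synthetic.simulate_behavior(cfg)
        span = (0.0, cfg.duration)
        st = st_mod.define_states(truth.egg_times, span)
        df = truth.transients[cell]
        labeled = st_mod.assign_states(df, st)
        iv = st_mod.inter_transient_intervals(labeled, st)
        samples.extend(iv.loc[iv.state == "active", "interval_s"].tolist())
        if len(samples) >= min_intervals:
            break
    return np.asarray(samples[: max(min_intervals, len(samples))])
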