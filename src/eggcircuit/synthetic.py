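"""Ground-truthed synthetic recordings of the egg-laying circuit.

The generator emulates the statistical structure of ratiometric GCaMP5/mCherry
recordings of the *C. elegans* egg-laying circuit in behaving animals:

* behavior alternates between long inactive states (~20 min) and short active
  states (~2 min) during which eggs are laid;
* each cell type produces Ca2+ transients with characteristic half-max widths
  and state-dependent inter-transient intervals (HSN ~4 s wide, rhythmic at
  ~20 s in the active state; VC ~2 s wide, ~10 s apart; vulval-muscle twitches
  locked to the ~10 s body-bend cycle, with egg-laying transients ~4x larger;
  uv1 transients triggered by egg release);
* egg release coincides with an HSN transient, is accompanied by a VC
  transient, and occurs at characteristic body-bend phases;
* the two fluorescence channels share a multiplicative motion artifact and
  carry independent additive noise, sampled at 20 frames/s.

Every realization carries its ground truth (state timeline, body-bend
landmarks, egg times, per-cell transient trains with phases), so each analysis
stage downstream can be tested by parameter recovery without external data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "PhaseLock",
    "CellParams",
    "NoiseParams",
    "ImageParams",
    "SimConfig",
    "GroundTruth",
    "TwoChannelRecording",
    "default_config",
    "simulate_behavior",
    "render_traces",
    "render_frames",
]

CELL_TYPES = ("HSN", "VC", "vm", "uv1")

# FWHM of a Gaussian = 2*sqrt(2*ln 2) * sigma
FWHM_TO_SIGMA = 1.0 / 2.3548200450309493

# closest resolvable peak spacing, in units of FWHM (~3.3 sigma): below this
# two Gaussian transients of unequal amplitude fuse into one local maximum
MIN_PEAK_GAP_FWHM = 1.4


@dataclass(frozen=True)
class PhaseLock:
    """Von Mises phase preference on the body-bend cycle.

    preferred_phase_deg in [0, 360): 0/360 = ventral contraction,
    180 = ventral relaxation. concentration is the von Mises kappa;
    larger = tighter locking.
    """

    preferred_phase_deg: float
    concentration: float


@dataclass(frozen=True)
class CellParams:
    """Transient-train parameters for one cell type.

    Active-state trains are produced by a jittered oscillator of period
    ``rhythm_period``; the mean inter-transient interval is matched to
    ``active_interval_mean`` by adding a second transient ("doublet", a short
    train) ``doublet_offset`` seconds after the primary with probability
    rhythm_period/active_interval_mean - 1 (or by thinning cycles if the
    interval mean exceeds the period).  Cells with ``rhythm_period`` None use a
    plain exponential renewal train in the active state.  ``bend_locked``
    cells (vulval muscles) instead place transients on body-bend cycles at a
    preferred phase.  ``egg_triggered`` cells (uv1) only respond to eggs.
    """

    transient_fwhm: float
    active_interval_mean: float
    inactive_interval_mean: float
    amplitude_mean: float
    amplitude_cv: float
    rhythm_period: float | None = None
    rhythm_cv: float = 0.12
    doublet_offset: float = 7.0
    egg_amplitude_factor: float = 1.0
    egg_fwhm: float | None = None
    egg_coupling_prob: float = 0.0
    mode: str = "oscillator"  # oscillator | bend_locked | egg_triggered


@dataclass(frozen=True)
class NoiseParams:
    gcamp_sd: float = 2.0
    mcherry_sd: float = 2.0
    artifact_amplitude: float = 0.1
    artifact_timescale: float = 5.0  # s; smoothness of the shared motion artifact


@dataclass(frozen=True)
class ImageParams:
    height: int = 48
    width: int = 64
    cell_radius_px: float = 3.0
    background_mean: float = 200.0
    background_sd: float = 10.0
    blob_amplitude: float = 2000.0
    cell_centroids: dict = field(default_factory=dict)  # cell -> (row, col)


def _default_cell_params() -> dict:
    return {
        # HSN: ~4 s FWHM; 17 s mean active interval on a 20 s (50 mHz) rhythm
        # occurring as single events or short trains; 41 s inactive intervals;
        # amplitudes consistent (low CV).
        "HSN": CellParams(
            transient_fwhm=4.0,
            active_interval_mean=17.0,
            inactive_interval_mean=41.0,
            amplitude_mean=1.0,
            amplitude_cv=0.2,
            rhythm_period=20.0,
            egg_coupling_prob=1.0,
        ),
        # VC: ~2 s FWHM, ~10 s active intervals, rare inactive transients,
        # variable amplitude; every egg is accompanied by a VC transient.
        "VC": CellParams(
            transient_fwhm=2.0,
            active_interval_mean=10.0,
            inactive_interval_mean=120.0,
            amplitude_mean=0.8,
            amplitude_cv=0.5,
            rhythm_period=10.0,
            egg_coupling_prob=1.0,
        ),
        # Vulval muscles: twitches locked to the ~10 s body-bend cycle (one
        # candidate per bend in the active state), egg-laying transients ~4x
        # larger and wider, replacing the twitch of their bend cycle.
        "vm": CellParams(
            transient_fwhm=2.0,
            active_interval_mean=10.0,
            inactive_interval_mean=40.0,
            amplitude_mean=0.5,
            amplitude_cv=0.4,
            egg_amplitude_factor=4.0,
            egg_fwhm=4.0,
            egg_coupling_prob=1.0,
            mode="bend_locked",
        ),
        # uv1: mechanically activated by egg passage; transient rise starts at
        # egg release, peak ~2 s later.  No spontaneous trains.
        "uv1": CellParams(
            transient_fwhm=4.0,
            active_interval_mean=np.inf,
            inactive_interval_mean=np.inf,
            amplitude_mean=1.5,
            amplitude_cv=0.4,
            egg_coupling_prob=0.9,
            mode="egg_triggered",
        ),
    }


def _default_phase_lock() -> dict:
    return {
        "vm_twitch": PhaseLock(270.0, 8.0),
        "vm_egg": PhaseLock(225.0, 8.0),
        "hsn_egg": PhaseLock(180.0, 4.0),
        "vc": PhaseLock(270.0, 2.0),
    }


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one synthetic recording."""

    frame_rate: float = 20.0
    duration: float = 1800.0
    seed: int = 0
    inactive_mean: float = 1200.0
    active_mean: float = 120.0
    bend_period_mean: float = 10.0
    bend_cv: float = 0.05
    egg_rate_active: float = 0.03
    egg_margin: float = 60.0
    hsn_egg_lead: float = 1.8
    vc_egg_lead: float = 0.1
    uv1_lag_mean: float = 0.5
    uv1_lag_sd: float = 0.25
    gcamp_baseline: float = 100.0
    mcherry_baseline: float = 200.0
    cell_params: dict = field(default_factory=_default_cell_params)
    phase_lock: dict = field(default_factory=_default_phase_lock)
    noise: NoiseParams = field(default_factory=NoiseParams)
    render_frames: bool = False
    image: ImageParams = field(default_factory=ImageParams)

    def __post_init__(self):
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be > 0")
        if self.duration < 0:
            raise ValueError("duration must be >= 0")
        n = self.frame_rate * self.duration
        if abs(n - round(n)) > 1e-9:
            raise ValueError("frame_rate * duration must be an integer number of samples")
        for name in ("inactive_mean", "active_mean", "bend_period_mean"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.egg_rate_active < 0:
            raise ValueError("egg_rate_active must be >= 0")
        for cell, p in self.cell_params.items():
            if p.transient_fwhm <= 0:
                raise ValueError(f"{cell}: transient_fwhm must be > 0")
            if not (0.0 <= p.egg_coupling_prob <= 1.0):
                raise ValueError(f"{cell}: egg_coupling_prob must be in [0, 1]")
            if p.active_interval_mean <= 0 or p.inactive_interval_mean <= 0:
                raise ValueError(f"{cell}: interval means must be > 0")
        for key, lock in self.phase_lock.items():
            if not (0.0 <= lock.preferred_phase_deg < 360.0):
                raise ValueError(f"{key}: preferred_phase must be in [0, 360)")

    @property
    def n_samples(self) -> int:
        return int(round(self.frame_rate * self.duration))


def default_config(**overrides) -> SimConfig:
    """The default wild-type study conditions."""
    return replace(SimConfig(), **overrides) if overrides else SimConfig()


@dataclass
class TwoChannelRecording:
    """Per-ROI two-channel fluorescence traces at a fixed frame rate."""

    time: np.ndarray
    gcamp: np.ndarray
    mcherry: np.ndarray
    frame_rate: float
    cell_type: str

    @property
    def ratio(self) -> np.ndarray:
        return self.gcamp / self.mcherry


@dataclass
class GroundTruth:
    """Everything the analysis should recover from a synthetic recording."""

    duration: float
    state_intervals: list  # (start, end, label)
    landmark_times: np.ndarray
    landmark_kinds: np.ndarray  # 'contraction' | 'relaxation'
    egg_times: np.ndarray
    transients: dict  # cell -> DataFrame(peak_time, amplitude, fwhm, egg_coupled, phase_deg)

    @property
    def bend_landmarks(self) -> list:
        return list(zip(self.landmark_times.tolist(), self.landmark_kinds.tolist()))

    def active_intervals(self) -> list:
        return [(s, e) for s, e, lab in self.state_intervals if lab == "active"]


# ---------------------------------------------------------------------------
# random streams

_STREAM_NAMES = (
    "timeline", "bends", "eggs", "HSN", "VC", "vm", "uv1",
    "noise_HSN", "noise_VC", "noise_vm", "noise_uv1", "frames",
)


def _streams(config: SimConfig) -> dict:
    children = np.random.SeedSequence(config.seed).spawn(len(_STREAM_NAMES))
    return {name: np.random.default_rng(ss) for name, ss in zip(_STREAM_NAMES, children)}


def _gamma_draws(rng, mean: float, cv: float, size: int) -> np.ndarray:
    """Positive jittered durations with the given mean and CV (Gamma)."""
    if cv <= 0:
        return np.full(size, mean)
    shape = 1.0 / cv**2
    return rng.gamma(shape, mean * cv**2, size=size)


def _amplitudes(rng, params: CellParams, size: int) -> np.ndarray:
    return _gamma_draws(rng, params.amplitude_mean, params.amplitude_cv, size)


# ---------------------------------------------------------------------------
# behavior simulation


def _draw_timeline(rng, config: SimConfig) -> list:
    """Alternating inactive/active intervals tiling [0, duration]."""
    T = config.duration
    if T <= 0:
        return []
    intervals, t, label = [], 0.0, "inactive"
    while t < T:
        mean = config.inactive_mean if label == "inactive" else config.active_mean
        d = rng.exponential(mean)
        intervals.append((t, min(t + d, T), label))
        t += d
        label = "active" if label == "inactive" else "inactive"
    if len(intervals) == 1:
        warnings.warn("recording shorter than one behavior state; single-state timeline")
    return intervals


def _draw_landmarks(rng, config: SimConfig):
    """Jittered body-bend oscillator: alternating contraction/relaxation
    landmarks half a period apart, starting with a contraction at t=0."""
    T = config.duration
    if T <= 0:
        return np.empty(0), np.empty(0, dtype=object)
    half = config.bend_period_mean / 2.0
    # generous upper bound on the number of half-periods
    n_max = int(np.ceil(T / half * 1.5)) + 20
    gaps = _gamma_draws(rng, half, config.bend_cv, n_max)
    times = np.concatenate([[0.0], np.cumsum(gaps)])
    times = times[times < T]
    kinds = np.where(np.arange(times.size) % 2 == 0, "contraction", "relaxation").astype(object)
    return times, kinds


def phase_of_time(t, landmark_times, landmark_kinds):
    """Body-bend phase (degrees in [0, 360)) at times t; NaN outside landmarks.

    Contraction landmarks map to 0/360, relaxations to 180, linear in between.
    """
    t = np.atleast_1d(np.asarray(t, dtype=float))
    phase = np.full(t.shape, np.nan)
    if landmark_times.size < 2:
        return phase
    idx = np.searchsorted(landmark_times, t, side="right") - 1
    ok = (idx >= 0) & (idx < landmark_times.size - 1)
    i = idx[ok]
    t0 = landmark_times[i]
    t1 = landmark_times[i + 1]
    frac = (t[ok] - t0) / (t1 - t0)
    base = np.where(landmark_kinds[i] == "contraction", 0.0, 180.0)
    phase[ok] = (base + 180.0 * frac) % 360.0
    return phase


def _time_at_phase(target_deg, near_time, landmark_times, landmark_kinds, max_shift):
    """Nearest time to `near_time` where the bend phase equals target_deg,
    or None if no crossing lies within max_shift."""
    if landmark_times.size < 2:
        return None
    lo = np.searchsorted(landmark_times, near_time - max_shift) - 1
    hi = np.searchsorted(landmark_times, near_time + max_shift) + 1
    lo = max(lo, 0)
    hi = min(hi, landmark_times.size - 1)
    best = None
    target = target_deg % 360.0
    for k in range(lo, hi):
        t0, t1 = landmark_times[k], landmark_times[k + 1]
        base = 0.0 if landmark_kinds[k] == "contraction" else 180.0
        # phase on [t0, t1) runs base -> base + 180
        rel = (target - base) % 360.0
        if rel < 180.0:
            t_cross = t0 + (rel / 180.0) * (t1 - t0)
            if abs(t_cross - near_time) <= max_shift and (
                best is None or abs(t_cross - near_time) < abs(best - near_time)
            ):
                best = t_cross
    return best


def _oscillator_train(rng, start, end, params: CellParams):
    """Rhythmic active-state train: jittered cycles of the configured period,
    with doublets (or thinned cycles) matching the configured interval mean."""
    period = params.rhythm_period
    if period is None:
        return _renewal_train(rng, start, end, params.active_interval_mean,
                              dead_time=MIN_PEAK_GAP_FWHM * params.transient_fwhm)
    ratio = period / params.active_interval_mean
    p_double = max(ratio - 1.0, 0.0)
    p_keep = min(ratio, 1.0)
    length = end - start
    n_max = int(np.ceil(length / period * 1.5)) + 10
    gaps = _gamma_draws(rng, period, params.rhythm_cv, n_max)
    cycles = start + rng.uniform(0, period) + np.concatenate([[0.0], np.cumsum(gaps)])
    cycles = cycles[(cycles >= start) & (cycles < end)]
    peaks = []
    for c in cycles:
        if p_keep < 1.0 and rng.uniform() >= p_keep:
            continue
        peaks.append(c)
        if p_double > 0.0 and rng.uniform() < p_double:
            d = c + params.doublet_offset + rng.normal(0.0, 0.5)
            if start <= d < end:
                peaks.append(d)
    return np.sort(np.asarray(peaks))


def _renewal_train(rng, start, end, interval_mean, dead_time=0.0):
    """Poisson-like renewal train with exponential intervals.

    ``dead_time`` adds a refractory floor (a Ca2+ transient cannot recur
    within its own width); intervals are dead_time + Exp(mean - dead_time),
    keeping the configured mean exact.
    """
    if not np.isfinite(interval_mean) or interval_mean <= 0:
        return np.empty(0)
    dead = min(max(dead_time, 0.0), 0.8 * interval_mean)
    length = end - start
    n_max = int(np.ceil(length / interval_mean * 2.0)) + 10
    gaps = dead + rng.exponential(interval_mean - dead, size=n_max)
    times = start + np.cumsum(gaps)
    return times[times < end]


def simulate_behavior(config: SimConfig) -> GroundTruth:
    """Draw a ground-truthed realization of circuit behavior.

    Produces the alternating-state timeline, the jittered body-bend landmark
    sequence, per-cell transient trains with state-dependent statistics, and
    egg events that are confined to active states, coincide with HSN
    transients, and carry a body-bend phase preference.  Deterministic for a
    fixed config (including seed).
    """
    rngs = _streams(config)
    T = config.duration

    intervals = _draw_timeline(rngs["timeline"], config)
    lm_times, lm_kinds = _draw_landmarks(rngs["bends"], config)
    active = [(s, e) for s, e, lab in intervals if lab == "active"]
    inactive = [(s, e) for s, e, lab in intervals if lab == "inactive"]

    transients: dict[str, dict[str, list]] = {
        c: {"peak_time": [], "amplitude": [], "fwhm": [], "egg_coupled": []}
        for c in config.cell_params
    }

    def add(cell, times, amps, fwhm, coupled=False):
        tr = transients[cell]
        tr["peak_time"].extend(np.atleast_1d(times).tolist())
        tr["amplitude"].extend(np.atleast_1d(amps).tolist())
        fw = np.broadcast_to(fwhm, np.atleast_1d(times).shape)
        tr["fwhm"].extend(fw.tolist())
        tr["egg_coupled"].extend([coupled] * np.atleast_1d(times).size)

    # --- HSN: oscillator in active states, renewal in inactive -------------
    hsn = config.cell_params.get("HSN")
    hsn_rng = rngs["HSN"]
    hsn_active_peaks = []
    if hsn is not None:
        for s, e in active:
            hsn_active_peaks.append(_oscillator_train(hsn_rng, s, e, hsn))
        hsn_active_peaks = (
            np.sort(np.concatenate(hsn_active_peaks)) if hsn_active_peaks else np.empty(0)
        )
        for s, e in inactive:
            pk = _renewal_train(hsn_rng, s, e, hsn.inactive_interval_mean,
                                dead_time=MIN_PEAK_GAP_FWHM * hsn.transient_fwhm)
            add("HSN", pk, _amplitudes(hsn_rng, hsn, pk.size), hsn.transient_fwhm)

    # --- eggs: in active-state interiors, snapped to HSN peaks -------------
    egg_rng = rngs["eggs"]
    egg_times: list[float] = []
    hsn_peaks_list = list(np.atleast_1d(hsn_active_peaks)) if hsn is not None else []
    egg_coupled_flags = [False] * len(hsn_peaks_list)
    hsn_lock = config.phase_lock.get("hsn_egg")
    if config.egg_rate_active > 0 and hsn is not None and hsn_peaks_list:
        peaks_arr = np.asarray(hsn_peaks_list)
        used: set[int] = set()
        accepted_peaks: list[float] = []
        for s, e in active:
            lo, hi = s + config.egg_margin, e - config.egg_margin
            if hi <= lo:
                continue
            n = egg_rng.poisson(config.egg_rate_active * (hi - lo))
            for t_cand in np.sort(egg_rng.uniform(lo, hi, size=n)):
                j = int(np.argmin(np.abs(peaks_arr - t_cand)))
                if j in used:
                    continue
                peak = peaks_arr[j]
                if hsn_lock is not None and lm_times.size >= 2:
                    theta = np.degrees(
                        egg_rng.vonmises(
                            np.radians(hsn_lock.preferred_phase_deg), hsn_lock.concentration
                        )
                    )
                    shifted = _time_at_phase(
                        theta, peak, lm_times, lm_kinds, config.bend_period_mean / 2.0
                    )
                    if shifted is not None and lo <= shifted + config.hsn_egg_lead <= hi:
                        peak = shifted
                egg = peak + config.hsn_egg_lead
                if not (lo <= egg <= hi):
                    continue
                # keep egg-bearing HSN peaks far enough apart that none is
                # lost when unresolvably close peaks are merged
                if any(abs(peak - p) < MIN_PEAK_GAP_FWHM * hsn.transient_fwhm
                       for p in accepted_peaks):
                    continue
                accepted_peaks.append(peak)
                used.add(j)
                hsn_peaks_list[j] = peak
                egg_coupled_flags[j] = egg_rng.uniform() < hsn.egg_coupling_prob
                egg_times.append(egg)
    egg_times_arr = np.sort(np.asarray(egg_times))

    if hsn is not None:
        order = np.argsort(hsn_peaks_list) if hsn_peaks_list else np.empty(0, dtype=int)
        pk = np.asarray(hsn_peaks_list)[order] if hsn_peaks_list else np.empty(0)
        flags = np.asarray(egg_coupled_flags)[order] if hsn_peaks_list else np.empty(0, dtype=bool)
        amps = _amplitudes(hsn_rng, hsn, pk.size)
        for t_pk, a, cp in zip(pk, amps, flags):
            add("HSN", t_pk, a, hsn.transient_fwhm, bool(cp))

    # --- VC: oscillator in active states, sparse renewal in inactive;
    #         an extra transient just before each egg ------------------------
    vc = config.cell_params.get("VC")
    if vc is not None:
        vc_rng = rngs["VC"]
        vc_lock = config.phase_lock.get("vc")
        for s, e in active:
            pk = _oscillator_train(vc_rng, s, e, vc)
            if vc_lock is not None and lm_times.size >= 2:
                shifted = []
                for t_pk in pk:
                    theta = np.degrees(
                        vc_rng.vonmises(np.radians(vc_lock.preferred_phase_deg),
                                        vc_lock.concentration)
                    )
                    t_new = _time_at_phase(theta, t_pk, lm_times, lm_kinds,
                                           config.bend_period_mean / 2.0)
                    shifted.append(t_pk if t_new is None else t_new)
                pk = np.sort(np.asarray(shifted))
            add("VC", pk, _amplitudes(vc_rng, vc, pk.size), vc.transient_fwhm)
        for s, e in inactive:
            pk = _renewal_train(vc_rng, s, e, vc.inactive_interval_mean,
                                dead_time=MIN_PEAK_GAP_FWHM * vc.transient_fwhm)
            add("VC", pk, _amplitudes(vc_rng, vc, pk.size), vc.transient_fwhm)
        for egg in egg_times_arr:
            if vc_rng.uniform() < vc.egg_coupling_prob:
                add("VC", egg - config.vc_egg_lead,
                    _amplitudes(vc_rng, vc, 1), vc.transient_fwhm, True)

    # --- vm: bend-locked twitches; egg transients replace the cycle twitch --
    vm = config.cell_params.get("vm")
    if vm is not None:
        vm_rng = rngs["vm"]
        lock = config.phase_lock.get("vm_twitch", PhaseLock(270.0, 8.0))
        egg_lock = config.phase_lock.get("vm_egg", PhaseLock(225.0, 8.0))
        contr = lm_times[lm_kinds == "contraction"]
        for k in range(contr.size - 1):
            c0, c1 = contr[k], contr[k + 1]
            label = _state_at(intervals, c0)
            mean = vm.active_interval_mean if label == "active" else vm.inactive_interval_mean
            p_tw = min(config.bend_period_mean / mean, 1.0) if np.isfinite(mean) else 0.0
            has_egg = egg_times_arr.size and np.any(
                (egg_times_arr >= c0) & (egg_times_arr < c1)
            )
            if has_egg:
                continue  # the egg transient takes this cycle's slot
            if vm_rng.uniform() < p_tw:
                theta = np.degrees(
                    vm_rng.vonmises(np.radians(lock.preferred_phase_deg), lock.concentration)
                )
                mid = (c0 + c1) / 2.0
                t_tw = _time_at_phase(theta, mid, lm_times, lm_kinds,
                                      (c1 - c0) / 2.0 + 1e-9)
                if t_tw is None:
                    t_tw = c0 + ((theta % 360.0) / 360.0) * (c1 - c0)
                add("vm", t_tw, _amplitudes(vm_rng, vm, 1), vm.transient_fwhm)
        for egg in egg_times_arr:
            if vm_rng.uniform() < vm.egg_coupling_prob:
                amp = vm.egg_amplitude_factor * _amplitudes(vm_rng, vm, 1)
                add("vm", egg, amp, vm.egg_fwhm or vm.transient_fwhm, True)
        del egg_lock  # egg time already fixes the vm egg-transient phase

    # --- uv1: triggered by egg passage --------------------------------------
    uv1 = config.cell_params.get("uv1")
    if uv1 is not None:
        uv1_rng = rngs["uv1"]
        for egg in egg_times_arr:
            if uv1_rng.uniform() < uv1.egg_coupling_prob:
                lag = max(uv1_rng.normal(config.uv1_lag_mean, config.uv1_lag_sd), 0.0)
                # rise (half-max onset) starts ~lag after egg; peak half a FWHM later
                add("uv1", egg + lag + uv1.transient_fwhm / 2.0,
                    _amplitudes(uv1_rng, uv1, 1), uv1.transient_fwhm, True)

    # --- assemble ------------------------------------------------------------
    frames: dict[str, pd.DataFrame] = {}
    for cell, tr in transients.items():
        df = pd.DataFrame(tr)
        df = df[(df.peak_time >= 0) & (df.peak_time < T)] if len(df) else df
        df = df.sort_values("peak_time").reset_index(drop=True)
        df = _merge_close_peaks(df)
        df["phase_deg"] = phase_of_time(df.peak_time.to_numpy(), lm_times, lm_kinds) \
            if len(df) else pd.Series(dtype=float)
        frames[cell] = df

    return GroundTruth(
        duration=T,
        state_intervals=intervals,
        landmark_times=lm_times,
        landmark_kinds=lm_kinds,
        egg_times=egg_times_arr,
        transients=frames,
    )


def _merge_close_peaks(df: pd.DataFrame) -> pd.DataFrame:
    """Merge transients closer than ~1.4 FWHM into a single event.

    Two Gaussian transients closer than ~3 sigma can fuse into one local
    maximum (the threshold grows as their amplitudes diverge), so the
    generator never emits peak pairs the waveform cannot represent.
    Egg-coupled peaks win a merge (egg coincidence is structural); otherwise
    the larger amplitude is kept.
    """
    if len(df) < 2:
        return df
    keep_rows: list[int] = []
    for i in range(len(df)):
        if not keep_rows:
            keep_rows.append(i)
            continue
        j = keep_rows[-1]
        gap = df.peak_time.iloc[i] - df.peak_time.iloc[j]
        min_gap = MIN_PEAK_GAP_FWHM * max(df.fwhm.iloc[i], df.fwhm.iloc[j])
        if gap >= min_gap:
            keep_rows.append(i)
            continue
        keep_i = (
            (df.egg_coupled.iloc[i], df.amplitude.iloc[i])
            > (df.egg_coupled.iloc[j], df.amplitude.iloc[j])
        )
        if keep_i:
            keep_rows[-1] = i
    return df.iloc[keep_rows].reset_index(drop=True)


def _state_at(intervals, t):
    for s, e, lab in intervals:
        if s <= t < e:
            return lab
    return "inactive"


# ---------------------------------------------------------------------------
# forward models


def transient_signal(t: np.ndarray, peaks, amplitudes, fwhms) -> np.ndarray:
    """Sum of Gaussian transient kernels; overlapping transients add linearly."""
    out = np.zeros_like(t, dtype=float)
    if len(t) == 0:
        return out
    dt = t[1] - t[0] if len(t) > 1 else 1.0
    for p, a, w in zip(np.atleast_1d(peaks), np.atleast_1d(amplitudes), np.atleast_1d(fwhms)):
        sigma = w * FWHM_TO_SIGMA
        lo = max(int((p - 5 * sigma - t[0]) / dt), 0)
        hi = min(int((p + 5 * sigma - t[0]) / dt) + 2, t.size)
        if hi <= lo:
            continue
        tt = t[lo:hi]
        out[lo:hi] += a * np.exp(-0.5 * ((tt - p) / sigma) ** 2)
    return out


def _artifact(rng, n: int, config: SimConfig) -> np.ndarray:
    """Smooth multiplicative motion/focus artifact shared by both channels."""
    amp = config.noise.artifact_amplitude
    if amp <= 0 or n == 0:
        return np.ones(n)
    from scipy.ndimage import gaussian_filter1d

    z = gaussian_filter1d(rng.standard_normal(n), config.noise.artifact_timescale
                          * config.frame_rate, mode="reflect")
    sd = z.std()
    if sd > 0:
        z = z / sd
    return np.clip(1.0 + amp * z, 0.1, None)


def render_traces(truth: GroundTruth, config: SimConfig, cells=None) -> dict:
    """Render two-channel fluorescence traces from ground truth.

    GCaMP = baseline * (1 + sum of transient kernels); mCherry = constant
    baseline; both channels share a multiplicative artifact m(t) (which cancels
    in the ratio) and carry independent additive Gaussian noise.
    """
    rngs = _streams(config)
    n = config.n_samples
    t = np.arange(n) / config.frame_rate
    cells = tuple(cells) if cells is not None else tuple(truth.transients)
    out = {}
    for cell in cells:
        df = truth.transients[cell]
        sig = transient_signal(
            t, df.peak_time.to_numpy(), df.amplitude.to_numpy(), df.fwhm.to_numpy()
        )
        rng = rngs.get(f"noise_{cell}", rngs["frames"])
        m = _artifact(rng, n, config)
        gcamp = config.gcamp_baseline * (1.0 + sig) * m
        mch = config.mcherry_baseline * np.ones(n) * m
        if config.noise.gcamp_sd > 0:
            gcamp = gcamp + rng.normal(0.0, config.noise.gcamp_sd, size=n)
        if config.noise.mcherry_sd > 0:
            mch = mch + rng.normal(0.0, config.noise.mcherry_sd, size=n)
        out[cell] = TwoChannelRecording(
            time=t, gcamp=gcamp, mcherry=mch, frame_rate=config.frame_rate, cell_type=cell
        )
    return out


def render_frames(truth: GroundTruth, config: SimConfig, cell: str = "vm"):
    """Render a two-channel image stack for one cell.

    The cell is a 2-D Gaussian blob (truncated at 3x its radius): the mCherry
    blob is constant, the GCaMP blob follows the noise-free rendered trace, and
    background pixels are Normal(background_mean, background_sd).  Returns
    (gcamp_stack, mcherry_stack, true_ratio) where true_ratio is the
    area-weighted mean pixel ratio over the noise-free threshold mask per
    frame.
    """
    img = config.image
    n = config.n_samples
    rng = _streams(config)["frames"]
    df = truth.transients[cell]
    t = np.arange(n) / config.frame_rate
    sig = transient_signal(t, df.peak_time.to_numpy(), df.amplitude.to_numpy(),
                           df.fwhm.to_numpy())
    r0 = config.gcamp_baseline / config.mcherry_baseline
    ratio_t = r0 * (1.0 + sig)

    cy, cx = img.cell_centroids.get(cell, (img.height / 2.0, img.width / 2.0))
    if not (0 <= cy < img.height and 0 <= cx < img.width):
        raise ValueError("cell centroid outside image bounds")
    yy, xx = np.mgrid[0:img.height, 0:img.width]
    d2 = (yy - cy) ** 2 + (xx - cx) ** 2
    # truncated at 2x the radius so the blob support is well above any
    # plausible detection threshold (min blob value = amplitude * e^-2)
    prof = np.exp(-0.5 * d2 / img.cell_radius_px**2)
    prof[d2 > (2.0 * img.cell_radius_px) ** 2] = 0.0
    if np.any((prof > 0) & ((yy == 0) | (yy == img.height - 1) | (xx == 0) | (xx == img.width - 1))):
        warnings.warn("cell blob clipped by the frame edge; blob mass truncated")

    mch_blob = img.blob_amplitude * prof
    mask = mch_blob > max(2.0 * img.background_sd, 0.0)  # noise-free detection mask
    gcamp = np.empty((n, img.height, img.width), dtype=float)
    mch = np.empty_like(gcamp)
    true_ratio = np.empty(n)
    for i in range(n):
        g_blob = img.blob_amplitude * ratio_t[i] * prof
        bg_g = img.background_mean + (
            rng.normal(0.0, img.background_sd, prof.shape) if img.background_sd > 0 else 0.0
        )
        bg_m = img.background_mean + (
            rng.normal(0.0, img.background_sd, prof.shape) if img.background_sd > 0 else 0.0
        )
        gcamp[i] = bg_g + g_blob
        mch[i] = bg_m + mch_blob
        clean_g = img.background_mean + g_blob
        clean_m = img.background_mean + mch_blob
        true_ratio[i] = np.mean(clean_g[mask] / clean_m[mask]) if mask.any() else np.nan
    return gcamp, mch, true_ratio
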