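"""Generator correctness: determinism, timeline statistics, landmark
structure, egg placement, and the fluorescence forward model."""

from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

import eggcircuit as ec
from eggcircuit.synthetic import phase_of_time

from conftest import noise_free_config


def test_identical_config_gives_bit_identical_outputs():
    cfg = ec.default_config(duration=600.0, seed=11)
    t1 = ec.simulate_behavior(cfg)
    t2 = ec.simulate_behavior(cfg)
    assert np.array_equal(t1.egg_times, t2.egg_times)
    assert np.array_equal(t1.landmark_times, t2.landmark_times)
    for cell in t1.transients:
        pd.testing.assert_frame_equal(t1.transients[cell], t2.transients[cell])
    r1 = ec.render_traces(t1, cfg, cells=("HSN",))["HSN"]
    r2 = ec.render_traces(t2, cfg, cells=("HSN",))["HSN"]
    assert np.array_equal(r1.gcamp, r2.gcamp)
    assert np.array_equal(r1.mcherry, r2.mcherry)


def test_different_seeds_differ():
    a = ec.simulate_behavior(ec.default_config(duration=600.0, seed=1))
    b = ec.simulate_behavior(ec.default_config(duration=600.0, seed=2))
    assert not np.array_equal(a.landmark_times, b.landmark_times)


def test_zero_duration_gives_empty_ground_truth():
    truth = ec.simulate_behavior(ec.default_config(duration=0.0, seed=0))
    assert truth.state_intervals == []
    assert truth.egg_times.size == 0
    assert truth.landmark_times.size == 0
    assert all(len(df) == 0 for df in truth.transients.values())


def test_deterministic_oscillator_landmarks():
    # 10 s bend period, zero CV, 60 s: 6 contractions + 6 relaxations, 5 s apart
    cfg = ec.default_config(duration=60.0, seed=0, bend_cv=0.0)
    truth = ec.simulate_behavior(cfg)
    assert truth.landmark_times.size == 12
    assert np.allclose(np.diff(truth.landmark_times), 5.0)
    kinds = truth.landmark_kinds
    assert (kinds[::2] == "contraction").all()
    assert (kinds[1::2] == "relaxation").all()


@pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
def test_landmarks_alternate_and_increase(seed):
    truth = ec.simulate_behavior(ec.default_config(duration=900.0, seed=seed))
    assert (np.diff(truth.landmark_times) > 0).all()
    kinds = truth.landmark_kinds
    assert (kinds[:-1] != kinds[1:]).all()


def test_states_tile_recording_and_long_run_active_fraction():
    # renewal-process oracle: long-run fraction active =
    # active_mean / (active_mean + inactive_mean) = 120/1320 ~ 0.0909
    total_active, total = 0.0, 0.0
    for seed in range(200):
        cfg = ec.default_config(duration=3000.0, seed=seed,
                                cell_params={}, egg_rate_active=0.0)
        truth = ec.simulate_behavior(cfg)
        spans = [(e - s) for s, e, _ in truth.state_intervals]
        assert np.isclose(sum(spans), cfg.duration)
        total_active += sum(e - s for s, e, lab in truth.state_intervals
                            if lab == "active")
        total += cfg.duration
    expect = 120.0 / 1320.0
    assert abs(total_active / total - expect) < 0.015


def test_interval_mean_recovery_in_truth():
    # empirical mean inter-transient interval converges to the configured
    # mean; one long uninterrupted inactive stretch avoids window censoring
    cfg = ec.default_config(duration=36000.0, seed=5, inactive_mean=1e9,
                            egg_rate_active=0.0)
    with pytest.warns(UserWarning):
        truth = ec.simulate_behavior(cfg)
    gaps = np.diff(truth.transients["HSN"].peak_time.to_numpy())
    assert gaps.size >= 500
    assert abs(gaps.mean() - 41.0) / 41.0 < 0.05


def test_eggs_inside_active_states_and_hsn_spans():
    cfg = ec.default_config(duration=36000.0, seed=9)
    truth = ec.simulate_behavior(cfg)
    assert truth.egg_times.size >= 5
    active = truth.active_intervals()
    for egg in truth.egg_times:
        assert any(s <= egg < e for s, e in active)
    hsn = truth.transients["HSN"]
    onsets = hsn.peak_time - hsn.fwhm / 2.0
    offsets = hsn.peak_time + hsn.fwhm / 2.0
    for egg in truth.egg_times:
        assert np.any((egg >= onsets) & (egg <= offsets)), "egg outside HSN spans"
    # egg-coupled flags match egg placement
    coupled = hsn.loc[hsn.egg_coupled, "peak_time"].to_numpy()
    assert coupled.size == truth.egg_times.size


def test_zero_egg_rate_means_no_eggs_and_no_uv1():
    cfg = ec.default_config(duration=3600.0, seed=2, egg_rate_active=0.0)
    truth = ec.simulate_behavior(cfg)
    assert truth.egg_times.size == 0
    assert len(truth.transients["uv1"]) == 0


def test_vm_egg_transients_are_four_fold_and_flagged():
    cfg = ec.default_config(duration=36000.0, seed=4)
    truth = ec.simulate_behavior(cfg)
    vm = truth.transients["vm"]
    eggs = vm[vm.egg_coupled]
    twitches = vm[~vm.egg_coupled]
    assert len(eggs) >= 3
    ratio = eggs.amplitude.mean() / twitches.amplitude.mean()
    assert 3.0 < ratio < 5.0


def test_rendered_ratio_constant_without_transients_or_noise():
    cfg = noise_free_config(duration=60.0, seed=0, cell_params={}, egg_rate_active=0.0)
    truth = ec.simulate_behavior(cfg)
    truth.transients["HSN"] = pd.DataFrame(
        {"peak_time": [], "amplitude": [], "fwhm": [], "egg_coupled": [],
         "phase_deg": []})
    rec = ec.render_traces(truth, cfg, cells=("HSN",))["HSN"]
    r0 = cfg.gcamp_baseline / cfg.mcherry_baseline
    assert np.allclose(rec.ratio, r0, rtol=1e-12)


def test_shared_artifact_cancels_in_ratio():
    cfg = noise_free_config(duration=300.0, seed=6)
    truth = ec.simulate_behavior(cfg)
    clean = ec.render_traces(truth, cfg, cells=("HSN",))["HSN"]
    arty = replace(cfg, noise=ec.NoiseParams(gcamp_sd=0.0, mcherry_sd=0.0,
                                             artifact_amplitude=0.5))
    dirty = ec.render_traces(truth, arty, cells=("HSN",))["HSN"]
    assert not np.allclose(clean.gcamp, dirty.gcamp)  # channels do differ
    assert np.allclose(clean.ratio, dirty.ratio, rtol=1e-12)


def test_single_transient_peak_equals_amplitude():
    cfg = noise_free_config(duration=60.0, seed=0, cell_params={}, egg_rate_active=0.0)
    truth = ec.simulate_behavior(cfg)
    amp = 0.8
    truth.transients["HSN"] = pd.DataFrame(
        {"peak_time": [30.0], "amplitude": [amp], "fwhm": [4.0],
         "egg_coupled": [False], "phase_deg": [np.nan]})
    rec = ec.render_traces(truth, cfg, cells=("HSN",))["HSN"]
    r0 = cfg.gcamp_baseline / cfg.mcherry_baseline
    droverr = rec.ratio / r0 - 1.0
    assert abs(droverr.max() - amp) < 1e-9
    assert abs(rec.time[np.argmax(droverr)] - 30.0) <= 1.0 / cfg.frame_rate


def test_phase_of_time_matches_convention():
    lm_t = np.array([0.0, 5.0, 10.0])
    lm_k = np.array(["contraction", "relaxation", "contraction"], dtype=object)
    assert phase_of_time(2.5, lm_t, lm_k)[0] == pytest.approx(90.0)
    assert phase_of_time(7.5, lm_t, lm_k)[0] == pytest.approx(270.0)
    assert np.isnan(phase_of_time(11.0, lm_t, lm_k)[0])


def test_render_frames_noise_free_recovery():
    from dataclasses import replace as drep

    cfg = noise_free_config(duration=1.0, seed=0, cell_params={},
                            egg_rate_active=0.0)
    cfg = drep(cfg, image=ec.ImageParams(background_mean=0.0, background_sd=0.0))
    truth = ec.simulate_behavior(cfg)
    truth.transients["vm"] = pd.DataFrame(
        {"peak_time": [], "amplitude": [], "fwhm": [], "egg_coupled": [],
         "phase_deg": []})
    g, m, true_ratio = ec.render_frames(truth, cfg, cell="vm")
    r0 = cfg.gcamp_baseline / cfg.mcherry_baseline
    assert np.allclose(true_ratio, r0, rtol=1e-12)
    trace, area, qc = ec.extract_trace(g, m, cfg.frame_rate)
    assert np.allclose(trace.ratio, true_ratio, rtol=1e-9)
    assert (area > 0).all()


def test_render_frames_default_noise_rmse():
    cfg = ec.default_config(duration=5.0, seed=8, cell_params={},
                            egg_rate_active=0.0)
    truth = ec.simulate_behavior(cfg)
    truth.transients["vm"] = pd.DataFrame(
        {"peak_time": [2.0], "amplitude": [1.0], "fwhm": [1.0],
         "egg_coupled": [True], "phase_deg": [np.nan]})
    g, m, true_ratio = ec.render_frames(truth, cfg, cell="vm")
    trace, _, _ = ec.extract_trace(g, m, cfg.frame_rate)
    rmse = np.sqrt(np.mean((trace.ratio - true_ratio) ** 2))
    noise_floor = 3.0 * cfg.image.background_sd / cfg.image.blob_amplitude
    assert rmse < max(noise_floor, 0.02)


def test_invalid_config_rejected():
    with pytest.raises(ValueError):
        ec.default_config(duration=-5.0)
    with pytest.raises(ValueError):
        ec.default_config(frame_rate=0.0)
    with pytest.raises(ValueError):
        ec.default_config(duration=10.013)  # non-integer sample count at 20 fps
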