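"""Smoothing, baselining and transient detection."""

import numpy as np
import pandas as pd
import pytest

import eggcircuit as ec
from eggcircuit.synthetic import FWHM_TO_SIGMA, transient_signal

from conftest import noise_free_config


def _trace(values, fr=20.0):
    values = np.asarray(values, dtype=float)
    return ec.RatioTrace(time=np.arange(values.size) / fr, ratio=values,
                         frame_rate=fr)


class TestSmooth:
    def test_constant_unchanged(self):
        tr = ec.smooth(_trace(np.full(50, 2.5)))
        assert np.allclose(tr.ratio, 2.5)

    def test_three_point_mean(self):
        tr = ec.smooth(_trace([0.0, 3.0, 0.0]))
        assert tr.ratio[1] == pytest.approx(1.0)
        assert tr.ratio[0] == pytest.approx(1.5)  # shrunken edge window

    def test_impulse_becomes_h_over_3(self):
        x = np.zeros(41)
        x[20] = 6.0
        tr = ec.smooth(_trace(x))
        assert tr.ratio.max() == pytest.approx(2.0)

    def test_low_frame_rate_identity_with_warning(self):
        with pytest.warns(UserWarning):
            tr = ec.smooth(_trace(np.arange(10.0), fr=2.0))
        assert np.allclose(tr.ratio, np.arange(10.0))


class TestBaseline:
    def test_constant_trace(self):
        tr = ec.compute_baseline(_trace(np.full(100, 3.0)))
        assert tr.baseline == pytest.approx(3.0)
        assert np.allclose(tr.droverr, 0.0)

    def test_lowest_decile_of_1_to_20(self):
        tr = ec.compute_baseline(_trace(np.arange(1.0, 21.0)))
        assert tr.baseline == pytest.approx(1.5)  # mean of {1, 2}

    def test_bimodal_floor(self):
        x = np.concatenate([np.full(90, 1.0), np.full(10, 5.0)])
        tr = ec.compute_baseline(_trace(x))
        assert tr.baseline == pytest.approx(1.0)

    def test_matches_sort_and_average_oracle(self, rng):
        for _ in range(20):
            x = rng.uniform(0.5, 3.0, size=rng.integers(20, 500))
            k = max(int(np.floor(0.1 * x.size)), 1)
            oracle = np.sort(x)[:k].mean()
            assert ec.compute_baseline(_trace(x)).baseline == pytest.approx(oracle)

    def test_nonpositive_baseline_rejected(self):
        with pytest.raises(ValueError):
            ec.compute_baseline(_trace(np.linspace(-1.0, 1.0, 50)))

    def test_baseline_below_mean_and_floor_averages_zero(self, rng):
        x = 1.0 + 0.02 * rng.standard_normal(2000)
        tr = ec.compute_baseline(_trace(x))
        assert tr.baseline <= x.mean()
        k = max(int(0.1 * x.size), 1)
        floor = np.sort(tr.droverr)[:k]
        assert abs(floor.mean()) < 0.05


class TestDetect:
    def _render(self, peaks, amps, fwhms, duration=120.0, fr=20.0):
        t = np.arange(int(duration * fr)) / fr
        sig = transient_signal(t, peaks, amps, fwhms)
        tr = ec.RatioTrace(time=t, ratio=0.5 * (1.0 + sig), frame_rate=fr)
        return ec.process_trace(tr)

    def test_flat_trace_empty(self):
        proc = ec.compute_baseline(_trace(np.full(100, 1.0)))
        assert len(ec.detect_transients(proc)) == 0

    @pytest.mark.parametrize("fwhm", [1.0, 2.0, 4.0, 6.0])
    def test_single_gaussian_amplitude_and_fwhm(self, fwhm):
        amp = 0.9
        proc = self._render([60.0], [amp], [fwhm])
        det = ec.detect_transients(proc)
        assert len(det) == 1
        row = det.iloc[0]
        assert abs(row.peak_time - 60.0) <= 1.0 / proc.frame_rate
        # 3-point smoothing slightly attenuates narrow kernels
        assert row.amplitude == pytest.approx(amp, rel=0.05)
        # FWHM = 2.3548 sigma recovered within 2 samples
        assert abs(row.fwhm - fwhm) <= 2.0 / proc.frame_rate
        assert row.onset < row.peak_time < row.offset

    def test_two_transients_twenty_seconds_apart(self):
        proc = self._render([40.0, 60.0], [1.0, 0.8], [4.0, 4.0])
        det = ec.detect_transients(proc)
        assert len(det) == 2
        assert np.allclose(det.peak_time, [40.0, 60.0], atol=1.0 / proc.frame_rate)

    def test_noise_free_count_matches_ground_truth(self):
        cfg = noise_free_config(duration=3600.0, seed=21)
        truth = ec.simulate_behavior(cfg)
        rec = ec.render_traces(truth, cfg, cells=("HSN",))["HSN"]
        det = ec.detect_transients(ec.process_trace(ec.RatioTrace.from_recording(rec)))
        assert len(det) == len(truth.transients["HSN"])

    def test_false_positive_rate_on_pure_noise(self):
        # < 1 detection per 10 min on average over 100 seeded noise runs
        fr, n = 20.0, 12000  # 10 min
        counts = []
        for seed in range(100):
            r = np.random.default_rng(seed)
            x = 1.0 + 0.02 * r.standard_normal(n)
            proc = ec.process_trace(ec.RatioTrace(time=np.arange(n) / fr,
                                                  ratio=x, frame_rate=fr))
            counts.append(len(ec.detect_transients(proc)))
        assert np.mean(counts) < 1.0

    def test_amplitude_recovery_under_default_noise(self):
        # relative RMSE of recovered peak amplitudes < 10% over >= 200 transients
        errs = []
        for seed in (31, 32, 33):
            cfg = ec.default_config(duration=3600.0, seed=seed)
            truth = ec.simulate_behavior(cfg)
            rec = ec.render_traces(truth, cfg, cells=("HSN",))["HSN"]
            det = ec.detect_transients(
                ec.process_trace(ec.RatioTrace.from_recording(rec)))
            tt = truth.transients["HSN"]
            for _, row in det.iterrows():
                j = (tt.peak_time - row.peak_time).abs().idxmin()
                if abs(tt.peak_time[j] - row.peak_time) < 1.0:
                    errs.append((row.amplitude - tt.amplitude[j]) / tt.amplitude[j])
        errs = np.asarray(errs)
        assert errs.size >= 200
        assert np.sqrt(np.mean(errs**2)) < 0.10

    def test_overlapping_spans_truncated_at_interpeak_minimum(self):
        proc = self._render([50.0, 54.0], [1.0, 1.0], [4.0, 4.0])
        det = ec.detect_transients(proc)
        assert len(det) == 2
        assert det.offset.iloc[0] <= det.onset.iloc[1] + 1e-9


class TestNormalize:
    def test_examples(self):
        df = pd.DataFrame({"amplitude": [2.0, 4.0]})
        out = ec.normalize_amplitudes(df)
        assert np.allclose(out.normalized_amplitude, [0.5, 1.0])
        single = ec.normalize_amplitudes(pd.DataFrame({"amplitude": [3.3]}))
        assert single.normalized_amplitude.iloc[0] == pytest.approx(1.0)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            ec.normalize_amplitudes(pd.DataFrame({"amplitude": []}))

    def test_vm_twitch_to_egg_ratio(self):
        # vm egg transients are ~4x twitches, so the median normalized twitch
        # is ~0.25 of the median normalized egg transient
        cfg = ec.default_config(duration=36000.0, seed=13)
        truth = ec.simulate_behavior(cfg)
        vm = ec.normalize_amplitudes(truth.transients["vm"].copy())
        med_egg = vm.loc[vm.egg_coupled, "normalized_amplitude"].median()
        med_tw = vm.loc[~vm.egg_coupled, "normalized_amplitude"].median()
        assert med_tw / med_egg == pytest.approx(0.25, abs=0.10)
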