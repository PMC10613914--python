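"""Acoustic voice-quality measures: formula oracles and synthesis recovery."""

import math

import numpy as np
import pytest

from pdscreen import acoustic
from pdscreen.acoustic import (F0Track, PeriodSequence, Waveform, ddk_measures,
                               duv, energy_rel_sd, extract_task_features,
                               f0_contour, formant_rel_sd, hnr_mean, jitter_ppq5,
                               pause_metrics, period_sequence, rel_sd,
                               shimmer_apq5, syllable_nuclei, task_feature_map)
from pdscreen.synthetic import synth_connected_speech, synth_ddk, synth_vowel

FS = 48000.0


def make_track(voiced, f0=150.0):
    v = np.asarray(voiced, dtype=bool)
    n = v.size
    return F0Track(times=np.arange(n) * 0.01,
                   f0=np.where(v, f0, np.nan),
                   voiced=v, corr_peak=np.where(v, 0.9, 0.1))


class TestDuvRelSd:
    def test_duv_all_voiced(self):
        assert duv(make_track([True] * 10)) == 0.0

    def test_duv_all_unvoiced(self):
        assert duv(make_track([False] * 10)) == 1.0

    def test_duv_fraction(self):
        assert duv(make_track([True] * 7 + [False] * 3)) == pytest.approx(0.3)

    def test_rel_sd_constant(self):
        assert rel_sd([100.0, 100.0, 100.0]) == 0.0

    def test_rel_sd_two_values(self):
        assert rel_sd([90.0, 110.0]) == pytest.approx(0.1)

    def test_rel_sd_scale_invariant(self, rng):
        x = rng.uniform(50, 150, 40)
        assert rel_sd(3.7 * x) == pytest.approx(rel_sd(x), rel=1e-12)

    def test_rel_sd_zero_mean_undefined(self):
        assert math.isnan(rel_sd([-1.0, 1.0]))


def direct_ppq5(vals):
    """Literal five-point perturbation quotient, plain loops."""
    m = sum(vals) / len(vals)
    devs = []
    for i in range(2, len(vals) - 2):
        win = sum(vals[i - 2:i + 3]) / 5.0
        devs.append(abs(vals[i] - win))
    return 100.0 * (sum(devs) / len(devs)) / m


class TestPerturbationQuotients:
    def test_constant_periods_zero(self):
        ps = PeriodSequence(np.full(20, 0.01), np.ones(20))
        assert jitter_ppq5(ps) == 0.0
        assert shimmer_apq5(ps) == 0.0

    def test_alternating_matches_direct_formula(self):
        periods = np.array([0.010, 0.0102] * 10)
        amps = np.array([1.0, 1.1] * 10)
        ps = PeriodSequence(periods, amps)
        assert jitter_ppq5(ps) == pytest.approx(direct_ppq5(periods), abs=1e-9)
        assert shimmer_apq5(ps) == pytest.approx(direct_ppq5(amps), abs=1e-9)

    def test_random_sequences_match_direct_formula(self, rng):
        for _ in range(20):
            n = rng.integers(5, 40)
            periods = rng.uniform(0.005, 0.012, n)
            ps = PeriodSequence(periods, rng.uniform(0.5, 1.0, n))
            assert jitter_ppq5(ps) == pytest.approx(
                direct_ppq5(periods), abs=1e-9)

    def test_too_few_cycles_error(self):
        with pytest.raises(acoustic.InsufficientCyclesError):
            jitter_ppq5(PeriodSequence(np.full(4, 0.01), np.ones(4)))


class TestPitchTracking:
    def test_f0_recovery_150hz(self):
        w = synth_vowel(150, 0, 0, 40, duration_s=2.0, fs=FS, seed=5)
        tr = f0_contour(w)
        assert 147.0 <= np.median(tr.f0[tr.voiced]) <= 153.0

    def test_silence_has_no_voiced_frames(self):
        tr = f0_contour(Waveform(np.zeros(int(FS)), FS))
        assert int(tr.voiced.sum()) == 0

    def test_white_noise_mostly_unvoiced(self, rng):
        tr = f0_contour(Waveform(rng.normal(0, 0.3, int(2 * FS)), FS))
        assert duv(tr) >= 0.9

    def test_invalid_band_error(self):
        with pytest.raises(ValueError):
            f0_contour(Waveform(np.zeros(int(FS)), FS), fmin=300, fmax=100)


class TestHNR:
    def test_high_periodicity_floor(self):
        w = synth_vowel(150, 0, 0, 40, duration_s=2.0, fs=FS, seed=1)
        assert hnr_mean(w, f0_contour(w)) >= 25.0

    def test_equal_power_near_zero_db(self):
        w = synth_vowel(150, 0, 0, 0, duration_s=2.0, fs=FS, seed=1)
        tr = f0_contour(w, voicing_threshold=0.3)
        assert hnr_mean(w, tr) == pytest.approx(0.0, abs=3.0)

    def test_noise_dominated_negative(self):
        w = synth_vowel(150, 0, 0, -10, duration_s=2.0, fs=FS, seed=1)
        tr = f0_contour(w, voicing_threshold=0.02)
        assert hnr_mean(w, tr) < 0.0

    def test_no_voiced_frames_undefined(self):
        assert math.isnan(hnr_mean(Waveform(np.zeros(int(FS)), FS),
                                   make_track([False] * 10)))


class TestMonotoneRecovery:
    def test_jitter_sweep_strictly_increasing(self):
        ests = []
        for j in (0.5, 1.0, 2.0, 4.0):
            w = synth_vowel(150, j, 0, 30, duration_s=2.0, fs=FS, seed=3)
            ests.append(jitter_ppq5(period_sequence(w, f0_contour(w))))
        assert all(a < b for a, b in zip(ests, ests[1:]))

    def test_shimmer_sweep_increasing(self):
        ests = []
        for s in (0.0, 3.0, 8.0):
            w = synth_vowel(150, 0.5, s, 30, duration_s=2.0, fs=FS, seed=3)
            ests.append(shimmer_apq5(period_sequence(w, f0_contour(w))))
        assert all(a < b for a, b in zip(ests, ests[1:]))

    def test_jitter_shimmer_grid_rank_recovery(self):
        """Across an f0 grid, estimates rank-order with injected levels."""
        from scipy.stats import spearmanr
        for f0 in (100.0, 150.0, 220.0):
            levels, jit_est, shim_est = (0.0, 1.0, 3.0), [], []
            for lv in levels:
                w = synth_vowel(f0, lv, lv * 2, 25, duration_s=2.0, fs=FS, seed=9)
                ps = period_sequence(w, f0_contour(w))
                jit_est.append(jitter_ppq5(ps))
                shim_est.append(shimmer_apq5(ps))
            assert spearmanr(levels, jit_est).statistic == pytest.approx(1.0)
            assert spearmanr(levels, shim_est).statistic == pytest.approx(1.0)


class TestFormants:
    def test_fixed_formants_low_relsd(self):
        w = synth_vowel(130, 0.3, 1, 30, formants=((500, 80), (1500, 120)),
                        duration_s=2.0, fs=FS, seed=3)
        r1, r2 = formant_rel_sd(w, f0_contour(w))
        assert r1 <= 0.05 and r2 <= 0.05

    def test_swept_f1_exceeds_fixed(self):
        segs = [synth_vowel(130, 0.3, 1, 30, formants=((f1, 80), (1500, 120)),
                            duration_s=0.5, fs=FS, seed=3).samples
                for f1 in np.linspace(400, 800, 5)]
        swept = Waveform(np.concatenate(segs), FS)
        r1_swept, _ = formant_rel_sd(swept, f0_contour(swept))
        fixed = synth_vowel(130, 0.3, 1, 30, formants=((500, 80), (1500, 120)),
                            duration_s=2.0, fs=FS, seed=3)
        r1_fixed, _ = formant_rel_sd(fixed, f0_contour(fixed))
        assert r1_swept >= 3.0 * r1_fixed

    def test_unvoiced_noise_undefined(self, rng):
        w = Waveform(rng.normal(0, 0.2, int(2 * FS)), FS)
        r1, r2 = formant_rel_sd(w, f0_contour(w))
        assert math.isnan(r1) and math.isnan(r2)


class TestEnergy:
    def test_constant_vowel_low(self):
        w = synth_vowel(150, 0.3, 1, 30, duration_s=2.0, fs=FS, seed=2)
        assert energy_rel_sd(w) <= 0.2

    def test_amplitude_modulation_raises(self):
        w = synth_vowel(150, 0.3, 1, 30, duration_s=2.0, fs=FS, seed=2)
        ts = np.arange(w.samples.size) / FS
        wm = Waveform(w.samples * (1 + 0.5 * np.sin(2 * np.pi * 1.3 * ts)), FS)
        assert energy_rel_sd(wm) >= 3.0 * energy_rel_sd(w)

    def test_silence_undefined(self):
        assert math.isnan(energy_rel_sd(Waveform(np.zeros(int(FS)), FS)))


class TestSyllablesAndPauses:
    def test_ddk_burst_count_recovered(self):
        w = synth_ddk(4.0, 0.0, 12, fs=FS, seed=4)
        assert len(syllable_nuclei(w)) == 12

    def test_silence_no_nuclei(self):
        assert len(syllable_nuclei(Waveform(np.zeros(int(FS)), FS))) == 0

    def test_close_bursts_merged(self):
        from pdscreen.synthetic import _tone_burst
        x = np.zeros(int(FS))
        burst = _tone_burst(FS, 0.020)
        for on in (0.500, 0.530):      # 30 ms apart: below minimum separation
            i = int(on * FS)
            x[i:i + burst.size] += burst
        assert len(syllable_nuclei(Waveform(x, FS))) <= 1

    def test_ddk_measures_exact_spacing(self):
        onsets = np.arange(12) / 6.0
        rate, reg = ddk_measures(onsets)
        assert rate == pytest.approx(6.0)
        assert reg == pytest.approx(0.0, abs=1e-12)

    def test_ddk_reg_two_intervals(self):
        rate, reg = ddk_measures([0.0, 0.2, 0.5])
        assert reg == pytest.approx(0.05)

    def test_ddk_rate_recovery(self):
        w = synth_ddk(6.0, 0.0, 12, fs=FS, seed=4)
        rate, _ = ddk_measures(syllable_nuclei(w))
        assert rate == pytest.approx(6.0, abs=0.3)

    def test_ddk_reg_recovery_band(self):
        regs = []
        for seed in range(10):
            w = synth_ddk(3.0, 0.02, 12, fs=FS, seed=seed)
            regs.append(ddk_measures(syllable_nuclei(w))[1])
        assert 0.01 <= np.mean(regs) <= 0.03

    def test_spir_three_pauses_in_30s(self):
        w, _ = synth_connected_speech(4, 3, 30.0, fs=FS, seed=6)
        assert pause_metrics(w)["SPIR"] == pytest.approx(6.0)

    def test_spir_no_pauses(self):
        w, _ = synth_connected_speech(1, 0, 10.0, fs=FS, seed=1)
        assert pause_metrics(w)["SPIR"] == 0.0

    def test_nsr_against_ground_truth(self):
        w, seg = synth_connected_speech(4, 3, 30.0, fs=FS, seed=6)
        pm = pause_metrics(w)
        truth_nst = seg.loc[seg["kind"] == "speech",
                            ["start_s", "end_s"]].diff(axis=1)["end_s"].sum()
        truth_nsr = seg["n_nuclei"].sum() / truth_nst
        assert pm["NST"] == pytest.approx(truth_nst, rel=0.05)
        assert pm["NSR"] == pytest.approx(truth_nsr, rel=0.15)


class TestTaskMapping:
    def test_sustained_vowel_set(self):
        w = synth_vowel(150, 1, 3, 20, duration_s=1.5, fs=FS, seed=2)
        fs = extract_task_features(w, "TSK3")
        for name in ("jitter", "shimmer", "meanHNR", "DUV", "relF0SD",
                     "relF1SD", "relF2SD"):
            assert math.isfinite(getattr(fs, name)), name
        assert math.isnan(fs.DDKrate) and math.isnan(fs.SPIR)

    def test_ddk_task_set(self):
        w = synth_ddk(5.0, 0.01, 12, fs=FS, seed=3)
        fs = extract_task_features(w, "TSK18")
        assert math.isfinite(fs.DDKrate) and math.isfinite(fs.DDKreg)
        assert math.isnan(fs.jitter)

    def test_mpt_is_longest_voiced_stretch(self):
        w = synth_vowel(150, 0.5, 2, 25, duration_s=1.5, fs=FS, seed=6)
        fs = extract_task_features(w, "TSK1")
        assert fs.MPT == pytest.approx(1.5, abs=0.15)

    def test_unknown_task_error(self):
        w = synth_vowel(150, 0, 0, 20, duration_s=1.0, fs=FS, seed=1)
        with pytest.raises(acoustic.TaskMappingError):
            extract_task_features(w, "TSK99")

    def test_applicability_lists(self):
        assert "MPT" in task_feature_map("TSK1")
        assert "MPT" not in task_feature_map("TSK3")
        assert task_feature_map("TSK18") == ("DDKrate", "DDKreg")
        assert "SPIR" in task_feature_map("TSK42")
        assert "SPIR" not in task_feature_map("TSK19")
        assert "NSR" in task_feature_map("TSK30")
        assert "NSR" not in task_feature_map("TSK42")


class TestAmplitudeInvariance:
    @pytest.mark.parametrize("gain", [0.5, 1.1])
    def test_relative_measures_unchanged(self, gain):
        w = synth_vowel(150, 1.5, 4, 20, duration_s=1.5, fs=FS, seed=8)
        scaled = Waveform(w.samples * gain, FS)
        a = extract_task_features(w, "TSK3")
        b = extract_task_features(scaled, "TSK3")
        for name in ("relF0SD", "jitter", "shimmer", "DUV"):
            assert getattr(a, name) == pytest.approx(getattr(b, name), abs=1e-6)
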