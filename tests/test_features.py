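"""Tests of the 24 gait characteristics against analytic and oracle values."""

import numpy as np
import pytest

from circlegait.features import (
    average_directions,
    cyclic_regularity,
    extract_feature_vector,
    harmonic_ratio,
    index_of_harmonicity,
    signal_sd,
    spectral_peak_features,
    step_time_asymmetry,
    stride_time_stats,
    temporal_counts,
    trimmed_sd,
    welch_psd,
)
from circlegait.preprocess import segment_step_cycles
from circlegait.simulate import GaitSignalParams, generate_gait_accel
from circlegait.types import FEATURE_NAMES, AccelTrial, GaitFeatureVector, StepSegmentation

from conftest import make_trial


def seg_from_truth(onsets):
    """Segmentation built from ground-truth onset times."""
    return StepSegmentation((np.asarray(onsets) * 100).round().astype(int))


class TestWelch:
    def test_pure_tone_lands_in_its_bin(self):
        t = np.arange(3000) / 100.0
        psd = welch_psd(np.sin(2 * np.pi * 2.0 * t))
        assert abs(psd.freqs[np.argmax(psd.power)] - 2.0) <= psd.resolution
        assert psd.resolution == pytest.approx(100 / 9000)

    def test_integrated_psd_matches_variance(self):
        t = np.arange(3000) / 100.0
        x = np.sin(2 * np.pi * 2.0 * t)
        psd = welch_psd(x)
        total = np.trapezoid(psd.power, psd.freqs)
        assert total == pytest.approx(x.var(), rel=0.05)

    @pytest.mark.parametrize("seed", [0, 1])
    def test_white_noise_spectrum_is_flat(self, seed):
        x = np.random.default_rng(seed).normal(0, 1, 4000)
        psd = welch_psd(x)
        band = psd.power[psd.freqs > 0.1]
        assert band.max() / np.median(band) < 10

    def test_short_signal_aborts(self):
        with pytest.raises(ValueError):
            welch_psd(np.ones(200))


class TestTemporal:
    def test_counts_and_duration(self):
        onsets = 2.0 + 0.55 * np.arange(21)
        seg = seg_from_truth(onsets)
        n = 2000
        trial = AccelTrial(time=np.arange(n) / 100, acc_vt=np.zeros(n) + 9.81,
                           acc_ml=np.zeros(n), acc_ap=np.zeros(n), trial_bounds=(200, 1700))
        n_steps, dur = temporal_counts(seg, trial)
        assert n_steps == 20
        assert dur == pytest.approx(15.0)

    def test_asymmetry_hand_example(self):
        durs = np.tile([0.5, 0.6], 10)
        onsets = np.concatenate([[0.0], np.cumsum(durs)])
        assert step_time_asymmetry(seg_from_truth(2.0 + onsets)) == pytest.approx(0.10, abs=1e-9)

    def test_asymmetry_from_generator_truth(self):
        p = GaitSignalParams(n_strides=15, stride_time_sd=0.0, step_asymmetry=0.04,
                             noise_sd=0.0, seed=1)
        _, onsets = generate_gait_accel(p)
        assert step_time_asymmetry(seg_from_truth(onsets)) == pytest.approx(0.04, abs=0.01)

    def test_equal_steps_have_zero_asymmetry(self):
        onsets = 2.0 + 0.55 * np.arange(20)
        assert step_time_asymmetry(seg_from_truth(onsets)) == pytest.approx(0.0, abs=1e-9)


class TestStrideStats:
    def test_outlier_is_trimmed(self):
        strides = np.concatenate([np.full(20, 1.0), [2.0]])
        # onsets with these stride durations: steps of stride/2
        durs = np.repeat(strides / 2, 2)
        onsets = np.concatenate([[0.0], np.cumsum(durs)])
        med, var = stride_time_stats(seg_from_truth(onsets))
        assert med == pytest.approx(1.0, abs=0.02)
        assert var < 0.02  # the 2 s outlier is excluded

    def test_trimmed_sd_matches_oracle(self):
        rng = np.random.default_rng(0)
        x = rng.normal(1.0, 0.05, 200)
        # independent oracle: sort, drop ceil(5%) from each tail, population SD
        s = np.sort(x)
        k = int(np.ceil(0.05 * x.size))
        oracle = np.std(s[k:-k])
        assert trimmed_sd(x) == pytest.approx(oracle, rel=1e-12)

    def test_trimmed_never_exceeds_untrimmed(self):
        from hypothesis import given, settings, strategies as st

        @settings(max_examples=50, derandomize=True, deadline=None)
        @given(st.lists(st.floats(-1e6, 1e6), min_size=6, max_size=200))
        def check(values):
            x = np.asarray(values)
            sd = np.std(x)
            assert trimmed_sd(x) <= sd + 1e-9 + 1e-9 * sd

        check()


class TestSignalSd:
    def test_closed_forms_and_oracle(self):
        n = 2000
        t = np.arange(n) / 100.0
        rng = np.random.default_rng(2)
        noise = rng.normal(0, 1, n)
        trial = AccelTrial(time=t, acc_vt=np.full(n, 3.0), acc_ml=np.sin(2 * np.pi * 2 * t),
                           acc_ap=noise, trial_bounds=(0, n))
        sds = signal_sd(trial)
        assert sds["vt"] == pytest.approx(0.0, abs=1e-12)
        assert sds["ml"] == pytest.approx(1 / np.sqrt(2), rel=0.01)
        # naive two-pass oracle
        mu = noise.mean()
        oracle = np.sqrt(np.sum((noise - mu) ** 2) / (n - 1))
        assert sds["ap"] == pytest.approx(oracle, rel=1e-12)


class TestRegularity:
    def test_periodic_signal_is_fully_regular(self):
        t = np.arange(3000) / 100.0
        x = np.sin(2 * np.pi * 1.0 * t)
        assert cyclic_regularity(x, 1.0) >= 0.99

    def test_white_noise_is_irregular(self):
        for seed in range(3):
            x = np.random.default_rng(seed).normal(0, 1, 2000)
            assert abs(cyclic_regularity(x, 0.5)) < 0.2

    def test_alternating_step_shapes_favor_stride_lag(self):
        # odd steps scaled 1.5x: step-lag similarity drops, stride-lag stays
        t = np.arange(4000) / 100.0
        step = np.sin(2 * np.pi * 2.0 * t)
        scale = np.where((t // 0.5).astype(int) % 2 == 1, 1.5, 1.0)
        x = step * scale
        step_reg = cyclic_regularity(x - x.mean(), 0.5)
        stride_reg = cyclic_regularity(x - x.mean(), 1.0)
        assert step_reg < stride_reg

    def test_overlong_lag_rejected(self):
        with pytest.raises(ValueError):
            cyclic_regularity(np.sin(np.arange(300) / 10), 2.0)


class TestHarmonicRatio:
    AMPS = (0.25, 1.0, 0.0, 0.5)  # odd A1=0.25; even A2=1.0, A4=0.5

    def _trial(self):
        p = GaitSignalParams(n_strides=30, mean_stride_time=1.0, stride_time_sd=0.0,
                             noise_sd=0.0, harmonic_amps_vt=self.AMPS,
                             harmonic_amps_ml=self.AMPS, harmonic_amps_ap=self.AMPS, seed=1)
        trial, _ = generate_gait_accel(p)
        return trial

    def test_constructed_amplitude_ratio(self):
        trial = self._trial()
        x = trial.walking("vt")
        hr = harmonic_ratio(x - x.mean(), 1.0, "vt")
        assert hr == pytest.approx((1.0 + 0.5) / 0.25, rel=0.05)

    def test_ml_is_reciprocal_by_definition(self):
        trial = self._trial()
        x = trial.walking("ml")
        hr_ml = harmonic_ratio(x - x.mean(), 1.0, "ml")
        assert hr_ml == pytest.approx(0.25 / 1.5, rel=0.05)

    def test_even_only_signal_has_huge_ratio(self):
        p = GaitSignalParams(n_strides=20, mean_stride_time=1.0, stride_time_sd=0.0,
                             noise_sd=0.0, harmonic_amps_vt=(1e-8, 1.0), seed=2)
        trial, _ = generate_gait_accel(p)
        x = trial.walking("vt")
        assert harmonic_ratio(x - x.mean(), 1.0, "vt") > 100


class TestIndexOfHarmonicity:
    def test_pure_fundamental_is_one(self):
        t = np.arange(3000) / 100.0
        psd = welch_psd(np.sin(2 * np.pi * 2.0 * t))
        assert index_of_harmonicity(psd, 2.0) >= 0.95

    def test_six_equal_harmonics_give_one_sixth(self):
        t = np.arange(6000) / 100.0
        x = sum(np.sin(2 * np.pi * 1.0 * k * t + 0.3 * k) for k in range(1, 7))
        psd = welch_psd(x)
        assert index_of_harmonicity(psd, 1.0) == pytest.approx(1 / 6, rel=0.10)

    def test_always_within_unit_interval(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            amps = rng.uniform(0, 2, 6)
            t = np.arange(3000) / 100.0
            x = sum(a * np.sin(2 * np.pi * 1.1 * k * t) for k, a in enumerate(amps, 1))
            x += rng.normal(0, 0.1, x.size)
            ih = index_of_harmonicity(welch_psd(x), 1.1)
            assert 0.0 <= ih <= 1.0


class TestSpectralPeak:
    def test_tone_width_matches_window_mainlobe(self):
        t = np.arange(3000) / 100.0
        psd = welch_psd(np.sin(2 * np.pi * 2.0 * t))
        _, width = spectral_peak_features(psd)
        hann_fwhm = 1.44 * 100 / 900  # FWHM of the Hanning mainlobe, 900-sample window
        assert width == pytest.approx(hann_fwhm, rel=0.20)

    def test_width_grows_with_stride_jitter(self):
        widths = []
        for sd in (0.0, 0.0125, 0.025, 0.0375, 0.05):
            per_seed = []
            for seed in range(6):
                trial, _ = make_trial(n_strides=30, stride_time_sd=sd, noise_sd=0.05, seed=seed)
                x = trial.walking("ap")
                psd = welch_psd(x - x.mean())
                per_seed.append(spectral_peak_features(psd)[1])
            widths.append(np.mean(per_seed))
        assert np.all(np.diff(widths) > 0)

    def test_noise_reduces_normalized_peak(self):
        peaks = []
        for noise in (0.0, 0.5, 1.5):
            trial, _ = make_trial(n_strides=25, stride_time_sd=0.0, noise_sd=noise, seed=9)
            x = trial.walking("ap")
            peaks.append(spectral_peak_features(welch_psd(x - x.mean()))[0])
        assert peaks[0] > peaks[1] > peaks[2]


class TestFeatureVector:
    def test_exactly_24_locked_names(self, default_trial):
        trial, _ = default_trial
        vec = extract_feature_vector(trial)
        assert len(vec.values) == 24
        assert tuple(vec.values) == FEATURE_NAMES
        with pytest.raises(ValueError):
            GaitFeatureVector({"n_steps": 1.0})

    def test_extraction_is_deterministic(self, default_trial):
        trial, _ = default_trial
        a = extract_feature_vector(trial).as_array()
        b = extract_feature_vector(trial).as_array()
        assert np.array_equal(a, b)

    def test_amplitude_scaling_touches_only_sd(self, clean_trial):
        trial, _ = clean_trial
        seg = segment_step_cycles(trial)
        v1 = extract_feature_vector(trial, seg)
        doubled = trial.with_axes(2 * trial.acc_vt, 2 * trial.acc_ml, 2 * trial.acc_ap)
        v2 = extract_feature_vector(doubled, seg)
        for name in FEATURE_NAMES:
            if name.startswith("sd_"):
                assert v2[name] == pytest.approx(2 * v1[name], rel=1e-6)
            elif name.startswith("norm_peak"):
                # peak/total integrated power is amplitude-invariant
                assert v2[name] == pytest.approx(v1[name], rel=0.01)
            else:
                assert v2[name] == pytest.approx(v1[name], rel=0.01, abs=1e-9)

    def test_standing_prefix_length_is_irrelevant(self):
        kwargs = dict(n_strides=20, stride_time_sd=0.0, noise_sd=0.0, seed=13,
                      harmonic_amps_vt=(0.0, 2.0, 0.0, 0.8),
                      harmonic_amps_ml=(1.0, 0.0, 0.3),
                      harmonic_amps_ap=(0.0, 1.4, 0.0, 0.5))
        va = extract_feature_vector(make_trial(standing_duration=1.5, **kwargs)[0])
        vb = extract_feature_vector(make_trial(standing_duration=4.0, **kwargs)[0])
        for name in FEATURE_NAMES:
            if name == "total_duration":
                continue
            assert va[name] == pytest.approx(vb[name], rel=0.02, abs=1e-9)

    def test_failed_segmentation_yields_flagged_nan_vector(self):
        from conftest import white_noise_trial

        vec = extract_feature_vector(white_noise_trial(seed=1))
        assert "segmentation" in vec.flags
        assert np.isnan(vec.as_array()).all()


class TestAverageDirections:
    def _vec(self, value):
        return GaitFeatureVector({k: value for k in FEATURE_NAMES})

    def test_mean_and_commutativity(self):
        a, b = self._vec(1.0), self._vec(3.0)
        ab = average_directions(a, b)
        ba = average_directions(b, a)
        assert all(ab[k] == 2.0 for k in FEATURE_NAMES)
        assert ab.values == ba.values

    def test_identical_inputs_unchanged(self):
        a = self._vec(1.7)
        assert average_directions(a, a).values == a.values

    def test_flagged_side_falls_back_to_other(self):
        a, b = self._vec(1.0), self._vec(3.0)
        a.values["sd_vt"] = float("nan")
        out = average_directions(a, b)
        assert out["sd_vt"] == 3.0
        assert out["sd_ml"] == 2.0


class TestParameterRecovery:
    """Generator sweeps produce monotone feature responses."""

    def test_stride_time_variability_tracks_jitter(self):
        levels = (0.005, 0.015, 0.03, 0.045, 0.06)
        resp = []
        for sd in levels:
            vals = []
            for seed in range(10):
                p = GaitSignalParams(n_strides=40, stride_time_sd=sd, seed=seed)
                _, onsets = generate_gait_accel(p)
                _, v = stride_time_stats(seg_from_truth(onsets))
                vals.append(v)
            resp.append(np.mean(vals))
        assert np.all(np.diff(resp) > 0)

    def test_asymmetry_tracks_generator_offset(self):
        levels = (0.0, 0.01, 0.02, 0.03, 0.04)
        resp = []
        for asym in levels:
            vals = []
            for seed in range(10):
                p = GaitSignalParams(n_strides=30, stride_time_sd=0.01,
                                     step_asymmetry=asym, seed=seed)
                _, onsets = generate_gait_accel(p)
                vals.append(step_time_asymmetry(seg_from_truth(onsets)))
            resp.append(np.mean(vals))
        assert np.all(np.diff(resp) > 0)

    def test_harmonic_ratio_tracks_even_odd_balance(self):
        resp = []
        for even in (0.5, 1.0, 1.5, 2.0, 2.5):
            vals = []
            for seed in range(5):
                amps = (0.5, even, 0.2, even / 3)
                trial, _ = make_trial(n_strides=25, stride_time_sd=0.0, noise_sd=0.05,
                                      harmonic_amps_vt=amps, seed=seed)
                x = trial.walking("vt")
                vals.append(harmonic_ratio(x - x.mean(), 1.05, "vt"))
            resp.append(np.mean(vals))
        assert np.all(np.diff(resp) > 0)

    def test_regularity_degrades_with_noise(self):
        resp = []
        for noise in (0.0, 0.4, 0.8, 1.2, 1.6):
            vals = []
            for seed in range(5):
                trial, _ = make_trial(n_strides=25, stride_time_sd=0.0, noise_sd=noise, seed=seed)
                x = trial.walking("vt")
                vals.append(cyclic_regularity(x - x.mean(), 1.05))
            resp.append(np.mean(vals))
        assert np.all(np.diff(resp) < 0)
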