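import math

import numpy as np
import pytest

from cogspeech._types import AudioClip
from cogspeech.acoustic import (
    Segmentation,
    acoustic_feature_vector,
    detect_voiced_segments,
    extract_lld_matrix,
    lld_functionals,
    segment_duration_stats,
    signal_summary_stats,
)
from cogspeech.synthetic import gen_audio_clip


def tone(freq, duration=1.0, rate=16000, amp=0.5):
    t = np.arange(int(duration * rate)) / rate
    return AudioClip(samples=amp * np.sin(2 * np.pi * freq * t), rate=rate)


def silence(duration=1.0, rate=16000):
    return AudioClip(samples=np.zeros(int(duration * rate)), rate=rate)


# --- naive reference for the functionals ------------------------------------

def ref_functionals(x):
    x = np.asarray(x, float)
    mean = x.mean()
    sd = x.std(ddof=1) if x.size > 1 else 0.0
    q1, q2, q3 = np.quantile(x, [0.25, 0.5, 0.75])
    d = np.diff(x)
    pos, neg = d[d > 0], d[d < 0]
    m2 = ((x - mean) ** 2).mean()
    return {
        "mean": mean,
        "cv": sd / mean if mean != 0 else 0.0,
        "q1": q1, "q2": q2, "q3": q3, "iqr": q3 - q1,
        "posslope": pos.mean() if pos.size else 0.0,
        "negslope": neg.mean() if neg.size else 0.0,
        "skew": ((x - mean) ** 3).mean() / m2**1.5 if m2 > 0 else 0.0,
        "kurtosis": ((x - mean) ** 4).mean() / m2**2 - 3 if m2 > 0 else 0.0,
    }


class TestFunctionals:
    def test_hand_arithmetic(self):
        f = lld_functionals(np.array([1.0, 2.0, 3.0, 4.0]))
        assert f["mean"] == pytest.approx(2.5)
        assert f["q2"] == pytest.approx(2.5)
        assert f["posslope"] == pytest.approx(1.0)
        assert f["negslope"] == 0.0

    def test_constant_series(self):
        f = lld_functionals(np.array([5.0, 5.0, 5.0]))
        assert f["cv"] == 0.0 and f["iqr"] == 0.0 and f["skew"] == 0.0

    def test_mixed_slopes(self):
        f = lld_functionals(np.array([1.0, 3.0, 2.0]))
        assert f["posslope"] == pytest.approx(2.0)
        assert f["negslope"] == pytest.approx(-1.0)

    def test_empty_masked_series_all_missing(self):
        f = lld_functionals(np.array([1.0, 2.0]), mask=np.array([False, False]))
        assert all(math.isnan(v) for v in f.values())

    def test_matches_reference_on_random_series(self, rng):
        for _ in range(1000):
            x = rng.normal(size=int(rng.integers(2, 60)))
            got = lld_functionals(x)
            want = ref_functionals(x)
            for k in want:
                assert got[k] == pytest.approx(want[k], abs=1e-9), k


class TestLLDExtraction:
    def test_220hz_semitone(self):
        lld = extract_lld_matrix(tone(220.0))
        med = np.nanmedian(lld.descriptors["f0semitone"])
        assert med == pytest.approx(36.0, abs=0.5)  # 220 = 27.5 * 2^3

    def test_silence_unvoiced_zero_loudness(self):
        lld = extract_lld_matrix(silence())
        assert not lld.voiced_mask.any()
        assert np.nanmax(lld.descriptors["loudness"]) == pytest.approx(0.0)

    def test_constant_tone_near_zero_perturbation(self):
        clip, _ = gen_audio_clip(f0=180, voiced_pattern=(True,), snr_db=None,
                                 duration=1.0, seed=0)
        lld = extract_lld_matrix(clip)
        assert np.nanmean(lld.descriptors["jitter"]) == pytest.approx(0, abs=1e-2)
        assert np.nanmean(lld.descriptors["shimmer"]) == pytest.approx(0, abs=1e-1)

    def test_f0_accuracy_across_range_and_snr(self):
        for f0 in (80.0, 150.0, 280.0, 400.0):
            for snr in (None, 20.0):
                clip, _ = gen_audio_clip(f0=f0, voiced_pattern=(True,),
                                         snr_db=snr, duration=0.8, seed=1)
                lld = extract_lld_matrix(clip)
                st = np.nanmedian(lld.descriptors["f0semitone"])
                hz = 27.5 * 2 ** (st / 12)
                assert abs(hz - f0) / f0 < 0.02

    def test_f0_defined_only_on_voiced_frames(self):
        clip, _ = gen_audio_clip(f0=140, voiced_pattern=(True, False),
                                 duration=1.0, seed=2)
        lld = extract_lld_matrix(clip)
        assert np.all(np.isnan(lld.descriptors["f0semitone"][~lld.voiced_mask]))

    def test_too_short_clip_rejected(self):
        with pytest.raises(ValueError):
            extract_lld_matrix(AudioClip(samples=np.zeros(100), rate=16000))


class TestVad:
    def test_tone_then_silence_single_interval(self):
        clip, truth = gen_audio_clip(f0=160, voiced_pattern=(True, False),
                                     snr_db=None, duration=1.0, seed=0)
        lld = extract_lld_matrix(clip)
        seg = detect_voiced_segments(clip, lld)
        assert len(seg.voiced) == 1
        a, b = seg.voiced[0]
        want_a, want_b = truth["voiced_intervals"][0]
        assert (min(b, want_b) - max(a, want_a)) >= 0.9 * (want_b - want_a)

    def test_all_silence_empty(self):
        clip = silence()
        seg = detect_voiced_segments(clip, extract_lld_matrix(clip))
        assert seg.voiced == []
        assert seg.unvoiced == [(0.0, clip.duration)]

    def test_alternating_pattern_three_intervals(self):
        clip, _ = gen_audio_clip(
            f0=150, voiced_pattern=(True, False, True, False, True, False),
            snr_db=None, duration=1.8, seed=0)
        lld = extract_lld_matrix(clip)
        seg = detect_voiced_segments(clip, lld)
        assert len(seg.voiced) == 3

    def test_external_backend_contract(self):
        clip = silence()
        backend = lambda c: Segmentation(voiced=[(0.0, 0.5)],  # noqa: E731
                                         unvoiced=[(0.5, 1.0)])
        seg = detect_voiced_segments(clip, extract_lld_matrix(clip), backend)
        assert seg.voiced == [(0.0, 0.5)]


class TestSignalSummary:
    def test_pure_tone_centroid(self):
        s = signal_summary_stats(tone(1000.0))
        assert s["sig_centroid_mean"] == pytest.approx(1000.0, rel=0.05)

    def test_noise_zcr_above_tone(self, rng):
        noise = AudioClip(samples=rng.uniform(-0.5, 0.5, 16000), rate=16000)
        s_noise = signal_summary_stats(noise)
        s_tone = signal_summary_stats(tone(440.0))
        assert s_noise["sig_zcr_mean"] > s_tone["sig_zcr_mean"]

    def test_silence_zero_rms(self):
        assert signal_summary_stats(silence())["sig_rms_mean"] == 0.0


class TestSegmentDurations:
    def test_constant_durations(self):
        seg = Segmentation(voiced=[(0.0, 0.3), (0.5, 0.8), (1.0, 1.3)],
                           unvoiced=[(0.3, 0.5), (0.8, 1.0)])
        s = segment_duration_stats(seg)
        assert s["voiced_dur_mean"] == pytest.approx(0.3)
        assert s["voiced_dur_sd"] == pytest.approx(0.0, abs=1e-12)

    def test_two_durations(self):
        seg = Segmentation(voiced=[(0.0, 0.2), (0.5, 0.9)], unvoiced=[])
        s = segment_duration_stats(seg)
        assert s["voiced_dur_mean"] == pytest.approx(0.3)
        assert s["voiced_dur_q2"] == pytest.approx(0.3)

    def test_empty_class_flagged(self):
        seg = Segmentation(voiced=[(0.0, 1.0)], unvoiced=[])
        s = segment_duration_stats(seg)
        assert s["unvoiced_count"] == 0.0
        assert s["unvoiced_dur_mean"] == 0.0


class TestFeatureVector:
    def test_schema_and_determinism(self):
        clip, _ = gen_audio_clip(f0=190, voiced_pattern=(True, False, True),
                                 snr_db=25.0, duration=1.2, seed=4)
        v1 = acoustic_feature_vector(clip)
        v2 = acoustic_feature_vector(clip)
        assert v1 == v2
        assert "ac_f0semitone_mean_img" in v1
        assert "ac_loudness_mean_img" in v1
        assert "ac_alpharatio_mean_unvoiced_img" in v1

    def test_silence_only_global_features(self):
        v = acoustic_feature_vector(silence(1.5))
        assert math.isnan(v["ac_f0semitone_mean_img"])
        assert not math.isnan(v["ac_loudness_mean_img"])
        assert v["ac_seg_voiced_count_img"] == 0.0

    def test_gain_invariance_of_pitch_and_spectral_stats(self):
        clip, _ = gen_audio_clip(f0=170, voiced_pattern=(True,), snr_db=None,
                                 duration=0.8, seed=5)
        half = AudioClip(samples=clip.samples * 0.5, rate=clip.rate)  # -6 dB
        v1, v2 = acoustic_feature_vector(clip), acoustic_feature_vector(half)
        for key in ("ac_f0semitone_mean_img", "ac_sig_zcr_mean_img",
                    "ac_sig_centroid_mean_img"):
            assert v1[key] == pytest.approx(v2[key], rel=1e-2, abs=1e-6)
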