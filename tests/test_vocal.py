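"""Vocal domain: framing, pitch, rhythm, level, power, duration."""

import numpy as np
import pytest

from fatiguefusion.errors import InvalidParameterError
from fatiguefusion.fixtures import synth_speech
from fatiguefusion.vocal import (
    AudioClip,
    average_power,
    frame_signal,
    fundamental_frequency,
    rate_of_speech,
    sound_pressure_level,
    speech_duration,
    vocal_features,
)


def autocorr_oracle(samples, sr):
    """Whole-clip autocorrelation pitch oracle, 50-400 Hz band."""
    x = samples - samples.mean()
    ac = np.correlate(x, x, mode="full")[len(x) - 1 :]
    lo, hi = int(sr / 400), int(sr / 50)
    k = int(np.argmax(ac[lo : hi + 1])) + lo
    a, b, c = ac[k - 1], ac[k], ac[k + 1]
    delta = 0.5 * (a - c) / (a - 2 * b + c)
    return sr / (k + delta)


class TestFrameSignal:
    def test_frame_count_formula(self):
        clip = AudioClip(samples=np.zeros(16000), sample_rate=16000)
        frames = frame_signal(clip, frame_len_ms=25, hop_ms=10)
        assert frames.shape == (98, 400)  # floor((16000-400)/160)+1

    def test_non_overlapping_partition(self):
        clip = AudioClip(samples=np.arange(8000.0) / 8000, sample_rate=8000)
        frames = frame_signal(clip, frame_len_ms=100, hop_ms=100)
        assert frames.shape == (10, 800)
        assert np.array_equal(frames.ravel(), clip.samples[:8000])

    def test_short_clip_single_frame_with_warning(self):
        clip = AudioClip(samples=np.zeros(100), sample_rate=8000)
        with pytest.warns(UserWarning):
            frames = frame_signal(clip, frame_len_ms=40, hop_ms=10)
        assert frames.shape == (1, 100)

    def test_hop_larger_than_frame_rejected(self):
        clip = AudioClip(samples=np.zeros(8000), sample_rate=8000)
        with pytest.raises(InvalidParameterError):
            frame_signal(clip, frame_len_ms=10, hop_ms=20)


class TestFundamentalFrequency:
    @pytest.mark.parametrize("f0", [80.0, 120.0, 200.0, 300.0])
    def test_recovers_harmonic_fixture_within_2hz(self, f0):
        clip, truth = synth_speech(f0, 1.0, sample_rate=16000, seed=1)
        est = fundamental_frequency(clip)
        assert est == pytest.approx(truth.f0, abs=2.0)
        assert autocorr_oracle(clip.samples, 16000) == pytest.approx(f0, abs=2.0)

    def test_white_noise_flagged_unvoiced(self):
        rng = np.random.default_rng(0)
        clip = AudioClip(samples=0.3 * rng.normal(size=16000), sample_rate=16000)
        assert fundamental_frequency(clip) is None

    def test_no_octave_error_with_strong_second_harmonic(self):
        sr, t = 16000, np.arange(16000) / 16000
        x = 0.2 * np.sin(2 * np.pi * 100 * t) + 0.6 * np.sin(2 * np.pi * 200 * t)
        clip = AudioClip(samples=x, sample_rate=sr)
        assert fundamental_frequency(clip) == pytest.approx(100.0, abs=2.0)

    def test_resample_invariance(self):
        for sr in (16000, 44100):
            clip, _ = synth_speech(200.0, 1.0, sample_rate=sr, seed=2)
            assert fundamental_frequency(clip) == pytest.approx(200.0, abs=2.0)


class TestRateOfSpeech:
    def test_silence_is_zero(self):
        clip = AudioClip(samples=np.zeros(16000), sample_rate=16000)
        assert rate_of_speech(clip) == 0.0

    def test_four_bursts_in_ten_seconds(self):
        # speech everywhere except four long pauses -> 4 voiced segments
        pauses = [(0.0, 0.5), (2.5, 1.0), (5.0, 1.0), (7.5, 1.0), (9.5, 0.5)]
        clip, _ = synth_speech(150.0, 10.0, 16000, pause_spec=pauses, seed=3)
        assert rate_of_speech(clip) == pytest.approx(0.4, abs=0.05)

    def test_continuous_tone_is_single_segment(self):
        clip, _ = synth_speech(150.0, 2.0, 16000, seed=4)
        assert rate_of_speech(clip) == pytest.approx(1 / 2.0, abs=0.05)


class TestLevelAndPower:
    def test_full_scale_square_wave_is_zero_dbfs(self):
        x = np.where(np.arange(8000) % 80 < 40, 1.0, -1.0)
        clip = AudioClip(samples=x, sample_rate=8000)
        assert sound_pressure_level(clip) == pytest.approx(0.0, abs=1e-9)

    def test_unit_sine_is_minus_3db(self):
        t = np.arange(16000) / 16000
        clip = AudioClip(samples=np.sin(2 * np.pi * 200 * t), sample_rate=16000)
        assert sound_pressure_level(clip) == pytest.approx(-3.0103, abs=0.01)

    def test_silence_clamped_at_floor(self):
        clip = AudioClip(samples=np.zeros(8000), sample_rate=8000)
        assert sound_pressure_level(clip) == -120.0

    def test_gain_adds_exactly_in_db(self):
        rng = np.random.default_rng(5)
        x = 0.05 * rng.normal(size=8000)
        base = sound_pressure_level(AudioClip(samples=x, sample_rate=8000))
        scaled = sound_pressure_level(AudioClip(samples=4 * x, sample_rate=8000))
        assert scaled - base == pytest.approx(20 * np.log10(4), abs=1e-9)

    def test_average_power_of_unit_sine(self):
        t = np.arange(16000) / 16000
        clip = AudioClip(samples=np.sin(2 * np.pi * 100 * t), sample_rate=16000)
        assert average_power(clip) == pytest.approx(0.5, abs=1e-3)

    def test_average_power_matches_spectral_oracle(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=4096) * 0.1
        clip = AudioClip(samples=x, sample_rate=8000)
        spectral = np.sum(np.abs(np.fft.fft(x)) ** 2) / len(x) ** 2
        assert average_power(clip) == pytest.approx(spectral, rel=1e-9)


class TestSpeechDuration:
    def test_silence_is_zero(self):
        clip = AudioClip(samples=np.zeros(16000), sample_rate=16000)
        assert speech_duration(clip) == 0.0

    def test_voiced_span_between_pauses(self):
        pauses = [(0.0, 2.0), (7.0, 3.0)]  # voiced only in [2 s, 7 s]
        clip, _ = synth_speech(150.0, 10.0, 16000, pause_spec=pauses, seed=7)
        assert speech_duration(clip) == pytest.approx(5.0, abs=0.05)

    def test_fully_voiced_clip_spans_duration(self):
        clip, _ = synth_speech(150.0, 3.0, 16000, seed=8)
        assert speech_duration(clip) == pytest.approx(3.0, abs=0.05)


def test_vocal_features_bundle_consistent_with_components():
    clip, _ = synth_speech(180.0, 4.0, 16000, pause_spec=[(1.5, 0.5)], seed=9)
    vec = vocal_features(clip)
    assert vec.FFP == pytest.approx(fundamental_frequency(clip))
    assert vec.RSH == pytest.approx(rate_of_speech(clip))
    assert vec.SPL == pytest.approx(sound_pressure_level(clip))
    assert vec.PSD == pytest.approx(average_power(clip))
    assert vec.SPD == pytest.approx(speech_duration(clip))
    assert vec.SPD <= clip.duration
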