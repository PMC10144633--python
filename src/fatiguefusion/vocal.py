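"""Vocal features from a mono audio clip: pitch, rhythm, level, power, duration.

Five scalar features summarise one prompted-sentence recording:

FFP  fundamental frequency (pitch) in Hz, the median over voiced frames of
     an autocorrelation peak search restricted to 50-400 Hz; None when no
     frame passes the voicing gate
RSH  rate of speech as voiced segments per second — a pause-pattern rate
     (adjacent voiced frames merge; gaps shorter than 100 ms are bridged)
SPL  sound pressure level in dB relative to digital full scale (no
     microphone calibration exists for file input), floor-clamped at -120
PSD  average signal power, the finite-sample mean square (the discrete
     realisation of the limiting time-average power of s(t))
SPD  speech duration in seconds: last voiced-frame end minus first
     voiced-frame start, 0 for an all-silent clip

Voicing gate: frame RMS above a fixed dBFS energy threshold AND normalized
autocorrelation peak above a periodicity threshold; both configurable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.io import wavfile

from .errors import InvalidParameterError

__all__ = [
    "AudioClip",
    "VocalFeatureVector",
    "VoicingGate",
    "read_wav",
    "write_wav",
    "frame_signal",
    "fundamental_frequency",
    "rate_of_speech",
    "sound_pressure_level",
    "average_power",
    "speech_duration",
    "vocal_features",
    "VOCAL_FEATURE_NAMES",
]

VOCAL_FEATURE_NAMES = ("FFP", "RSH", "SPL", "PSD", "SPD")

PITCH_MIN_HZ = 50.0
PITCH_MAX_HZ = 400.0
SPL_FLOOR_DB = -120.0


@dataclass(frozen=True)
class AudioClip:
    """Mono audio samples in [-1, 1] at a known sample rate (>= 8 kHz)."""

    samples: np.ndarray
    sample_rate: int

    def __post_init__(self):
        samples = np.asarray(self.samples, dtype=float).ravel()
        if samples.size == 0:
            raise InvalidParameterError("audio clip is empty")
        if self.sample_rate < 8000:
            raise InvalidParameterError("sample_rate must be >= 8000 Hz")
        object.__setattr__(self, "samples", samples)

    @property
    def duration(self) -> float:
        return len(self.samples) / self.sample_rate


@dataclass(frozen=True)
class VocalFeatureVector:
    FFP: float | None  # Hz; None = unvoiced clip
    RSH: float
    SPL: float
    PSD: float
    SPD: float

    def as_array(self) -> np.ndarray:
        vals = [np.nan if self.FFP is None else self.FFP]
        vals += [self.RSH, self.SPL, self.PSD, self.SPD]
        return np.array(vals, dtype=float)


@dataclass(frozen=True)
class VoicingGate:
    """Energy + periodicity gate labelling frames voiced or unvoiced."""

    energy_threshold_db: float = -45.0
    periodicity_threshold: float = 0.3
    frame_len_ms: float = 40.0
    hop_ms: float = 10.0


def read_wav(path: str | Path) -> AudioClip:
    """Read a PCM/float WAV; stereo input is down-mixed with a warning."""
    rate, data = wavfile.read(str(path))
    data = np.asarray(data)
    if data.ndim == 2:
        warnings.warn(f"{path}: stereo input down-mixed to mono", stacklevel=2)
        data = data.mean(axis=1)
    if np.issubdtype(data.dtype, np.integer):
        data = data / float(np.iinfo(data.dtype).max)
    return AudioClip(samples=data.astype(float), sample_rate=int(rate))


def write_wav(clip: AudioClip, path: str | Path) -> None:
    pcm = np.clip(clip.samples, -1.0, 1.0)
    wavfile.write(str(path), clip.sample_rate, (pcm * 32767).astype(np.int16))


def frame_signal(
    clip: AudioClip, frame_len_ms: float = 40.0, hop_ms: float = 10.0
) -> np.ndarray:
    """Slice the clip into overlapping frames (last partial frame dropped).

    Returns a (n_frames, frame_len) array. A clip shorter than one frame
    falls back to a single frame (the whole clip) with a warning.
    """
    if hop_ms <= 0 or frame_len_ms < hop_ms:
        raise InvalidParameterError("require frame_len >= hop > 0")
    frame_len = int(round(frame_len_ms * clip.sample_rate / 1000.0))
    hop = int(round(hop_ms * clip.sample_rate / 1000.0))
    x = clip.samples
    if len(x) < frame_len:
        warnings.warn("clip shorter than one frame; using a single frame", stacklevel=2)
        return x[np.newaxis, :]
    n_frames = (len(x) - frame_len) // hop + 1
    idx = np.arange(frame_len)[np.newaxis, :] + hop * np.arange(n_frames)[:, np.newaxis]
    return x[idx]


def _frame_rms_db(frames: np.ndarray) -> np.ndarray:
    rms = np.sqrt(np.mean(frames**2, axis=1))
    with np.errstate(divide="ignore"):
        return np.maximum(20.0 * np.log10(np.where(rms > 0, rms, 1e-12)), SPL_FLOOR_DB)


def _autocorr_pitch(frame: np.ndarray, sr: int) -> tuple[float | None, float]:
    """(f0, normalized peak) from the autocorrelation of one frame.

    Searches lags for 50-400 Hz; the peak lag is refined by parabolic
    interpolation so the estimate is not quantised to integer lags.
    """
    frame = frame - frame.mean()
    energy = float(np.dot(frame, frame))
    if energy <= 0:
        return None, 0.0
    ac = np.correlate(frame, frame, mode="full")[len(frame) - 1 :]
    lag_min = max(int(np.floor(sr / PITCH_MAX_HZ)), 2)
    lag_max = int(np.ceil(sr / PITCH_MIN_HZ))
    if lag_max >= len(ac):
        lag_max = len(ac) - 1
    if lag_min >= lag_max:
        return None, 0.0
    seg = ac[lag_min : lag_max + 1]
    k = int(np.argmax(seg)) + lag_min
    peak = ac[k] / ac[0]
    if 0 < k < len(ac) - 1:
        a, b, c = ac[k - 1], ac[k], ac[k + 1]
        denom = a - 2 * b + c
        delta = 0.5 * (a - c) / denom if denom != 0 else 0.0
        delta = float(np.clip(delta, -0.5, 0.5))
    else:
        delta = 0.0
    return sr / (k + delta), float(peak)


def _voiced_mask(
    clip: AudioClip, gate: VoicingGate
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(voiced mask, per-frame f0 or nan, frame start times in s)."""
    frames = frame_signal(clip, gate.frame_len_ms, gate.hop_ms)
    energies = _frame_rms_db(frames)
    f0s = np.full(len(frames), np.nan)
    voiced = np.zeros(len(frames), dtype=bool)
    for i, frame in enumerate(frames):
        if energies[i] <= gate.energy_threshold_db:
            continue
        f0, peak = _autocorr_pitch(frame, clip.sample_rate)
        if f0 is not None and peak > gate.periodicity_threshold:
            voiced[i] = True
            f0s[i] = f0
    hop_s = gate.hop_ms / 1000.0
    starts = hop_s * np.arange(len(frames))
    return voiced, f0s, starts


def fundamental_frequency(
    clip: AudioClip, gate: VoicingGate = VoicingGate()
) -> float | None:
    """Median pitch (Hz) over voiced frames, or None for an unvoiced clip."""
    voiced, f0s, _ = _voiced_mask(clip, gate)
    if not voiced.any():
        return None
    return float(np.median(f0s[voiced]))


def _voiced_segments(
    voiced: np.ndarray, starts: np.ndarray, frame_len_s: float, bridge_s: float = 0.1
) -> list[tuple[float, float]]:
    """Merge voiced frames into (start, end) segments, bridging short gaps."""
    segments: list[tuple[float, float]] = []
    for i in np.flatnonzero(voiced):
        s, e = starts[i], starts[i] + frame_len_s
        if segments and s - segments[-1][1] < bridge_s:
            segments[-1] = (segments[-1][0], e)
        else:
            segments.append((s, e))
    return segments


def rate_of_speech(clip: AudioClip, gate: VoicingGate = VoicingGate()) -> float:
    """Voiced segments per second (gaps under 100 ms bridged); 0 for silence."""
    voiced, _, starts = _voiced_mask(clip, gate)
    segments = _voiced_segments(voiced, starts, gate.frame_len_ms / 1000.0)
    return len(segments) / clip.duration


def sound_pressure_level(clip: AudioClip) -> float:
    """20*log10(rms) dB re digital full scale, clamped at the -120 dB floor."""
    rms = float(np.sqrt(np.mean(clip.samples**2)))
    if rms <= 0:
        return SPL_FLOOR_DB
    return max(20.0 * np.log10(rms), SPL_FLOOR_DB)


def average_power(clip: AudioClip) -> float:
    """Mean of squared samples (full-scale units squared)."""
    return float(np.mean(clip.samples**2))


def speech_duration(clip: AudioClip, gate: VoicingGate = VoicingGate()) -> float:
    """Span of the voiced part of the clip in seconds (0 if all silent).

    Measured between the centres of the first and last voiced frames: a
    frame that merely straddles a speech edge still passes the energy gate,
    so an endpoint at the frame boundary would inflate the span by almost a
    full frame on each side; the centre is within half a frame of the true
    edge.
    """
    voiced, _, starts = _voiced_mask(clip, gate)
    if not voiced.any():
        return 0.0
    idx = np.flatnonzero(voiced)
    return float(starts[idx[-1]] - starts[idx[0]])


def vocal_features(
    clip: AudioClip, gate: VoicingGate = VoicingGate()
) -> VocalFeatureVector:
    """All five vocal features from one clip (single framing pass)."""
    voiced, f0s, starts = _voiced_mask(clip, gate)
    frame_len_s = gate.frame_len_ms / 1000.0
    if voiced.any():
        ffp = float(np.median(f0s[voiced]))
        idx = np.flatnonzero(voiced)
        spd = float(starts[idx[-1]] - starts[idx[0]])
    else:
        ffp, spd = None, 0.0
    segments = _voiced_segments(voiced, starts, frame_len_s)
    return VocalFeatureVector(
        FFP=ffp,
        RSH=len(segments) / clip.duration,
        SPL=sound_pressure_level(clip),
        PSD=average_power(clip),
        SPD=spd,
    )
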