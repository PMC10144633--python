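"""Synthetic four-modality fixtures with known ground truth.

The original study's recordings (webcam frames, thermal images, keystroke
logs, voice clips from sleep-deprived and rested subjects) are private, so
every generator here emulates one modality with controllable alert-versus-
fatigued effect sizes and exact ground truth:

* :func:`render_eye_frames` — parametric face templates (two bright sclera
  ellipses with dark pupils plus a vertical nose ridge when open; nose ridge
  only when closed). The eye-state classifier operates on binary run
  structure along a profile line, which these templates reproduce exactly;
  photo-realism is deliberately out of scope.
* :func:`render_thermal_image` — a smooth radiometric gradient plus an
  oriented sinusoidal texture, intensity-shifted so a stated fraction of
  pixels exceeds the fixed binarization threshold.
* :func:`simulate_typing` — a press/release event stream for a prompted
  sentence with truncated-normal inter-key gaps (floor 10 ms) and sampled
  substitution/transposition errors.
* :func:`synth_speech` — a harmonic signal (fundamental plus three decaying
  harmonics) with silent gaps and a low noise floor.
* :func:`generate_cohort` — balanced labelled cohorts in which fatigue
  shifts *generator parameters* (longer eye closures, warmer periorbital
  fraction, slower and sloppier typing, lower pitch, longer speech), not
  features directly, so every pipeline stage stays in the loop.

All generators are bit-deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import InvalidParameterError
from .fusion import ALERT, FATIGUED, SubjectRecord
from .keystroke import KeystrokeEvent, KeystrokeLog, keystroke_features
from .thermal import ThermalImage, map_rois, thermal_features
from .visual import CLOSED, OPEN, EyePairROI, FrameSequence, extract_visual_features
from .vocal import AudioClip, vocal_features

__all__ = [
    "CohortSpec",
    "GroundTruth",
    "DEFAULT_TARGET_SENTENCE",
    "render_eye_frames",
    "render_thermal_image",
    "simulate_typing",
    "synth_speech",
    "generate_cohort",
    "generate_subject",
]

#: Prompt sentence used by default for typing and speech fixtures
#: (52 characters including spaces, inside the study's 48-54 band).
DEFAULT_TARGET_SENTENCE = "With the new day comes new strength and new thoughts"


@dataclass(frozen=True)
class GroundTruth:
    """Exact generating parameters stored alongside each artifact."""

    eye_states: tuple[str, ...] | None = None
    eye_roi: EyePairROI | None = None
    f0: float | None = None
    voiced_intervals: tuple[tuple[float, float], ...] | None = None
    typed_string: str | None = None
    intended_keys: tuple[str, ...] | None = None
    press_times_ms: tuple[float, ...] | None = None
    texture_orientation_deg: float | None = None
    hot_fraction: float | None = None


@dataclass(frozen=True)
class CohortSpec:
    """Conditions under which a synthetic cohort is generated.

    ``effect_sizes`` are standardized mean shifts applied to the fatigued
    class's generator parameters, one per domain. ``noise_scale`` multiplies
    every generator's noise amplitude. The remaining fields set the per-
    subject recording sizes (frames per clip, audio duration, image sizes).
    """

    n_subjects: int = 40
    effect_sizes: dict = field(
        default_factory=lambda: {d: 1.0 for d in ("visual", "thermal", "keystroke", "vocal")}
    )
    noise_scale: float = 1.0
    seed: int = 0
    n_frames: int = 90
    fps: float = 30.0
    frame_size: tuple[int, int] = (96, 128)  # (h, w)
    thermal_size: tuple[int, int] = (320, 240)  # (w, h)
    audio_sr: int = 8000
    audio_duration: float = 6.0
    target_sentence: str = DEFAULT_TARGET_SENTENCE

    def __post_init__(self):
        if self.n_subjects < 2 or self.n_subjects % 2:
            raise InvalidParameterError("n_subjects must be even and >= 2")
        for d in ("visual", "thermal", "keystroke", "vocal"):
            e = self.effect_sizes.get(d, 0.0)
            if not np.isfinite(e) or e < 0:
                raise InvalidParameterError(f"effect size for {d} must be finite, >= 0")
        if self.noise_scale <= 0:
            raise InvalidParameterError("noise_scale must be positive")


# ---------------------------------------------------------------------------
# visual


def _face_template(
    size: tuple[int, int], state: str
) -> tuple[np.ndarray, EyePairROI]:
    """Grayscale face template (float) plus the ground-truth eye-pair box."""
    h, w = size
    img = np.full((h, w), 30.0)
    cx, cy = w // 2, int(h * 0.5)
    # vertical nose ridge, present in both states
    nose_half = max(w // 50, 2)
    img[cy - h // 12 : cy + h // 3, cx - nose_half : cx + nose_half + 1] = 200.0
    eye_dx, rx, ry = w // 4 + 2, w // 10, h // 16
    ex_l, ex_r = cx - eye_dx, cx + eye_dx
    if state == OPEN:
        yy, xx = np.mgrid[0:h, 0:w]
        for ex in (ex_l, ex_r):
            sclera = ((xx - ex) / rx) ** 2 + ((yy - cy) / ry) ** 2 <= 1.0
            img[sclera] = 220.0
            pupil = (xx - ex) ** 2 + (yy - cy) ** 2 <= (ry // 2 + 1) ** 2
            img[pupil] = 30.0
    margin = 3
    x0 = max(ex_l - rx - margin, 0)
    x1 = min(ex_r + rx + margin, w)
    y0 = max(cy - ry - margin, 0)
    y1 = min(cy + ry + margin, h)
    roi = EyePairROI(x=x0, y=y0, width=x1 - x0, height=y1 - y0)
    return img, roi


def render_eye_frames(
    n_frames: int,
    fps: float,
    state_sequence: Sequence[str],
    seed: int,
    size: tuple[int, int] = (96, 128),
    noise_scale: float = 8.0,
) -> tuple[FrameSequence, GroundTruth]:
    """Render a grayscale frame sequence with known per-frame eye states.

    Open-state frames carry two bright sclera ellipses with dark pupil dots
    plus the central vertical nose ridge; closed-state frames carry the nose
    ridge only. Additive Gaussian noise at ``noise_scale`` (8-bit units).
    """
    if n_frames < 1:
        raise InvalidParameterError("n_frames must be >= 1")
    if fps <= 0:
        raise InvalidParameterError("fps must be positive")
    if size[0] < 16 or size[1] < 24:
        raise InvalidParameterError("frame size too small for the face template")
    if len(state_sequence) != n_frames:
        raise InvalidParameterError("state_sequence length must equal n_frames")
    states = tuple(state_sequence)
    if any(s not in (OPEN, CLOSED) for s in states):
        raise InvalidParameterError("states must be 'open' or 'closed'")
    rng = np.random.default_rng(seed)
    open_tmpl, roi = _face_template(size, OPEN)
    closed_tmpl, _ = _face_template(size, CLOSED)
    frames = np.empty((n_frames, *size), dtype=np.uint8)
    for i, s in enumerate(states):
        base = open_tmpl if s == OPEN else closed_tmpl
        noisy = base + rng.normal(0.0, noise_scale, size)
        frames[i] = np.clip(noisy, 0, 255).astype(np.uint8)
    seq = FrameSequence(
        frames=frames, timestamps=np.arange(n_frames) / fps, fps=fps
    )
    return seq, GroundTruth(eye_states=states, eye_roi=roi)


# ---------------------------------------------------------------------------
# thermal


def render_thermal_image(
    size: tuple[int, int] = (320, 240),
    orientation: float = 90.0,
    spatial_frequency: float = 16.0,
    hot_fraction: float = 0.25,
    seed: int = 0,
    texture_amplitude: float = 0.5,
    noise_scale: float = 0.05,
) -> tuple[ThermalImage, GroundTruth]:
    """Render a radiometric-gradient + oriented-texture thermal image.

    The image is a smooth centred warm blob plus a sinusoid at the stated
    orientation (degrees) and spatial frequency (cycles per image) plus
    Gaussian noise, affinely shifted so the fraction of pixels strictly
    above the fixed binarization threshold (128) equals ``hot_fraction``
    within +-2%.
    """
    w, h = size
    if w <= 0 or h <= 0:
        raise InvalidParameterError("size must be positive")
    if not 0.0 <= hot_fraction <= 1.0:
        raise InvalidParameterError("hot_fraction must lie in [0, 1]")
    if spatial_frequency < 0 or spatial_frequency >= min(w, h) / 2:
        raise InvalidParameterError(
            f"spatial_frequency must lie in [0, {min(w, h) / 2}) cycles/image"
        )
    rng = np.random.default_rng(seed)
    yy, xx = np.mgrid[0:h, 0:w]
    x, y = xx / w, yy / h
    gradient = np.exp(-(((x - 0.5) ** 2 + (y - 0.5) ** 2) / 0.18))
    theta = np.deg2rad(orientation)
    texture = texture_amplitude * np.cos(
        2.0 * np.pi * spatial_frequency * (x * np.cos(theta) + y * np.sin(theta))
    )
    raw = gradient + texture + rng.normal(0.0, noise_scale, (h, w))
    span = raw.max() - raw.min()
    scaled = (raw - raw.min()) / span * 255.0 if span > 0 else np.zeros_like(raw)
    if hot_fraction <= 0:
        shifted = scaled / 255.0 * 120.0  # everything below threshold
    elif hot_fraction >= 1:
        shifted = scaled / 255.0 * 100.0 + 129.0  # everything above
    else:
        q = np.quantile(scaled, 1.0 - hot_fraction)
        shifted = scaled - q + 128.0
    pixels = np.clip(np.round(shifted), 0, 255).astype(np.uint8)
    return (
        ThermalImage(pixels=pixels),
        GroundTruth(texture_orientation_deg=orientation, hot_fraction=hot_fraction),
    )


# ---------------------------------------------------------------------------
# keystroke


def _truncated_normal(
    rng: np.random.Generator, mean: float, sd: float, floor: float, n: int
) -> np.ndarray:
    return np.maximum(rng.normal(mean, sd, n), floor)


def simulate_typing(
    target: str,
    mean_interkey: float = 180.0,
    interkey_sd: float = 30.0,
    substitution_rate: float = 0.0,
    transposition_rate: float = 0.0,
    seed: int = 0,
    correction_rate: float = 0.0,
    hold_ms: float = 60.0,
) -> tuple[KeystrokeLog, GroundTruth]:
    """Simulate typing a prompted sentence as a press/release event stream.

    Adjacent transpositions and character substitutions are sampled at the
    stated rates and survive in the final string; ``correction_rate``
    samples slips the typist notices and fixes (wrong key, backspace, then
    the intended key — two extra presses that leave the string intact but
    raise the keystroke count and total time). Inter-key gaps come from a truncated
    normal with a 10 ms floor; each release precedes the next press so the
    log validates.
    """
    if not target:
        raise InvalidParameterError("target must be non-empty")
    for name, rate in (
        ("substitution", substitution_rate),
        ("transposition", transposition_rate),
        ("correction", correction_rate),
    ):
        if not 0.0 <= rate <= 1.0:
            raise InvalidParameterError(f"{name}_rate must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    chars = list(target)
    i = 0
    while i < len(chars) - 1:  # non-overlapping adjacent swaps
        if rng.random() < transposition_rate and chars[i] != chars[i + 1]:
            chars[i], chars[i + 1] = chars[i + 1], chars[i]
            i += 2
        else:
            i += 1
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    for i, c in enumerate(chars):
        if c != " " and rng.random() < substitution_rate:
            repl = c
            while repl == c:
                repl = alphabet[rng.integers(len(alphabet))]
            chars[i] = repl
    # expand into the actual key sequence, inserting corrected slips
    keys: list[str] = []
    for c in chars:
        if rng.random() < correction_rate:
            keys.append(alphabet[rng.integers(len(alphabet))])
            keys.append("\b")
        keys.append(c)
    gaps = _truncated_normal(rng, mean_interkey, interkey_sd, 10.0, max(len(keys) - 1, 0))
    press_times = np.concatenate([[0.0], np.cumsum(gaps)])
    events: list[KeystrokeEvent] = []
    for i, c in enumerate(keys):
        key = "space" if c == " " else ("backspace" if c == "\b" else c)
        gap_after = gaps[i] if i < len(gaps) else hold_ms / 0.8
        hold = min(max(rng.normal(hold_ms, 10.0), 10.0), 0.8 * gap_after)
        events.append(KeystrokeEvent(press_times[i], "press", key))
        events.append(KeystrokeEvent(press_times[i] + hold, "release", key))
    log = KeystrokeLog(events=tuple(events), target=target)
    truth = GroundTruth(
        typed_string="".join(chars),
        intended_keys=tuple(target),
        press_times_ms=tuple(press_times),
    )
    return log, truth


# ---------------------------------------------------------------------------
# vocal


def synth_speech(
    f0: float,
    duration: float,
    sample_rate: int = 16000,
    pause_spec: Sequence[tuple[float, float]] = (),
    amplitude: float = 0.5,
    seed: int = 0,
    noise_floor: float = 1e-3,
    n_harmonics: int = 4,
) -> tuple[AudioClip, GroundTruth]:
    """Synthesize a voiced harmonic clip with silent gaps at ``pause_spec``.

    The signal is a fundamental plus ``n_harmonics - 1`` decaying harmonics
    (amplitude ratio 0.6 per octave step), peak-normalized to ``amplitude``,
    silenced over each (start, length) pause, with a Gaussian noise floor.
    """
    if not 50.0 <= f0 <= 400.0:
        raise InvalidParameterError("f0 must lie in [50, 400] Hz")
    if duration <= 0:
        raise InvalidParameterError("duration must be positive")
    if sample_rate < 8000:
        raise InvalidParameterError("sample_rate must be >= 8000 Hz")
    if not 0.0 <= amplitude <= 1.0:
        raise InvalidParameterError("amplitude must lie in [0, 1]")
    for start, length in pause_spec:
        if start < 0 or length < 0 or start + length > duration + 1e-9:
            raise InvalidParameterError(f"pause ({start}, {length}) outside clip")
    rng = np.random.default_rng(seed)
    n = int(round(duration * sample_rate))
    t = np.arange(n) / sample_rate
    signal = np.zeros(n)
    for k in range(1, n_harmonics + 1):
        signal += (0.6 ** (k - 1)) * np.sin(2.0 * np.pi * k * f0 * t)
    peak = np.abs(signal).max()
    if peak > 0:
        signal = signal / peak * amplitude
    mask = np.ones(n, dtype=bool)
    for start, length in pause_spec:
        mask[int(start * sample_rate) : int((start + length) * sample_rate)] = False
    signal = np.where(mask, signal, 0.0)
    signal = signal + rng.normal(0.0, noise_floor, n)
    clip = AudioClip(samples=np.clip(signal, -1.0, 1.0), sample_rate=sample_rate)

    voiced: list[tuple[float, float]] = []
    edges = np.flatnonzero(np.diff(mask.astype(int)))
    bounds = np.concatenate([[0], edges + 1, [n]])
    for a, b in zip(bounds, bounds[1:]):
        if mask[a] and amplitude > 0:
            voiced.append((a / sample_rate, b / sample_rate))
    return clip, GroundTruth(f0=f0, voiced_intervals=tuple(voiced))


# ---------------------------------------------------------------------------
# cohort


@dataclass(frozen=True)
class SubjectParams:
    """Per-subject generator parameters sampled from class-conditional laws."""

    subject_id: str
    label: int
    blink_count: int
    closure_frames: float
    hot_fraction: float
    texture_orientation: float
    texture_frequency: float
    texture_amplitude: float
    mean_interkey: float
    interkey_sd: float
    substitution_rate: float
    transposition_rate: float
    correction_rate: float
    f0: float
    speech_len: float
    mid_pause: float
    amplitude: float


def _sample_subject_params(
    rng: np.random.Generator, subject_id: str, label: int, spec: CohortSpec
) -> SubjectParams:
    """Class-conditional generator parameters.

    Fatigue shifts each domain's parameter means by effect * sd in the
    physiologically expected direction: longer and more frequent eye
    closures, a larger hot (warm-pixel) fraction, slower and noisier typing
    with more errors, lower pitch, longer speech with longer pauses and a
    softer voice.
    """
    e = {d: spec.effect_sizes.get(d, 0.0) for d in ("visual", "thermal", "keystroke", "vocal")}
    f = 1.0 if label == FATIGUED else 0.0
    clip_s = spec.n_frames / spec.fps
    # parameter shifts are calibrated so a nominal per-domain effect of 1
    # realizes about one pooled-sd shift on that domain's leading features
    # (rendering, quantile remapping and discretisation attenuate the raw
    # parameter shift on the way to the extracted features)
    blink_lam = (1.0 + 0.5 * clip_s / 3.0) + f * e["visual"] * 1.2
    blink_count = 1 + int(rng.poisson(blink_lam))
    closure = max(1.0, rng.normal(2.0 + f * e["visual"] * 2.0, 1.0))
    hot = float(np.clip(rng.normal(0.20 + f * e["thermal"] * 0.07, 0.03), 0.02, 0.90))
    freq = float(np.clip(rng.normal(12.0 + f * e["thermal"] * 1.0, 1.0), 4.0, 40.0))
    # a warmer periorbital/forehead region also shows stronger thermal texture
    amp = float(np.clip(rng.normal(0.5 + f * e["thermal"] * 0.18, 0.08), 0.05, 1.8))
    return SubjectParams(
        subject_id=subject_id,
        label=label,
        blink_count=blink_count,
        closure_frames=closure,
        hot_fraction=hot,
        texture_orientation=float(rng.uniform(0.0, 180.0)),
        texture_frequency=freq,
        texture_amplitude=amp,
        mean_interkey=max(60.0, rng.normal(180.0 + f * e["keystroke"] * 24.0, 12.0)),
        interkey_sd=max(5.0, rng.normal(30.0 + f * e["keystroke"] * 5.0, 5.0)),
        substitution_rate=float(
            np.clip(rng.normal(0.005 + f * e["keystroke"] * 0.022, 0.004), 0.0, 0.3)
        ),
        transposition_rate=float(
            np.clip(rng.normal(0.005 + f * e["keystroke"] * 0.006, 0.003), 0.0, 0.3)
        ),
        correction_rate=float(
            np.clip(rng.normal(0.01 + f * e["keystroke"] * 0.03, 0.006), 0.0, 0.4)
        ),
        f0=float(np.clip(rng.normal(185.0 - f * e["vocal"] * 13.0, 9.0), 80.0, 350.0)),
        speech_len=float(
            np.clip(
                rng.normal(3.0 + f * e["vocal"] * 0.4, 0.25),
                0.8,
                spec.audio_duration - 0.6,
            )
        ),
        mid_pause=float(np.clip(rng.normal(0.20 + f * e["vocal"] * 0.12, 0.08), 0.0, 1.2)),
        amplitude=float(np.clip(rng.normal(0.5 - f * e["vocal"] * 0.06, 0.04), 0.05, 1.0)),
    )


def _blink_state_sequence(
    rng: np.random.Generator, n_frames: int, params: SubjectParams
) -> tuple[str, ...]:
    states = np.array([OPEN] * n_frames, dtype=object)
    for _ in range(params.blink_count):
        dur = max(1, int(round(rng.normal(params.closure_frames, 0.8))))
        if dur >= n_frames - 2:
            dur = max(1, n_frames - 3)
        start = int(rng.integers(1, max(n_frames - dur - 1, 2)))
        states[start : start + dur] = CLOSED
    return tuple(states)


def _subject_artifacts(params: SubjectParams, spec: CohortSpec, seed: int):
    """Render all four artifacts for one subject."""
    rng = np.random.default_rng(seed)
    child = lambda: int(rng.integers(0, 2**31 - 1))  # noqa: E731

    states = _blink_state_sequence(rng, spec.n_frames, params)
    frames, visual_truth = render_eye_frames(
        spec.n_frames,
        spec.fps,
        states,
        seed=child(),
        size=spec.frame_size,
        noise_scale=8.0 * spec.noise_scale,
    )
    thermal_img, thermal_truth = render_thermal_image(
        size=spec.thermal_size,
        orientation=params.texture_orientation,
        spatial_frequency=params.texture_frequency,
        hot_fraction=params.hot_fraction,
        seed=child(),
        texture_amplitude=params.texture_amplitude,
        noise_scale=0.05 * spec.noise_scale,
    )
    log, typing_truth = simulate_typing(
        spec.target_sentence,
        mean_interkey=params.mean_interkey,
        interkey_sd=params.interkey_sd,
        substitution_rate=params.substitution_rate,
        transposition_rate=params.transposition_rate,
        correction_rate=params.correction_rate,
        seed=child(),
    )
    t0 = 0.3
    pauses = [(0.0, t0)]
    mid = t0 + params.speech_len / 2.0
    if params.mid_pause > 0:
        pauses.append((mid, params.mid_pause))
    end = t0 + params.speech_len + params.mid_pause
    if end < spec.audio_duration:
        pauses.append((end, spec.audio_duration - end))
    clip, speech_truth = synth_speech(
        params.f0,
        spec.audio_duration,
        sample_rate=spec.audio_sr,
        pause_spec=pauses,
        amplitude=params.amplitude,
        seed=child(),
        noise_floor=1e-3 * spec.noise_scale,
    )
    truths = {
        "visual": visual_truth,
        "thermal": thermal_truth,
        "keystroke": typing_truth,
        "vocal": speech_truth,
    }
    return frames, thermal_img, log, clip, truths


def generate_subject(
    params: SubjectParams, spec: CohortSpec, seed: int
) -> SubjectRecord:
    """Render one subject's artifacts and run the full feature extraction."""
    frames, thermal_img, log, clip, truths = _subject_artifacts(params, spec, seed)
    roi = truths["visual"].eye_roi
    visual_vec = extract_visual_features(frames, roi=roi)
    th, tw_ = thermal_img.pixels.shape
    fh, fw = spec.frame_size
    rois = map_rois(roi.as_tuple(), visible_size=(fw, fh), thermal_size=(tw_, th))
    thermal_vec = thermal_features(thermal_img, rois)
    keystroke_vec = keystroke_features(log)
    vocal_vec = vocal_features(clip)
    return SubjectRecord(
        subject_id=params.subject_id,
        visual=visual_vec,
        thermal=thermal_vec,
        keystroke=keystroke_vec,
        vocal=vocal_vec,
        label=params.label,
    )


def sample_cohort_params(spec: CohortSpec) -> list[SubjectParams]:
    """Per-subject class-conditional parameters for a balanced cohort."""
    rng = np.random.default_rng(spec.seed)
    half = spec.n_subjects // 2
    out = []
    for i in range(spec.n_subjects):
        label = ALERT if i < half else FATIGUED
        out.append(_sample_subject_params(rng, f"S{i + 1:03d}", label, spec))
    return out


def generate_cohort(spec: CohortSpec) -> list[SubjectRecord]:
    """Generate a balanced labelled cohort and extract all features.

    The first half of the subjects is alert, the second half fatigued;
    fatigued subjects' generator parameters are shifted by the per-domain
    effect sizes. Identical spec (including seed) reproduces the cohort
    bit-for-bit.
    """
    params = sample_cohort_params(spec)
    seed_rng = np.random.default_rng(spec.seed + 1)
    seeds = seed_rng.integers(0, 2**31 - 1, size=spec.n_subjects)
    return [
        generate_subject(p, spec, int(s)) for p, s in zip(params, seeds)
    ]
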