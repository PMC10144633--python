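"""Vocal domain: pitch, speech rhythm, level, power and duration.

Synthesizes a 6-second utterance at 170 Hz with a mid-sentence pause and
prints the five vocal features next to the generating ground truth.
"""

from fatiguefusion import vocal_features
from fatiguefusion.fixtures import synth_speech

clip, truth = synth_speech(
    f0=170.0,
    duration=6.0,
    sample_rate=16000,
    pause_spec=[(0.0, 0.4), (2.8, 0.5), (5.4, 0.6)],  # lead-in, mid pause, tail
    amplitude=0.5,
    seed=9,
)

vec = vocal_features(clip)
print(f"FFP = {vec.FFP:.1f} Hz   pitch (ground truth {truth.f0} Hz)")
print(f"RSH = {vec.RSH:.2f} /s   voiced segments per second (2 bursts / 6 s)")
print(f"SPL = {vec.SPL:.1f} dBFS  overall level")
print(f"PSD = {vec.PSD:.4f}      average power (mean squared sample)")
print(f"SPD = {vec.SPD:.2f} s    voiced span, lead-in and tail excluded")
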