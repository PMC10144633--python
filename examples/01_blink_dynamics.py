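"""Visual domain: render an eye-blink clip and extract blink dynamics.

Renders 3 seconds of synthetic face frames containing two blinks, runs the
frame classifier (equalize -> morphology -> profile-line transitions) and
prints the six blink features.
"""

import numpy as np

from fatiguefusion import blink_dynamics
from fatiguefusion.fixtures import render_eye_frames
from fatiguefusion.visual import CLOSED, OPEN, classify_sequence

# 90 frames at 30 fps with two blinks: frames 20-24 and 60-67 closed
states = [OPEN] * 90
for i in list(range(20, 25)) + list(range(60, 68)):
    states[i] = CLOSED

frames, truth = render_eye_frames(90, fps=30, state_sequence=states, seed=1)
series = classify_sequence(frames, roi=truth.eye_roi)

agreement = np.mean([p == s for p, s in zip(series.states, states)])
print(f"frame classification agreement vs ground truth: {agreement:.1%}")

vec = blink_dynamics(series)
print(f"ECP  = {vec.ECP:.3f} s   total eyes-closed time (13 closed frames / 30 fps)")
print(f"BKC  = {vec.BKC:.0f}       complete blinks in the clip")
print(f"ICFC = {vec.ICFC:.0f}       state-changeover boundaries (2 per blink)")
print(f"TCT  = {vec.TCT:.3f} s   changeover time, OCOP + COCP")
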