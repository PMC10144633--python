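# Methods

`fatiguefusion` detects sleep-deprivation fatigue nonintrusively by fusing
scalar scores from four behavioural/physiological domains. This note
documents the model, the tunable parameters, the synthetic-data generator
that stands in for (unavailable) human recordings, and the numerical and
design choices that were genuinely open.

## The classification model

Each subject contributes one recording per domain. Domain-specific feature
extraction yields four fixed-length vectors (6 visual + 5 thermal + 4
keystroke + 5 vocal = 20 features). Classification is *late fusion*:

1. **Per-domain score.** For each domain a `DomainScorer` is fitted on
   labelled training subjects: features are ranked by Fisher's
   discrimination ratio, FDR = (μ_a − μ_b)² / (σ_a² + σ_b²), and greedily
   admitted (up to `k`, default 6) while their absolute Pearson correlation
   with every already-admitted feature stays below `corr_cap` (default
   0.9). Each selected feature votes 1 iff the subject's value lies on the
   fatigued side of the midpoint between the class-conditional training
   means; the domain score is the mean vote, a number in [0, 1]. The vote
   scorer is deliberately simple — it is compatible with the fixed 0.5
   decision threshold without calibration — and is exposed behind a
   strategy interface so a probabilistic scorer can replace it.
2. **Weighted fusion.** The fused score is
   `α·visual + β·thermal + γ·keystroke + δ·vocal` with non-negative weights
   summing to one. A subject is classified **fatigued iff fused ≥ 0.5**
   (the boundary value goes to the fatigued side).
3. **Weight optimization.** Weights are found by exhaustive search over the
   3-simplex grid at `weight_resolution` (default 0.01, ≈177k grid points,
   evaluated as one matrix product), maximizing training accuracy at the
   0.5 threshold. Ties are broken deterministically: (a) largest mean
   signed margin `mean_i s_i(fused_i − ½)` (s_i = +1 fatigued, −1 alert) —
   the mean margin is linear in the weights, so among equally accurate
   candidates it concentrates weight on the domain whose scores separate
   the classes most strongly, which is what makes the weights
   interpretable as domain informativeness; (b) smallest distance to the
   uniform weights (¼,¼,¼,¼), which decides degenerate cases where margins
   are weight-invariant; (c) lexicographic order. A min-margin tie-break
   was considered and rejected: it is dominated by single worst-case
   subjects and fails to recover the informative domain's weight when the
   uninformative domains are noisy.
   The package also ships the `empirical-2023` preset
   (0.29, 0.37, 0.16, 0.18), the weight set reported for the original
   120-sample human cohort; it is a preset, not something this package can
   re-derive, because that cohort is private.

## Per-domain features

### Visual (blink dynamics)

Frames pass through eye-pair localisation (explicit ROI in fixture mode,
or a pluggable detector — the default brightness/shape blob detector finds
the two widest bright horizontal blobs), histogram equalization
(`S = T(r) = Σ_{j≤r} n_j/n`, rescaled to 0–255), and a four-step
morphological filter with a disk structuring element (radius
`selem_radius`, default 3): grayscale opening, closing, dilation, then
edge extraction as (dilated − filtered). The edge map is binarized at
`edge_fraction` (default 0.5) of its maximum response — a histogram-based
cut (Otsu) was tried first and discarded because the edge map of a
closed-eye ROI is mostly noise, which Otsu happily splits into fake
"edges" (~8–11% frame misclassification vs 0.2% with the fixed-fraction
cut). The mid-row profile of the binary edge map is scanned for white
runs; runs narrower than `min_run` (default 2 px — genuine edge lines are
as wide as the dilation element) are ignored, each run counts as two
intensity transitions, and the frame is **open** iff the transition count
reaches `open_threshold` (default 6: an open eye pair crosses the line
with ≈8+ edges from sclera, pupils and nose, closed eyes with ≈2 from the
nose alone).

Run-length statistics of the open/closed series give ECP (total closed
time, s), BKC (complete open→closed→open blinks), ICFC (state-change
boundaries), OCOP/COCP (mean changeover durations) and TCT = OCOP + COCP.
With a binary state sequence a changeover has no intrinsic duration; each
boundary is assigned one inter-frame interval (1/fps). Consequently OCOP
and COCP are 1/fps whenever the corresponding changeover occurs at all —
they are retained for format compatibility but carry no information on
binary series, and the scorer's zero-variance filter drops them
automatically.

### Thermal

`pixel_count` is the number of pixels strictly above the binarization
threshold (fixed 128 by default; `"otsu"` selectable) over the whole
facial image. The periorbital ROI is the eye-pair box mapped from the
visible image by axis scaling; the forehead ROI is the same-size box
directly above (clamped at the top edge). For each ROI the centred power
spectrum |F(u,v)|² is partitioned — off-DC bins within radius R₀ (default
half the smaller ROI dimension) — into `n_rings` equal-width concentric
rings and `n_wedges` equal angular wedges over [0, π) (16 each by
default; each bin assigned wholly by its centre, no interpolation, which
keeps the partition exact). The scalar features are the ring-partition
and wedge-partition totals; both equal the total off-DC power within R₀,
and the DC bin is excluded so brightness cannot masquerade as texture.

### Keystroke

From a press/release log of a prompted sentence (48–54 characters):
KSR = number of press events including backspaces (extra presses are the
fatigue signal); CRE = positionwise mismatches between the final typed
string (after backspace resolution) and the target, shorter string padded;
AVD = |Σ ASCII(typed) − Σ ASCII(target)| — zero under any character
permutation, so a transposed-but-complete sentence is distinguished from
one with wrong characters; TST = last release − first press, seconds.

### Vocal

Frames of 40 ms at a 10 ms hop. The voicing gate requires frame RMS above
a fixed energy threshold (−45 dBFS default) **and** a normalized
autocorrelation peak above 0.3 in the 50–400 Hz lag band. (A noise-floor-
relative energy gate was rejected: for a fully voiced clip every frame has
the same energy, so any per-clip adaptive floor silences it.) FFP is the
median over voiced frames of the autocorrelation peak frequency with
parabolic lag interpolation (without it, 16 kHz audio quantises 200 Hz to
±2.5 Hz steps); picking the global peak in the full lag band avoids octave
errors for signals with strong second harmonics. RSH is voiced segments
per second after bridging gaps under 100 ms. SPL is 20·log₁₀(rms) dB re
digital full scale, clamped at −120 dB (file audio has no pressure
calibration, so full scale is the only meaningful reference). PSD is the
finite-sample mean square — the discrete realisation of the limiting
time-average power of s(t) — kept scalar because it feeds a fixed-length
feature vector. SPD is the span between the centres of the first and last
voiced frames (frame centres, because a frame merely straddling a speech
edge passes the gate and a boundary-based endpoint would inflate the span
by nearly a full frame per side).

## Synthetic cohorts

The original recordings are private, so the `fixtures` module generates
all four modalities with exact ground truth:

* **Eye frames** are parametric templates, not photographs: two bright
  sclera ellipses with dark pupils plus a vertical nose ridge when open,
  nose ridge alone when closed, plus Gaussian noise (σ = 8 grey levels by
  default). The classifier operates on binary run structure along a
  profile line, which templates reproduce exactly; photo-realism would add
  nothing the pipeline reads.
* **Thermal images** are a smooth warm-blob gradient plus an oriented
  sinusoid plus noise, affinely shifted so the fraction of pixels above
  the fixed threshold equals the requested `hot_fraction` (±2%).
* **Typing logs** draw inter-key gaps from a truncated normal (floor
  10 ms); substitutions and adjacent transpositions survive into the final
  string, while *corrected slips* (wrong key, backspace, intended key) add
  presses and time without changing the string.
* **Speech** is a fundamental plus three decaying harmonics (ratio 0.6),
  peak-normalized, silenced over the requested pauses, over a −60 dB
  noise floor.

`generate_cohort` builds a balanced labelled cohort in which fatigue
shifts *generator parameters* — longer and more frequent eye closures, a
larger hot fraction and stronger thermal texture, slower typing with more
errors and corrections, lower pitch, longer speech with longer pauses and
a softer voice — never features directly, so every extraction stage stays
in the loop. Per-unit parameter shifts are calibrated so that a nominal
per-domain effect of about 3 makes that domain's score essentially
separable at cohort sizes of ~40 (realized feature-level separations are
roughly 1.5–2 pooled sd per nominal unit on the leading features); a
nominal effect of 0 produces exchangeable classes. Cohort defaults are
desk-scale by design: 40 subjects, 3 s of video at 30 fps (96×128 frames),
one 320×240 thermal image, one 52-character sentence, 6 s of 8 kHz audio.
Everything is bit-reproducible under a fixed seed.

**What passing tests do and do not show.** The generators exercise every
code path with known answers — they validate the arithmetic and the
plumbing, and they show the pipeline recovers planted signal and refuses
to invent signal in null data. They do not emulate head pose, lighting,
detector failure modes, radiometric drift, linguistic variability, or the
correlation structure of real fatigue physiology; accuracy numbers on
synthetic cohorts therefore say nothing about accuracy on real subjects.

## Evaluation harness

`confusion_matrix`/`accuracy` use fatigued as the positive class and
report percent to two decimals. `kfold_cv` performs seeded stratified
k-fold CV (default k = 3), refitting scorers *and* weights on each
training split. `baseline_comparison` trains five reference classifiers
(kNN k=5, a random-split decision tree, a 100-tree random forest, an
RBF-kernel SVM, and a one-hidden-layer-of-16 perceptron, the latter three
behind a standardising scaler) on the flat 20-feature matrix under one
stratified split; hyperparameters are fixed and recorded in the report —
the baselines are a comparison harness, not the contribution.

## Known limitations

* OCOP/COCP/TCT are uninformative on binary eye-state series (see above).
* The two ring/wedge sums of one ROI are equal by construction (both are
  the off-DC power within R₀); they differ only once profiles rather than
  totals are consumed.
* The vote scorer discards within-feature margin information; swapping in
  a calibrated logistic scorer is the first thing to try on real data.
* Grid-search weight optimization maximizes *training* accuracy and will
  overfit small cohorts; the cross-validation harness is the honest
  estimate.
* An unvoiced clip has no pitch; FFP is stored as NaN and the scorer
  drops NaN features at fit time and NaN votes at score time.
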