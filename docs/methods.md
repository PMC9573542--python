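# Methods

## Signal model and preprocessing

A session is a frame-indexed record at 60 Hz: pupil diameter (mm), gaze
position (screen px) and a per-frame eye state in
`{fixation, saccade, blink, missing}`.  Blinks and tracking dropouts leave
gaps; gaps are filled by linear interpolation between the nearest valid
neighbours, and leading/trailing gaps are clamped to the nearest valid value
— extrapolating a physiological signal linearly past its support is unsafe,
so the toolkit deliberately does not.  Frames labelled `blink` are treated
as missing diameters even when the tracker reports a value; the state label
itself is kept for the eye-event features.

Resting pupil size differs between subjects, so a calm-state mean (from a
separate calm recording or a designated pre-stimulus interval) is subtracted
per subject before any feature extraction.  A pooled (cross-subject)
baseline is available as an option; the per-subject default avoids mixing
between-subject size differences into the elevation signal.  After
subtraction the trace is an elevation in mm that may be negative.

The elevation histogram per emotion label is reported over the bins
`(-inf, 0], (0, 0.5), [0.5, 1), [1, +inf)` (boundary 0.5 belongs to the
third bin).  On data with the assumed structure, nearly all annotated frames
are elevated above the calm baseline, and the "bored" label shows both the
shallowest elevations and the largest below-zero share — the observation
that motivates splitting at local *minima* (upper-convex cycles).

## Adaptive partition

The split-point search walks `i` from `n` and declares frame `i` a split
point when `Pd[i]` is strictly below all `n` frames before it and all `n`
frames after it, then jumps `i` ahead by `n` (the minimum admissible window
length).  Implementation decisions:

* **Slice bounds.** The neighbourhoods are the `n` frames strictly before
  and strictly after `i` (`[i-n, i-1]` and `[i+1, i+n]`).
* **Tail handling.** Near the sequence end the right neighbourhood is
  truncated to the available suffix; a frame with an empty right
  neighbourhood (the last frame) cannot split.  The final window always ends
  at the sequence end (`tail_policy="keep"`) or is dropped on request.
* **Ties.** Strict `<` throughout: equal-valued plateau minima never split.
* **First window.** It starts at frame 0 regardless of whether frame 0 is a
  minimum, so it may be shorter than `n`; downstream dataset assembly
  filters windows below a representation-specific minimum length.
* **Convexity.** Splitting at local minima is the default; a lower-convex
  variant (minima of the negated signal, i.e. local maxima) is available
  behind a flag for signals where arousal depresses the measured quantity.
* **Shift invariance.** Minima locations are unchanged by constant
  subtraction, so the partition may equivalently run on raw or
  baseline-subtracted diameters; the pipeline uses the prepared
  (baseline-subtracted) trace.

A deliberately literal pure-Python interpreter of the same search
(`naive_reference_partition`) is kept in the package; the test suite and the
acceptance script verify the production routine against it on large random
suites.  Window length is reported as `alen = n + Tn` with `Tn` recorded as
`alen - n`.  The empirical rule that larger `n` yields no more split points
holds on random suites but is not a theorem under the jump rule; the suite
logs violations instead of failing on them.

## Features

All statistics use population (1/N) normalisation — fixed, documented, and
deliberately not the sample (1/(N-1)) convention, so that values are
reproducible functions of the window content alone.  "Energy" is the sum of
squares (window-length dependent, flagged as such).  The waveform family
follows the standard vibration-analysis definitions: crest = peak/RMS,
waveform = RMS/mean|x|, impulse = peak/mean|x|, clearance =
peak/(mean sqrt|x|)^2, skewness and kurtosis factors are the standardised
third and fourth central moments.  Zero-dispersion inputs cannot support the
ratio/moment factors; such windows are flagged degenerate and the affected
values emitted as 0 with a warning rather than NaN, so batch assembly never
silently drops windows.

MFCCs use 13 coefficients, 25 ms frames, 10 ms hop, 26 HTK-style mel
filters, pre-emphasis 0.97 and an orthonormal DCT-II; all parameters are
overridable.  The audio feature row pools the seven statistics over the
whole coefficient matrix (and over its temporal first difference) to keep
one row per window; a per-coefficient mode exists for finer analyses.

The video pixel-change rate uses the *absolute* inter-frame difference.
The signed sum (available behind a flag) lets opposite-signed pixel changes
cancel, so genuine motion can register as zero; the absolute convention is
the default for that reason and is symmetric under frame-pair reversal and
invariant to joint brightness shifts.

The feature manifest (names and order per modality) is published by
`feature_manifest()` and is the package's own deterministic ordering; group
membership for grouped correlation reporting follows the same names.

## Fine-grained feature curves

Each window is split into 8 contiguous sub-windows whose lengths differ by
at most one frame (remainder front-loaded — deterministic).  Every scalar
feature is then an 8-point curve; curves stack into `[batch, n_features, 8]`
tensors.  Eye, audio and video pass through the same split: audio
sub-windows are the 8 equal time slices, video sub-windows the corresponding
frame slices.  Eye-event features are extracted inside sub-samples too.
Consistency properties (the mean of sub-sample means equals the window mean
for divisible lengths; the max over the max-curve equals the window max) are
enforced by tests.  Sub-sample counts other than 8 are exposed as a constant
for ablation.  Windows need at least 2 frames per sub-sample (16 total) for
the split, and in practice at least 48 frames when video curves are
requested so every sub-window spans >= 3 video frames.

## Synthetic session generator

The generator emulates the statistical structure the method assumes, not
the physiology: the elevation signal is a concatenation of warped
raised-cosine arches `peak * sin(pi * w(k/L))^2`, exactly zero at each cycle
start, one emotion per cycle, periods uniform on 45–75 frames (mean 60 =
2n for the default n = 30), additive Gaussian noise (sd 0.02 mm), missing
runs at 2% of frames in geometric runs, and a 3.5 mm calm baseline.

Per-emotion defaults: interest and confused share a tall arch (peak
1.6 ± 0.15 mm), happy is medium (0.85 ± 0.10 mm), bored shallow
(0.32 ± 0.05 mm).  This reproduces the qualitative elevation ordering (the
interest/confused mass at or above 0.5 mm, happy inside (0, 1), bored inside
(0, 0.5) with the largest below-zero share, arising from noise near the
zero floor).  Interest and confused differ only in *when* a short saccade
run (an attention shift) occurs inside the cycle — early (phase 0.05–0.35)
for interest, late (0.65–0.95) for confusion.  This cue was chosen because
it is provably invisible to window-aggregate statistics (dwell times, run
counts and value distributions are identical in expectation) while being
trivially visible to the fine-grained sub-sample curves: it realises, in a
controlled way, the claim that feature curves retain temporal information
that scalar features lose.  An earlier design used time-reversed asymmetric
arches for the pair, but time reversal flips the sign of first-difference
odd moments, so scalar statistics of the differenced signal leaked the
label; the attention-burst design replaced it.  Arch warping (`warp_gamma`)
remains available per recipe for ablations.

Audio is a per-emotion tone/noise mixture and video a moving-square scene
whose speed depends on the emotion (bored nearly static), so all three
modalities carry label signal.  Annotation intervals coincide with cycles by
default; a misaligned mode shifts them by half a cycle to stress-test
windowing.  Everything derives from one integer seed and is bit-reproducible.

What the generator does **not** emulate: luminance-driven pupil responses,
foreshortening artefacts, inter-subject variability beyond the seeded
randomness, annotation noise, or any acoustic/visual structure of real
lessons.  Passing tests therefore demonstrate the correctness and the
directional behaviour of the *pipeline* under the method's assumptions, not
performance on human recordings.

## Models and evaluation

Reduction is z-score normalisation plus PCA fitted on training subjects
only, retaining components whose explained-variance ratio strictly exceeds
1% (a rate equal to the threshold is not retained; at least one component
always is).  Constant features are dropped with a warning before scaling.
For curve tensors the projection is fitted on the pooled sub-sample columns
and applied column-wise, preserving the 8-step time axis.  A joint
(train+test) normalisation mode is intentionally absent from the default
path to avoid leakage; the no-leakage property is asserted by test.

KNN (k = 5) and random forest (200 trees, seeded) come from scikit-learn.
The sequence families are compact numpy reference architectures sized for
desk-scale data: `tcn` = three causal dilated residual blocks (dilations
1/2/4, width 32) + global average pooling; `lstm` = one LSTM (hidden 64)
read at the last step; `cnn1d` = a single conv + pooling head (this family
also accepts flat vectors, read as a one-channel sequence); `tcn_cnn` /
`lstm_cnn` append an extra conv head.  Training is Adam (lr 1e-2, batch 32)
for at most 50 epochs with early stopping (patience 10) on an internal 20%
validation split; inputs are channel-standardised with training statistics.
Backpropagation is verified against central finite differences at a generic
parameter point (zero-initialised biases otherwise put ReLU pre-activations
exactly at the kink, where one-sided numerical derivatives disagree with the
subgradient by construction).  These are internal reference models for
comparing representations, not claims about any particular published
architecture.

Correlation of a feature with the 4-class label is the maximum absolute
point-biserial correlation over the four one-vs-rest indicator encodings
(an integer-coded Pearson mode exists for sensitivity analysis); group and
overall averages are means of absolute values, since signed averages cancel.
Constant features get correlation 0 with a warning.  Classification metrics
come from the confusion matrix (fixed class order); macro-F1 counts an
absent class as 0 with a warning; AUC macro-averages one-vs-rest over the
classes present in the test set.  Train/test splits are always subject-wise.
Windows are labelled by majority overlap with the annotation intervals.

## Problem sizes

The test suite and the acceptance script run on generated cohorts of 4–6
subjects at 45–60 s per session (roughly 40–60 windows per session at
n = 30), 10 seeds for the partition properties and 5 seeds for the
directional comparisons — sizes chosen as sensible desk-scale defaults for
a synthetic study.  The oracle-equivalence check uses 1000 random sequences
of 100–2000 frames with n in {5, 15, 30}.

## Known limitations

* The adaptive partition assumes a gap-free input; imputation quality near
  cycle boundaries directly affects boundary placement.
* The first and last windows of a session are structurally atypical (no
  bounding minimum on one side) and are excluded from length statistics.
* Waveform factors are unstable on near-zero-dispersion windows; they are
  flagged rather than suppressed.
* The sequence models are small and CPU-bound by design; they are
  comparison instruments, not production classifiers.
* Absolute accuracies on the synthetic cohorts say nothing about accuracy
  on human data; only the directional comparisons (adaptive vs static,
  curves vs scalars) are meaningful summaries.
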