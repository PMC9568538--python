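# Methods

## Labeling model

Each video frame's pain level is the Prkachin–Solomon Pain Intensity
score, PSPI = AU4 + max(AU6, AU7) + max(AU9, AU10) + AU43, with the five
graded action units coded 0–5 and AU43 (eye closure) binary; the score
ranges over the integers 0–16. The "or" terms are read as maxima — the
standard Prkachin–Solomon definition and the only reading consistent with
the 0–16 range. Scores are grouped into four ordinal classes
(0, 1, {2, 3}, ≥4), which partition all attainable scores; grouping is
monotone in the score. Class balancing draws uniformly without
replacement within each over-represented class under an explicit seed.
Only the resulting per-class counts are contractual — which particular
frames survive depends on the seed. AU tables are CSV with columns
`id,au4,au6,au7,au9,au10,au43`; a missing AU column is an error, never
imputed, because a silently-zero AU would silently deflate PSPI.

## Shutter-blinds geometry

Faces are assumed pre-cropped (face detection is out of scope) and are
resized to 224×224 with bilinear interpolation — chosen for determinism
and ubiquity; the method is not sensitive to the interpolant choice at
this resolution. The decomposition yields 21 full-width horizontal strips:
two of height 112, four of 56, seven of 32, eight of 28. All four scales
divide 224 exactly, so each scale tiles the face with no gap or overlap
(asserted at import). Canonical order is coarse→fine scale, top→bottom
within a scale, with the whole face appended last in the feature
concatenation; the arithmetic 21×1000 + 1000 fixes the whole-face block's
existence but not its position, so last-position is a documented
convention of this implementation.

## Backbone contract

A backbone is any deterministic map from a square RGB image to a fixed-
length float vector; strips are bilinearly resized to the backbone's
native square input (aspect ratio not preserved — the strips are extreme
rectangles and any fixed-input CNN must distort them somehow). The
reference configuration is a frozen ImageNet-pretrained DarkNet19 at its
global-average-pool output, 1000 features, used without fine-tuning; it
is an optional adapter because the pretrained weights cannot ship here.
The library's default is the toy backbone: per-channel means and
variances pooled over an 8×8 grid (384 statistics at input side 64),
passed through a seeded random linear projection and tanh. It is a real,
if shallow, texture/intensity-layout extractor — sufficient for the
band-structured fixtures — and makes the whole pipeline exactly
reproducible offline. Feature matrices persist as CSV with 17-significant-
digit floats and round-trip float64 bit-exactly (reading uses pandas'
round-trip parser; the default fast parser can be one ulp off).

## Feature selection

Min–max normalization maps each feature column to [0, 1]; constant
columns map to 0. In the default ("faithful") mode the scaler and the
ranking are fitted once on the full matrix before cross-validation,
mirroring the pipeline order of the architecture this package implements:
normalize → rank → iterate. That lets test rows influence the scaler and
ranking, so a strict `no_leakage` mode is equally first-class: per fold,
the scaler and the NCA ranking are refitted on the training rows only and
the candidate-length loss curve is pooled from honest fold errors. The
two modes answer different questions (reproduction vs. generalization);
on the synthetic fixtures they agree closely because the class signal is
strong.

The ranker is feature-selection NCA: per-feature weights w_l, kernel
exp(−d_w/σ) over the weighted city-block distance
d_w(a,b) = Σ_l w_l²·|a_l − b_l| (city-block to match the downstream kNN
metric), objective = expected leave-one-out correct-classification
probability − λ·Σ w_l², maximised by full-batch gradient ascent from
w = 1. Defaults: σ = 1 (features are in [0,1] after normalization, so
unit kernel width keeps softmax responsibilities informative), λ = 1/N
(scales the penalty with the objective's O(N) magnitude), 100 iterations,
learning rate 0.1 halved whenever a proposed step would decrease the
objective (the step is rejected). All are exposed as parameters. Ranking
is w² descending, ties toward the lower feature index. The gradient is
computed exactly with the pair-coefficient matrix and feature-chunked
|x_il − x_jl| sums, bounding memory at N²×256 doubles per chunk.

The iterative stage evaluates every ranked-prefix length in [lo, hi]
(step 1 by default; at the full 22,000-feature scale the default range
100–1000 yields 901 candidates) with the misclassification rate of the
k=1 Manhattan kNN under one fixed fold partition — the same folds for
every length, so the loss curve is comparable point to point — and keeps
the shortest best-loss prefix.

## Classification and metrics

Fine kNN: k = 1, Manhattan distance, distance ties broken by the lowest
training-row index (deterministic; relevant only on exactly-tied
distances). Cross-validation is stratified tenfold by default (the
conventional reading of "random tenfold" that keeps all classes in every
training split; plain shuffled folds are available), seeded, with every
sample tested exactly once and predictions pooled into a single K×K
confusion matrix. Per-fold accuracies are reported alongside.

All metrics derive from the pooled matrix: class-wise recall, precision
and F1; overall accuracy, UAR, UAP, macro-F1, Cohen's kappa, the
geometric mean of class recalls, and two Matthews-correlation
generalisations. The headline `mcc` is the unweighted mean of the four
one-vs-rest binary MCCs — independent recomputation from the published
confusion matrices of both archives shows this macro-averaged definition
(not Gorodkin's R_K) reproduces the published multiclass MCC values to
two decimals, so it is the definition the evaluation layer reports;
Gorodkin's R_K is computed as well and exposed as `mcc_rk`. Both reduce
to the classical binary MCC at K = 2. Internally everything is full
precision; percentages are rounded half-up to two decimals only at the
presentation layer.

## Synthetic fixtures

The generators replace the access-restricted archives. AU tables are
built per class by drawing a target score from the class's score set,
decomposing it uniformly over the (AU4, max67, max910, AU43) splits, and
expanding the max terms into concrete pairs — so the class counts are
exact by construction and every row re-scores into its class. Face
images are 448×448 grayscale-replicated arrays: a flat base intensity,
plus, for class c, a lift of band_contrast·255/2 and a zero-mean
sinusoidal grating in horizontal bands {c, c+4} of the eight positions
aligned with the finest (28-row) strip scale, plus i.i.d. Gaussian pixel
noise of sd noise_sd·255. Defaults: band_contrast 0.6, noise_sd 0.1 —
bands clearly above the noise floor but with per-pixel noise an order of
magnitude above the pooled-cell signal granularity, a regime a vision
practitioner would call an easy but non-degenerate texture problem.
Generation at 448 exercises the resize path.

What passing on fixtures shows: the geometry, extraction, selection,
classification and metric code compose correctly and recover spatially
localised class structure. What it does not show: performance on real
faces, where pain evidence is subtle, non-band-aligned, identity-
confounded and label-noisy — no claim about the archive-scale accuracies
follows from fixture results.

## Problem sizes

The fixture pipeline runs at 200 images (50 per class), toy backbone
feature_dim 25 (22×25 = 550 concatenated features) and selection range
[10, 60]; the 22,000-length constant is verified separately at
feature_dim 1000 on single faces. These sizes make the full suite and
the acceptance script complete in about a minute each while keeping every
stage's contract exercised at realistic shape ratios (N < D before
selection, N ≫ selected length after).

## Known limitations

- The real-backbone adapter (pretrained DarkNet19) is a contract, not a
  shipped component; archive-scale results require the archives and the
  weights.
- The faithful mode's normalization/ranking leakage is inherent to the
  reproduced pipeline order; use `no_leakage` for honest generalization
  estimates.
- Under-sampling is not stratified by subject (no subject metadata
  contract), so subject overlap across folds is possible with real video
  data.
- `nca_rank` is O(N²D) per iteration; for N in the tens of thousands a
  subsampled or minibatch variant would be needed.
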