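# Methods

This note documents the models and procedures implemented in
`thermoface`, the parameter choices that matter, and what the
synthetic validation does and does not establish.

## Data model

A session is a sequence of 8-bit grayscale frames (default 384×288 at
8.7 Hz).  Pixel intensity 0–255 is treated as an uncalibrated
*emissivity* proxy for skin temperature — lighter pixels are warmer.
No conversion to °C is attempted anywhere; all effect sizes are in
intensity units.  A session carries a segment table (one 3 s neutral
baseline, then one 30 s segment per emotion), a first-frame table of
ROI seed centers, and — for synthetic sessions — a ground-truth table
of planted effects.

Frame counts per segment are `round(fps × seconds)` with half-up
rounding, so the default schedule has 26 baseline + 5×261 emotion
= 1331 frames.

## Preprocessing

Each frame is median-filtered (default 3×3, edge replication) and
Gaussian-smoothed (default σ = 1 px), then thresholded to a binary
mask.  The threshold defaults to Otsu's method (a fixed intensity can
be supplied); the face must be the *lighter* region.  8-connected
components smaller than `min_component` pixels (default 50) are
removed.  The face box is then derived from mask extrema:

- top = uppermost foreground row;
- left/right = extreme foreground columns within a horizontal band of
  half-width 10 % of the frame height around the centroid row ("near
  the centroid") — the band width is configurable because no
  canonical value exists;
- bottom = top + `bottom_factor` × (centroid row − top), clipped to
  the frame.  `bottom_factor` defaults to 2.0 (the chin sits about as
  far below the centroid as the crown sits above it for an upright
  face); it is an explicit configuration parameter because the
  proportionality constant is a modeling choice, not a measurement.

Coordinates are 0-based and row-major; boxes are half-open on
bottom/right throughout.

## ROI geometry

Eleven square ROIs are placed at seed centers given for the first
frame (manual seeding is deliberate: automatic facial landmarking is
out of scope).  The square side is a fixed fraction of the face width
— nose 6.49 %, forehead 14.28 %, periorbital 3.24 %, cheek 9.74 %,
perinasal 3.24 %, chin 5.19 % — rounded half-up with a 1 px minimum.
Width equals height, the simplest reading of a single percentage per
region.  The canonical order (LF, RF, LPO, RPO, TN, LC, RC, LPN, RPN,
LCh, RCh) is load-bearing: the difference features subtract
consecutive ROIs in exactly this order.

Seeds may be fractional.  A parity caveat: an even-sided square
centered on an integer column cannot be pixel-exact mirror-symmetric
about an integer axis; half-integer seeds (or odd sides) restore exact
mirroring.  The bilateral-symmetry tests therefore use odd-sided
pairs.

ROIs are propagated to later frames by the translation of the
detected face box relative to frame 1; sizes never change.  A frame
whose shifted ROIs would leave its face crop (or the frame) is
*flagged* and excluded from feature extraction rather than silently
clipped — the software analogue of discarding badly tracked frames by
visual inspection.  Large head motion and pose changes are out of
scope (no tracker).

## Features

Per ROI: f₁ grand mean; f₂ overall sample variance (denominator
mn−1); f₃ mean over rows of per-row sample variance (denominator
n−1); f₄ the column analogue; f₅ overall median; f₆/f₇ means of
per-row/per-column medians.  Even-length medians average the two
central order statistics.  Degenerate single-row (single-column) ROIs
have no per-column (per-row) dispersion; that term is defined as 0.

Per frame, ROI k ≥ 2 additionally carries f₈–f₁₄ = its f₁–f₇ minus
ROI k−1's.  The difference is undefined for the first ROI; its seven
slots are set to 0, preserving the 11 × 14 = 154 vector length without
inventing a circular adjacency.  Each frame is one sample ("pattern");
no temporal aggregation or trend features are computed.

## NCA feature selection

Diagonal NCA with the weighted absolute-difference distance
d(xᵢ,xⱼ) = Σₗ wₗ²|xᵢₗ−xⱼₗ| (note: absolute, not squared,
differences — this deviates from classical NCA on purpose), soft
neighbour probabilities pᵢⱼ = exp(−d/σ)/Σ_{k≠i} exp(−d/σ), and the
L2-penalized objective ξ(w) = Σᵢ pᵢ − λΣₗ wₗ².  The analytic gradient
is verified against central finite differences in the tests.

Numerical choices: the softmax is computed with per-row max
subtraction (large distances would otherwise underflow); fitting is
deterministic gradient ascent from w = 1 with backtracking step
halving and a growing step on success, stopping at `max_iter` or when
the objective gain drops below `tol`.  Because ξ depends on w only
through w², the iterate is folded to |w| after each step — weights
stay nonnegative without altering the objective.  Identical samples
produce uniform neighbour probabilities (a well-defined limit).

Defaults: σ = 1 on z-scored features; λ = 1/N.  λ = 1/N is the grid
midpoint of the usual {0.25, 0.5, 1, 2, 4}/N cross-validation grid and
behaves well across the synthetic conditions; a `tune_lambda` helper
implements the inner 3-fold CV tuner for callers who want the tuned
value, but the pipeline does not pay that cost by default.  Selection
keeps features with wₗ > τ·max(w), τ = 0.1 by default (a top-N rule is
available); the rule is configurable because no canonical
weight-to-subset threshold exists.  Selection is never empty (argmax
fallback).

## Classification

Folds respect temporal structure: each emotion's contiguous segment is
cut into k contiguous sub-segments (k = 3) and a seeded permutation
assigns one sub-segment per emotion to each fold's validation set.
This is the strictest defensible reading of segment-wise
cross-validation — temporally adjacent, near-duplicate frames never
straddle the train/validation boundary, so the reported accuracy is
not inflated by frame autocorrelation.  Baseline frames are excluded
from the 5-class problem; they are the statistics module's reference.

Per fold, in order: z-scoring with training statistics only; NCA on a
stratified training subsample (default at most 200 rows — the NCA
cost is quadratic in samples and the weight estimates stabilize well
below the full segment size); feature selection; shared-covariance
LDA with uniform priors on the selected standardized features
(scikit-learn's lsqr solver with a small shrinkage, default 1e-6,
keeps the pooled covariance invertible); prediction of the validation
rows.  A leakage-sentinel test verifies that perturbing validation
rows leaves every fitted object unchanged.

Metrics are one-vs-rest per class: accuracy (TP+TN)/total, TPR
TP/(TP+FN), FPR FP/(FP+TN), plus overall accuracy and Cohen's κ.
Per-class "accuracy" is the one-vs-rest form (distinct from recall;
both are reported).  A `permute_labels` switch re-labels frames by a
seeded permutation while keeping segment geometry — the chance-level
control (≈ 1/5 for five balanced classes).

## Emissivity statistics

Per ROI and emotion, the emissivity variation is mean(f₁ during the
emotion) − mean(f₁ during baseline), reported on the raw intensity
scale.  Significance uses a two-sample Student's t on
log₂(x+1)-transformed intensities; the +1 offset admits legal zero
pixels and is inverted exactly by `inverse_log2`.  A two-sample (not
frame-paired) test is used: baseline and emotion segments have
different lengths, so no natural frame pairing exists.

Bonferroni families follow the two analysis panels: 55 tests for
emotion-vs-baseline (11 ROIs × 5 emotions) and 25 for bilateral
asymmetry (5 pairs × 5 emotions); both sizes are configurable.
Significance tiers: ns p > 0.05, * ≤ 0.05, ** ≤ 0.01, *** ≤ 0.001 on
the adjusted p.  The tendency label is the sign of the mean variation
when significant, else "stable".

The bilateral contrast tests the *difference of variations*: the
per-frame log-scale asymmetry s = log₂(L+1) − log₂(R+1) is contrasted
between the emotion segment and the baseline segment.  Referencing
both segments to the same asymmetry series keeps the test calibrated —
a static left/right offset, or the sampling error of the estimated
baseline mean, cancels instead of inflating the t statistic.  (A
formulation that subtracts each side's estimated baseline mean and
then compares sides is anti-conservative for exactly that reason.)

Normality screening uses the classical one-sample Kolmogorov–Smirnov
test against a normal with moment-estimated parameters.  With
estimated parameters this test is conservative under H₀ (a
Lilliefors-corrected variant would reject more); it is a screen, not
a gate, and the log₂ transform is applied unconditionally as part of
the standard analysis path.

Zero-pooled-variance contrasts (possible on noiseless synthetic data)
are reported as ns with a warning rather than an error.

## Synthetic data generator

The generator emulates the study conditions the pipeline targets:
384×288 frames at 8.7 Hz; 3 s baseline + 30 s per emotion for the five
emotions; a face rendered as an axis-aligned ellipse (semi-axes
110×77 px, centered) at intensity 180 on a background of 60 —
foreground lighter, extrema well defined for the face detector, and a
measured face width (155 px) close to the scale at which the ROI
percentages were defined.  Background/face levels and the geometry
are free parameters of `SessionConfig`.

Planted effects add a signed constant to all pixels of a named ROI
during an emotion segment (optionally from a fractional onset).
Noise is i.i.d. Gaussian per pixel and frame, rounded and clipped to
[0, 255] — sufficient for type-I-error and power tests, and exactly
recoverable in the noiseless limit (the mean-variation estimator
returns the planted delta bit-exactly).  Optional head micro-motion
jitters the face center by per-frame integer offsets
(`drift_px_sd`), exercising ROI propagation without a tracker.

Since no numeric per-ROI effect magnitudes exist to copy, the example
effect pattern (`example_effects`) encodes the qualitative findings
the statistics module is meant to surface — nose decrements for
disgust/fear/happiness, periorbital/chin decrements for
happiness/sadness/surprise, a divergent cheek pair (left +8, right −8)
for every emotion — with |delta| ≥ 8 intensity units.  The SAM sampler
draws rounded truncated normals on [1, 9]; its default profile is the
published five-emotion child self-report means/SDs (e.g. happiness
valence 8.68 ± 0.82).  Truncation at the scale ends biases the
realized mean toward the center (happiness valence ≈ 8.25); the tests
quantify that bias with a brute-force oracle rather than pretending it
away.

What the synthetic validation shows: the pipeline recovers planted
ROI effects, controls the family-wise error rate on null data, ranks
planted informative features above noise, and classifies separable
effect patterns at the expected accuracy, all under the study's
temporal design.  What it does not show: performance on real faces —
no facial-expression muscle deformation, perspiration dynamics,
non-elliptical head shapes, pose changes, or inter-subject
variability are modeled, and photorealistic thermal rendering is a
non-goal.

## Problem sizes used in validation

The repeated Monte-Carlo checks keep the temporal schedule at study
values (8.7 Hz, 3 s + 5×30 s) and scale the spatial frame instead
(1/3 scale, 128×96, for classification runs; 1/4 scale for the
200-replicate statistics calibration): ROI-level effect and noise
structure is preserved while a single replicate stays cheap.  The
classification pipeline caps the NCA training subsample at 200 rows
per fold, as above.

## Known limitations

- No face tracking: propagation is pure translation of the detected
  box; rotation/scale changes flag frames instead of following them.
- The first ROI's seven difference features are identically 0 —
  harmless for LDA (zero-variance features are guarded in
  normalization) but a convention to remember when interpreting
  selection maps.
- NCA ascent converges to a local optimum; with the deterministic
  w = 1 start this is reproducible, but no restarts are attempted.
- The KS normality screen uses estimated parameters without the
  Lilliefors correction (documented above).
- Even-sided ROI squares on integer seeds mirror with a 1 px offset
  about the symmetry axis.
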