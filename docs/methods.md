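# Methods

This note records the models, statistical procedures, numerical choices and
limitations behind `reefpoint`. Everything quantitative stated here is
computed by the test suite or by `scripts/acceptance.py`; nothing is quoted
from elsewhere.

## Data model

An annotation is a label at a pixel location, keyed by
`(image_id, point_index)`. Coordinates are 0-based `(row, col)` with row 0
at the top of the image. An `AnnotationSet` holds one annotator's labels
over a collection of such keys and enforces one label per key, all labels
drawn from a single `LabelSet`. The shipped consensus vocabulary has 20
labels — eight scleractinian genera plus a catch-all, the hydrozoan
*Millepora*, sponges, soft coral, three algal functional groups (macroalgae
above 1 cm, turf assemblages at or below 1 cm, crustose coralline algae),
sand, bare space, transect hardware, an "Unclear" label, and a catch-all —
with named functional groups (`coral`, `macroalgae`, `CCA`, `turf`) used
for binary agreement statistics.

Legacy vocabularies are reconciled by dataset-scoped *remaps* applied on
ingest. Two presets ship: `moorea` (bare rock there is CCA-covered, so
"Bare space" folds into CCA) and `heron` (corals unresolved to genus, so
all genera fold into "Other scleractinians"). Remaps are configuration, not
code: any `(source, target)` list whose targets are declared labels is
accepted.

Two survey-level corrections are implemented as explicit operations:

* **Transect-hardware majority rule.** Annotators disagree on whether to
  label the hardware or the substratum inferred beneath it. Where at least
  `threshold` (default 2) of the annotators call a point "Transect
  hardware", all annotators are rewritten to that label. The operation is
  idempotent.
* **Reference rebalancing.** Training and deployment data should not share
  class priors by construction. With `C` in-group and `N` out-of-group
  training annotations, a uniformly random subset of the out-of-group ones
  is discarded so the group proportion rises by a chosen relative amount
  (default +10%). The retained count `N′` is the integer minimising
  `|C/(C+N′) − target|`; ties resolve toward fewer discards. At the scale
  of a real reference pool (19,566 in-group of 94,200) this yields 66,070
  retained out-of-group annotations and a 22.85% group proportion; archived
  worked figures for the same arithmetic differ by a couple of counts,
  presumably from a different rounding rule, so tests accept ±5 counts
  rather than guess it.

## Patch encoder

The feature encoder is pluggable (any callable with a distinct
`encoder_id`); the default is deliberately simple and fully deterministic.
For a square patch of side `patch_size` centred on the point (edges filled
by reflection):

* per RGB channel: mean, standard deviation, and an 8-bin intensity
  histogram normalised by patch area (30 components);
* per smoothing scale σ ∈ {1, 2}: an 8-bin orientation histogram of
  gradient direction over [0, π) weighted by gradient magnitude, plus the
  mean gradient magnitude, both computed on the Gaussian-smoothed
  grey-level patch and normalised by area (18 components).

A constant patch therefore has exactly zero in every gradient-derived
component, and identical patch content yields identical vectors regardless
of position. The default side length is 224 px for survey-scale imagery;
the synthetic experiments use 13–21 px patches to match their 64–96 px
mosaics. The encoder is a documented default, not a reimplementation of
any particular published encoding; a Fisher-vector encoder can be swapped
in through the same interface.

## Classifier

One-versus-rest linear scoring: `score(x, m) = w_m·x + b_m`, fit with
`sklearn.svm.LinearSVC` (primal, fixed seed, standardised features with the
affine map folded into the stored weights, so scores remain affine in raw
features). The binary case is expanded to a symmetric two-row form so
argmax semantics match the multiclass case. Scores are raw decision
values, not calibrated probabilities: the deferral rule thresholds raw
scores. The inverse-regularisation constant defaults to 1.0 and can be
selected from {0.01, 0.1, 1, 10} on a seeded 80/20 validation split.

Labels in the vocabulary but absent from training receive a finite
sentinel score (−10¹²) and are therefore never predicted. The sentinel is
finite so score matrices satisfy the all-finite container invariant. Score
ties break toward the earlier label in the vocabulary order, which makes
argmax deterministic.

## Alleviate

The deferral rule is exactly `max[s_ik] > ε` (strict): at equality the
point goes to the human. The achieved level λ(ε) is a right-continuous
step function taking values `#{max-score > v}/n` at the distinct max
scores `v`; `epsilon_for_level` enumerates these candidates plus one value
below the minimum (λ = 1) and returns the threshold whose achieved level
is closest to the target, resolving ties toward the *lower* level (more
human decisions). Consequences worth noting: level 0 reproduces the human
annotation set exactly and level 1 the automated set exactly, so the
alleviation curve's endpoints equal the human-only and automated-only
kappas by construction, and with heavily tied scores some target levels
are unreachable (the tie rule then errs toward human effort).

## Abundance

If the classifier's confusion matrix Q′ (rows = true label, columns =
assigned, rows summing to 1) is known, the expected automated cover vector
is `Q′^T c_true`, so `c_corrected = (Q′^T)^{-1} c_automated` de-biases the
estimate. Numerical policy:

* Q′ rows with zero reference count are replaced by identity rows before
  inversion (an unobserved label passes through the correction untouched).
* A ridge of 1e−8 is added to the diagonal before solving; conditioning is
  judged on the *unridged* matrix, and condition numbers above 1e12 route
  to the pseudo-inverse with a warning (e.g. duplicated rows).
* Because Q′ is row-stochastic, the corrected vector conserves total mass
  (to 1e−6); individual entries may be negative and are returned as-is by
  default, since clipping would reintroduce bias in aggregate. A
  `clip_negative` flag clips and renormalises for display.

The correction is applied per image and averaged afterwards, following the
per-image definition of cover; an aggregate-then-correct path can be had
by correcting the mean automated cover directly with `abundance_correct`.

Q′ is estimated by k-fold cross-validation (default 20 folds) stratified
*by image*: all points of an image share a fold, so co-located patches
never straddle the train/test split. Folds equal to the number of images
give leave-one-image-out, verified in the tests against an explicit loop.

The Monte-Carlo experiment behind the unbiasedness claim draws per-image
true covers from a Dirichlet with concentration (4, 2, 1, 1) — one dominant
substratum and several rarer ones. The asymmetry is load-bearing: the
uniform vector is a fixed point of a symmetric confusion mixing, so a
symmetric prior would make even the *uncorrected* estimator appear
unbiased at the mean and the comparison vacuous. At 200 images × 10
points × 50 replicates the corrected mean cover lands well within 1.5
percentage points of truth while the raw automated mean is several points
off, and the per-image variance of corrected covers exceeds that of the
raw ones — the expected price of the inversion.

## Agreement and cover-error statistics

Cohen's κ = (p_o − p_e)/(1 − p_e) with chance agreement from the two
empirical marginals, computed over pairwise-shared keys; points where
either annotator used an excluded label (e.g. "Unclear") can be dropped
via `exclude_labels`. When both sets are the same constant labelling the
chance term degenerates and κ is defined as 1; a constant-but-disagreeing
pair has p_e < 1 and needs no special case. Group kappa κ_Ψ collapses the
vocabulary to in-Ψ/out-Ψ first. The implementation is independent of
scikit-learn's and is cross-checked against it in the tests.

Cover errors follow the d/e/MAE chain: per-image differences
`d_i(m) = c_i^a(m) − c_i^ref(m)`, per-label bias `e(m) = mean_i d_i(m)`,
and MAE as the mean of |e| over a caller-selected set of
(annotator, label) cells — the grouping (per substratum across surveys,
per annotator class, etc.) is configuration, not convention.

Inference on the `d` vectors is nonparametric:

* **Permutation t-test** (one-sample, sign-flip): the t statistic is
  recomputed under sign flips of `d`; all 2^n patterns are enumerated
  exactly for n ≤ 12, otherwise Monte-Carlo patterns are drawn with the
  observed pattern always counted. Two-sided p is the fraction of |t*| ≥
  |t| (with sd = 0 mapped to t = 0 or ±∞ by the sign of the mean — so a
  constant nonzero sample has p = 2/2^n). The Bonferroni-corrected
  threshold defaults to 0.05/8 = 0.00625, for the eight compared
  annotators and modes.
* **Percentile-t bootstrap**: t* = (mean* − mean)/se* over resamples;
  interval `(mean − q_{1−α/2}·se, mean − q_{α/2}·se)`. Constant input
  yields the degenerate zero-width interval. Empirical coverage at n = 200
  standard-normal samples sits in the 0.93–0.97 band (checked over 1,000
  replicates in the tests).

Mann-Whitney U, Kruskal-Wallis, one-sample Kolmogorov-Smirnov and Pearson
correlation are thin delegations to `scipy.stats` with arity checks only.

## Synthetic generators

`generate_mosaic` renders a Voronoi partition (nearest of `n_regions`
uniformly placed seeds) of the canvas, each region carrying a class with a
base colour, an oriented sinusoidal texture, and additive Gaussian noise;
the ground-truth label map is exact by construction, which is why Voronoi
was chosen over blob-growth models. A `separation` knob scales both colour
spread and texture divergence; at 0 all classes render identically and
classification sits at chance, which anchors the monotonicity tests.

`simulate_annotator` redraws each point's label independently from the
true label's row of a given confusion matrix — the standard conditional-
independence model of annotator noise. `simulate_scores` emulates the
classifier: argmax through a confusion row, max score from
N(μ_correct, σ) or N(μ_error, σ) depending on correctness, remaining
scores trailing the max by random positive gaps. μ_correct = μ_error is
allowed as the degenerate uninformative case.

What these generators do *not* emulate — and hence what passing tests do
not establish about real surveys: spatially correlated annotator errors
(real confusion concentrates along specific boundaries such as turf vs
CCA), within-image label autocorrelation beyond region contiguity, optical
degradation (turbidity, attenuation, strobe vignetting), class-imbalanced
rare taxa, and human annotators whose error rates drift with fatigue or
training. The synthetic results validate the *machinery* — estimators,
identities, invariances — not field-scale accuracy figures.

## Problem sizes and determinism

The default experiment configurations use 64–96 px mosaics, 6–10 images
per split, 20–30 points per image and 13–21 px patches; the Monte-Carlo
experiments use 2,000–100,000 simulated points. These sizes were chosen so
the whole suite and the acceptance script each run in well under a minute
of CPU while keeping every statistical check several standard errors away
from its threshold. All randomness flows from explicit integer seeds; no
function touches global RNG state, and identical configurations hash to
identical reports.

## Known limitations

* The default encoder is a compact colour/texture summary, not a
  state-of-the-art image representation; on real photoquadrats a stronger
  encoder (Fisher vectors, learned features) should be plugged in via
  `encoder_id`.
* Per-point features are computed independently; dense per-image
  pre-computation would be faster for many points per image.
* The Abundance correction assumes the deployed data follow the same
  distribution as the pool on which Q′ was estimated; under domain shift
  a subset of the target data must be annotated to re-estimate Q′.
* Negative corrected covers, while correct in aggregate, complicate
  per-image interpretation; the clip-and-renormalise display option is
  biased and should not feed further analysis.
* `AlleviateResult.level` reports the achieved level, which with tied max
  scores can differ from the requested target.
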