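# Methods

## The active-learning scheme

`alseg` implements stream-based selective sampling for segmentation
training. A segmenter is fitted on an initial set of `initial_n`
expert-labelled cases, then the unlabelled pool is consumed in fixed-size
batches (`increments`). For every batch case the current model predicts a
probability map and a thresholded mask, and a per-case decision is made:

* **oracle rule** — the prediction's Dice score against ground truth is
  computed; the case joins the training set with the *predicted* mask when
  `DSC ≥ τ` and with the expert ground truth otherwise. τ defaults to 0.7;
  0.8 is used when comparing against the three-class triage rule, so the
  two rules share a cut-point.
* **triage rule** — a reference-free quality classifier assigns one of
  `Poor` / `Acceptable with Adjustments` / `Acceptable`; only `Acceptable`
  keeps the predicted mask. The class boundaries are Dice 0.6 and 0.8 with
  a half-open convention (0.6 → Adjust, 0.8 → Acceptable): the boundary
  values are genuinely ambiguous in prose descriptions of such schemes, and
  half-open intervals give a total, non-overlapping partition.

Training then continues on the union of all records, and the fixed test
set is re-evaluated. The loop's invariants — training-set size equals
`initial_n + Σ increments` after each round, every pool case appears
exactly once with exactly one mask provenance, every decision matches the
rule given its recorded score — are asserted in the test suite rather than
assumed.

**Plateau checkpointing.** Before scoring a pool batch the model is rolled
back to the epoch where validation Dice first plateaued, so that
improvements after augmentation measure the value of the new data, not of
longer training. "Plateau" is formalised as the first epoch whose trailing
window (default 5 epochs) has range ≤ ε (default 0.005 Dice) and does not
end below the window's start by more than ε. When no window qualifies the
final epoch is used and a warning is logged — never a silent skip.

**Reference-free constraint.** In triage mode the pool's ground truth is
consulted only (a) for cases the triage routes to expert labelling —
emulating an expert segmenting on demand — and (b) for post-hoc test-set
evaluation. Every truth access is appended to an audit trail with its
purpose, and a test asserts that no substituted case's truth was ever read
as a training label and that no oracle-style pool scoring occurred.

**Equivalence property.** With a perfect (truth-peeking) triage predictor,
a triage-mode run is record-for-record identical to an oracle-mode run
with τ = 0.8, because `class ≠ Acceptable ⟺ DSC < 0.8` under the half-open
convention. This is asserted exactly (including mask bytes) and is the main
correctness check of the triage plumbing.

## The reference segmenter

The pluggable `SegmenterContract` requires only `fit`, `continue_fit`,
`predict` and (optionally) `restore_epoch`. The shipped reference model is
a per-voxel logistic classifier trained by SGD (scikit-learn
`SGDClassifier`, log loss, α = 1e-4), one pass over the training voxels per
"epoch", with per-epoch weight snapshots backing `restore_epoch`. Features
per voxel: the selected channel intensities (default T1, T2, FLAIR), the
same intensities Gaussian-smoothed at σ = 1 and 2.5 voxels, and normalised
spatial coordinates; features are standardised by the statistics of the
first fit. Background voxels are subsampled at 3:1 background:foreground
per case — lesions occupy a few percent of a brain volume, and without
rebalancing the classifier would favour the trivial background solution.
The decision threshold on the probability map is 0.5.

This model is intentionally small: the package's subject is the *loop*
(selection, substitution, bookkeeping, triage), and a desk-scale segmenter
makes every end-to-end property testable on one CPU in seconds. A GPU CNN
backend can implement the same contract; the hyperparameters such a backend
would conventionally use (batch size 40, initial learning rate 0.01, Adam,
Dice loss with 1e-5 decay, 64 epochs) are carried in
`ReferenceSegmenterConfig.deep_backend` as adapter defaults and are not
consumed by the reference model.

## The baseline triage predictor

The deployable triage predictor is a contract too. The shipped baseline is
multinomial logistic regression on summary features of the probability map
chosen to proxy model confidence: predicted volume fraction, mean
foreground probability, mean binary entropy, uncertainty mass (fraction of
voxels with probability in (0.3, 0.7)), connected-component count, and the
mean image-gradient magnitude over mask-boundary voxels per channel
(default T1c, T2, FLAIR — the channel triple most informative about lesion
conspicuity). It must be trained on labelled cases *disjoint* from the pool
it will score; `run_experiment` rejects any overlap. A CNN on the images
plus probability map could replace it behind the same contract.

## Segmentation metrics

Dice, Jaccard, voxel sensitivity and PPV are plain voxel-count ratios.
Degenerate conventions: both masks empty → Dice = Jaccard = 1 (perfect
agreement on absence); one empty → 0; sensitivity is NaN for an empty
truth, PPV for an empty prediction; cohort summaries exclude NaNs and
report the exclusion count. The modified Hausdorff distance is the
Dubuisson–Jain form — the maximum of the two directed *mean*
nearest-neighbour distances — computed between boundary voxel sets
(6-connectivity boundary), which matches common medical-imaging usage; a
flag switches to the full-voxel-set variant. Distances are in voxel units
by default and physical mm when spacing is supplied. All four metric
families are verified against independent brute-force oracles
(set arithmetic, all-pairs distances, pair-counting AUC) to 1e-9.

## Preprocessing

The crop box is derived from a maximum intensity projection over the whole
cohort: the tight bounding box of supra-threshold voxels, optionally
expanded symmetrically to a fixed target size (default 160×216×128 for
240×240×155 inputs), with odd padding biased toward the lower index for
determinism and the box clamped inside the grid. Intensities are
normalised to [0, 1] by the 98th-percentile value so a handful of bright
outliers cannot compress the dynamic range; the percentile is computed over
strictly positive voxels only (background-dominated brain volumes would
otherwise drag it toward 0) with the linear-interpolation quantile
convention, and values above it clip to 1. Both choices are configurable.
Bias-field correction is an external pre-step: the pipeline accepts
corrected volumes and renders a shell command for an external N4 tool
(`n4_hook_command`) rather than reimplementing it. Volumes on mismatched
grids are an error, never silently resampled.

## The phantom generator

Each case is an ellipsoidal "brain" (smooth low-frequency tissue texture,
base intensity 0.45) on a 48×48×32 unit-spacing grid with one or two
lesions built as nested anisotropic ellipsoids — necrotic core (label 1)
inside an enhancing rim (label 4) inside edema (label 2), outer radii drawn
from 4–9 voxels. Channel contrast is compartment-specific with the usual
signs (edema brightest on FLAIR, rim enhancing on T1c, core dark on
T1/T1c, bright on T2) and Gaussian noise (σ = 0.04 baseline) is added per
channel. A single difficulty scalar d ∈ [0, 1] couples what makes a case
hard: contrast × (1 − 0.9 d), noise × (1 + 3 d), plus Poisson(6 d)
distractor hyperintensities — small non-lesion blobs sharing the edema's
channel signature, the analogue of white-matter lesions or artifacts that
stress specificity. The shipped `mixed` preset draws per-case difficulty
uniformly from (0.1, 0.9), which at the shipped cohort sizes yields
per-case Dice scores spanning both sides of the 0.7 substitution threshold
and both sides of 0.8, as a heterogeneous clinical cohort would.

What the phantoms do **not** emulate: anatomical realism, bias fields,
multi-site intensity variation, registration error, or CNN-scale texture
complexity. Passing tests therefore demonstrate the correctness of the
selection/substitution/triage machinery and the qualitative behaviour of
the loop — not clinical segmentation performance, which requires a real
cohort and a deep segmenter behind the contract.

## Problem sizes and determinism

The shipped study conditions are a 78-case mixed cohort (12 test,
3 validation, 10 initial training, 53 pool) run as 10 → +20 → +30 — a
deliberate scale-down of the three-round staged design to desk scale — and
25-case fixed-difficulty cohorts at d = 0.2 / 0.5 / 0.8 for the difficulty
trend. All randomness (cohort synthesis, splits, pool order, SGD) flows
from explicit integer seeds; reruns with the same seed produce
byte-identical CSV/JSON outputs, which the test suite asserts at file
level. With a 12-case test set, round-to-round differences in mean test
Dice of a few points are within sampling noise; the directional claim
(final active-learning round not below the initial reduced-data model)
is asserted at the shipped conditions and seed.

## Known limitations

* The reference segmenter is linear per voxel; it cannot exploit shape or
  long-range context, so its absolute Dice on hard phantoms understates
  what a CNN achieves, and gains from additional training rounds are
  modest once its capacity saturates.
* The triage baseline's features summarise confidence globally; it cannot
  localise *where* a segmentation fails.
* Standard specificity TN/(TN+FP) is reported alongside NPV TN/(TN+FN)
  because published triage tables sometimes print the latter under the
  former's name; users comparing to external tables should check which
  convention those tables use.
* Whole-tumour (binary) segmentation only; the sub-region labels exist in
  the phantoms and the label policy, but multi-class training is out of
  scope.
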