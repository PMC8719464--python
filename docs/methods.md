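# Methods

## Overview

`perceptcad` implements a two-stage computer-aided diagnosis (CAD) method
for benign/malignant classification of breast masses on mammograms,
together with the observer-study arithmetic used to evaluate such a method
against radiologists, and a synthetic lesion phantom that makes every
stage runnable and testable without patient data.

The central idea of the method is *intermediate supervision by structured
radiology reports*: instead of training a CNN end-to-end against the
biopsy label, Stage 1 trains the network to regress the radiologist's own
BI-RADS description of the mass, quantified on a malignancy scale, and the
network's penultimate layer then serves as a fixed "perceptive feature"
representation for a classical Stage-2 classifier.

## BI-RADS quantification

A mass description is a five-tuple: shape (oval/round/irregular), margin
sharpness (circumscribed/obscured/indistinct), microlobulated margins
(yes/no), spiculated margins (yes/no), and density (low or fat-containing
/ equal / high).  Terms associated with malignancy code to 1, uncertain
terms to 0.5, benign terms to 0, giving a vector

    d = [d_shape, d_margin, d_lob, d_spic, d_density] in {0, 0.5, 1}^5

in that fixed order.  "An irregular mass with obscured and microlobulated
margins and high density" maps to [1, 0.5, 1, 0, 1].  Parsing of report
phrases is keyword spotting over this closed vocabulary — the reports the
pipeline consumes are structured lexicon phrases, not free text.  Density
is treated as a mandatory phrase; reports lacking one are rejected rather
than silently imputed.

## Stage 1 — perceptive-feature extractor

The network is a VGG16 layout: 13 convolution layers (3x3, ReLU) in five
max-pooled blocks, then three fully connected layers of which the last has
128 units, then a 5-unit linear head.  Input is a two-channel tensor: the
lesion patch (min-max normalized to [0,1]) and its binary ROI mask,
default side 288 px.  Loss is mean squared error between the head output
and the case's descriptor vector d; both the CC and MLO view of a case are
independent training samples sharing the same d.  Optimization is Adam,
learning rate 1e-4 decaying by 0.1 at epochs 30 and 60, for up to 70
epochs.  After training, the head is discarded, the weights are frozen,
and the post-ReLU activations of the 128-unit layer are the perceptive
features of a view.

Numerical choices:

* **Initialization** defaults to variance-scaled (He) normal draws.  A
  literal standard-normal initialization of every weight is retained as an
  option (`init_scheme="paper_normal"`), but it overflows float32 in a
  full-width stack within one epoch and is not recommended; the test suite
  demonstrates exactly that divergence.
* **Input centering**: the [0,1] channels are shifted by -0.5 at the
  network entry.  This is internal to the network (the input contract is
  unchanged) and materially speeds ReLU training from random init.
* Dropout (default 0.5) follows the first two fully connected layers,
  disabled at inference, so feature extraction is a pure function of
  (weights, patch).
* All tensors are float32; convolutions are im2col + BLAS GEMM with
  analytic backward passes.

**Downsized profile.**  The full 288-px network is CPU-hostile, so a
desk-scale profile (`ExtractorConfig.downsized()`) is provided and used
throughout the tests: 64-px input, conv widths at 1/8 of VGG16, fully
connected stack (512, 256, 128) — the 128-feature contract is preserved —
batch 8, Adam at 1e-3 with the step decays compressed to 70% and 90% of
the epoch budget, dropout 0.2, at most 30 epochs.  The higher learning
rate, smaller batch and lighter dropout reflect that at this scale the
limiting resource is gradient steps, not data; these settings were chosen
by validation experiments on phantom data.

The freeze point defaults to the final epoch (`freeze_policy="final"`,
the fixed-epoch convention); `"best_val"` instead restores the weights of
the epoch with the lowest validation MSE when validation cases are
supplied — the plateau-based alternative.

## Stage 2 — stepwise selection + LDA, fusion

Feature selection is classical forward/backward stepwise regression of the
0/1 pathology label on the 128 features: a candidate enters when the
partial-F p-value of its coefficient is below p_enter = 0.05 and a
selected variable leaves when its p-value rises above p_remove = 0.10
(the stepwisefit defaults); ties break on lowest p-value then lowest
index, so selection is deterministic.  The test on an *ordinary linear*
model is deliberate — it matches the named procedure — even though the
response is binary.

The classifier is equal-covariance Gaussian discriminant analysis on the
selected features, fitted lesion-wise (views undifferentiated).  The
probability of malignancy (POM) of a view is the malignant-class
posterior; class priors default to empirical frequencies; a singular
pooled covariance is ridged with `1e-6 * trace/d * I`.  A case's POM is
the arithmetic mean over its views.

Cross-validation builds the final model: cases (never single views) are
randomly partitioned into K = 10 folds, stratified by pathology label by
default; per fold, Stage 1 and then Stage 2 are trained on the other K−1
folds, giving K member models.  The fused POM of a test case is the mean
of the member POMs — posteriors are averaged, not discriminant scores,
matching the "averaged probability of malignancy" definition.  Fusion can
therefore never leave the [min, max] range of its members.

Interpretations made where the procedure was underdetermined: fold
assignment is at case level to prevent a case's two views leaking across
folds; stratification is on by default but switchable.

Two evaluation modes are exposed.  *Fused* scoring (`fused_pom`) averages
all K member posteriors for a case and is the deployment output for
independent test data.  *Out-of-fold* scoring (`oof_poms`) scores each
training-collection case with the member of its own validation fold,
giving the cross-validated ("held-out") predictions used to estimate
generalization without an external test set.

## MRMC observer-study analytics

Reader records (reader x session x case: BI-RADS category,
benign/malignant call, POM 0-100%, time in seconds) are analysed as a
fully crossed multi-reader multi-case design:

* **ROC/AUC** — thresholds sweep the ranked POMs ascending; TPR/FPR are
  computed at each distinct threshold; the trapezoidal AUC equals the
  Mann-Whitney two-sample statistic with half-credit for ties (asserted
  against an O(n^2) oracle in the tests).  The reader-averaged AUC is the
  arithmetic mean of per-reader AUCs.
* **AUC difference** — aided minus unaided reader-averaged AUC, with a
  case-level bootstrap (readers fixed, percentile interval, two-sided
  p-value).  This is a deliberate substitute for variance-component MRMC
  inference (Obuchowski-Rockette style): p-values produced by that family
  of methods are not reproduction targets of this package.
* **Binary metrics** — sens = TP/(TP+FN), spec = TN/(TN+FP),
  PPV = TP/(TP+FP), NPV = TN/(TN+FN); zero denominators yield NaN
  markers.  Printed rates can be inverted back to integer confusion counts
  given the class sizes (22 malignant / 29 benign in the packaged study);
  reconstruction tolerances are half a count by default, or printed
  precision (5e-4) when auditing table consistency.  One packaged
  sensitivity cell (reader 5 aided, printed 0.901 where 20/22 = 0.909) is
  flagged as a probable printing error; reported values are rounded half
  up to 3 decimals (2 for times) and table comparisons use a 0.001
  tolerance to absorb occasional truncation in the source tables.
* **BI-RADS changes** — categories are ordered 1 < 2 < 3 < 4 < 4a < 4b <
  4c < 5 (plain 4 admitted between 3 and 4a; only the direction of change
  matters).  A changed case is "closer to biopsy" when it moved toward the
  recall side (>= 4) under malignant truth or toward the follow-up side
  (<= 3) under benign truth — an explicit operationalization via the
  BI-RADS 4+ biopsy-recommendation convention.
* **Times** — per-reader means (2 decimals), aided-minus-unaided
  difference, percent change relative to unaided, two-sided paired t-test.

## Synthetic lesion phantom

The phantom emulates a curated FFDM mass dataset: per case, two
independently rendered views (CC/MLO) sharing one descriptor vector, a
radiologist-style ROI mask, and a biopsy-style label.

Geometry is a star-shaped polar radius function about the patch centre:
a base ellipse (axis ratio 0.70-0.95, random orientation, radius 16-22%
of the patch side); irregular shape adds random radial harmonics of order
2-6; microlobulation adds a sinusoidal undulation of 5-9 lobes;
spiculation adds 8-15 narrow Gaussian spikes (merged by maximum so they
cannot stack past the patch border).  Boundary-perturbation amplitudes are
sized so each descriptor's geometric signature spans multiple pixels at
the default 64-px test scale.  The mask is the pre-blur support — margin
blur (Gaussian sigma 0.5 / 1.6 / 3.2 px at 64 px, scaled with patch side)
degrades the image edge but not the ROI, as a radiologist outlines the
lesion regardless of edge conspicuity.  Density codes select
lesion-to-background contrast (0.14 / 0.28 / 0.46) over a correlated-noise
background; a mild pixel noise floor is added and intensities are clipped
to [0,1].

The label is Bernoulli with logit `w0 + w . d`.  Default weights
(intercept −9.5; shape 4.5, margin 4.5, lobulation 3.0, spiculation 5.0,
density 2.0) are ordered by clinical salience, with the intercept at minus
half the weight sum so the malignancy marginal is exactly 1/2 under the
symmetric default descriptor marginals.  The scale was chosen by a
design-time Monte-Carlo calculation so that the best achievable
(Bayes) case-level AUC under the label noise is ~0.95, emulating the
separability a well-trained CAD model reports on real curated data.

Per-case RNG streams hash (seed, case index), so generation is
reproducible and order-independent; the two views differ only through the
stream.

**What the phantom does not emulate:** X-ray physics, breast-density
(BI-RADS a-d) background structure, calcifications or other non-mass
findings, inter-view geometric consistency (views are i.i.d. re-renders,
not projections), and the intensity statistics of any particular detector.
Passing tests on phantom data therefore demonstrate that the pipeline
recovers a descriptor-mediated label from images whose descriptors are
rendered as controllable geometry — not that it reaches any particular
performance on clinical FFDM.

## Problem sizes and budgets used in the tests

The packaged checks run the downsized profile end to end: 400 phantom
cases at 64 px, K = 5 cross-validation (members train on 320 cases, 20
epochs), evaluated by the out-of-fold case-wise AUC.  Unit tests use smaller instances (tiny
32-px networks, 8-40 cases) chosen to exercise contracts rather than
performance.  The stepwise/LDA statistical checks use planted linear
models (n = 200, 5 informative of 20 features, noise sigma 0.1) and
two-Gaussian samples (n = 10,000 per class) with fixed seeds.

## Known limitations

* The numpy network trains on a single CPU; there is no GPU path, no
  data augmentation, and no ImageNet pretraining (the method trains from
  random initialization by design).
* Stepwise partial-F inference on a binary response is the named
  procedure, not a statistically efficient choice; it is kept for
  fidelity.
* The bootstrap AUC-difference test fixes readers, so it quantifies
  case-sampling variability only — reader-sampling variability (the
  second MRMC variance component) is out of scope.
* POM calibration beyond the LDA posterior (e.g. isotonic recalibration)
  is out of scope.
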