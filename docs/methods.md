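# Methods

## The model

DrVAE is a semi-supervised deep generative model for predicting binary drug
response of cancer cell lines from pre-treatment gene expression, while
jointly modeling the drug-induced transcriptomic perturbation observed in
short-term case/control screens.  The joint distribution over pre- and
post-treatment expression `x1, x2`, their latent embeddings `z1, z2`, a
class-independent latent `z3` and the response label `y` factorizes as

    p(x1, x2, z1, z2, z3, y)
        = p(x1|z1) p(x2|z2) p(z2|z1) p(z1|z3, y) p(z3) p(y)

with all conditionals diagonal Gaussians, `p(z3) = N(0, I)` and `p(y)`
uniform Bernoulli.  Assumptions worth stating explicitly:

* **Shared codec.** One encoder `q(z|x)` and one decoder `p(x|z)` serve
  both the pre- and post-treatment roles, forcing both states into one
  latent space.
* **Linear latent perturbation.** The mean of `p(z2|z1)` is constrained to
  `z1 + W z1 + b`; `W, b` are initialized with sd `pert_init_sd = 1e-4` so
  the perturbation starts as the identity.  Its variance is a free
  per-dimension parameter, independent of state.
* **Linear classifier.** `q(y|z1, z2)` is a two-unit linear softmax reading
  `[z1, z2 - z1]` — the embedded baseline and the predicted perturbation
  signature.
* **Gaussian gene likelihood** with a free per-gene variance shared across
  samples.  This fits standardized continuous expression; counts or
  mutation status would need other likelihoods and are out of scope.

Four data regimes contribute evidence lower bounds: labeled and unlabeled
perturbation pairs, labeled and unlabeled pre-treatment singletons.  For
unlabeled items the discrete label is summed out under the classifier
posterior and its entropy added (the standard semi-supervised VAE
construction).  Because the bounds for labeled data condition on `y`, a
weighted cross-entropy term (`class_loss_weight`) is added so the
classifier also trains on labeled items.  When `x2` is unobserved the
classifier reads the expected perturbation `z2 = E[p(z2|z1)]`.

### Estimator structure

All expectations use single-sample reparameterized draws.  Two
Gaussian-Gaussian terms are computed in closed form because they are exact
conditional expectations given the sampled conditioning variables: the
transition term `E_q(z2|x2)[log p(z2|z1) - log q(z2|x2)]` given `z1`, and
the `z3` prior term given `(z1, y)`.  The `z1`-prior term
`log p(z1|z3, y) - log q(z1|x1)` is deliberately kept as a sampled
log-ratio: the hierarchical posterior factor `q(z3|z1, y)` conditions on
the sampled `z1`, so substituting a closed-form KL (an expectation over a
*fresh* `z1`) would bias the estimator and can break the lower-bound
property.  With this structure every estimator is an unbiased single-sample
estimate of a true ELBO; the test suite verifies the bound against
trapezoid-quadrature log evidence on one-dimensional toy models and
verifies tightness in an all-affine conjugate construction whose exact
posterior lies inside the variational family (the label coefficient of the
prior network is zero there, since the encoder does not see `y`).

### Optimization

Gradients are obtained by reverse-mode automatic differentiation
(`autograd`) through the reparameterized objective; updates use Adam
(lr 1e-3 by default, moments 0.9/0.999) on minibatches of 64, with
gradient clipping at 1e4 as a safety net.  Training is fully determined by
a single integer seed (separate child generators for initialization, noise
and shuffling).  Early stopping monitors the validation objective
(patience 20 epochs, best parameters restored) evaluated with a noise draw
fixed per run so that epochs are comparable.  The classification-loss
weight is selected from a log-spaced grid `{0.1, 1, 10, 100}` by validation
AUROC, falling back to the validation objective when AUROC is undefined
(no labels, single class, or the unsupervised PertVAE).  Whether the
original protocol selected this weight by loss or AUROC is not documented;
AUROC matches the quantity being reported and is our choice.  The
cross-entropy term receives gradients through the same reparameterized
samples as the ELBO.

### Architecture defaults

Latent dimension `d = 100` for both `z1/z2` and `z3`; data encoder/decoder
have one ELU hidden layer of 512 units, the `z3` encoder and `z1` prior
network one of 256.  The hidden widths are package choices exposed in
`ModelConfig` (the reference description fixes only the latent
dimensionality and the one-hidden-layer, ELU convention); setting a hidden
width to 0 makes that network affine, which the conjugate tests rely on.
Variances are carried in log-space everywhere; classifier probabilities
are clamped at `1e-7` before logs.

### Ablations

* **SSVAE** — no perturbation modeling: pairs are flattened to their
  pre-treatment member and `W, b` and the perturbation variance are frozen
  at the identity, which makes the classifier's difference block
  identically zero (equivalent to a classifier on `z1` alone).  On a
  pairless batch its objective coincides term-for-term with DrVAE's.
* **PertVAE** — the unsupervised sub-model `p(x1|z1) p(x2|z2) p(z2|z1)`
  with standard-normal prior on `z1`; labels are ignored.  `embed(x)`
  (the mean of `q(z1|x)`) is the reduced representation handed to
  downstream classifiers.
* **DrVAE w/I** — `set_identity_perturbation` zeroes `W, b` in a trained
  model without retraining; its post-treatment prediction is then exactly
  the autoencoding reconstruction of `x1`.

Prediction is deterministic mean propagation (posterior mean of `z1`, mean
of `p(z2|z1)`, classifier on the means) and needs only `x1`, so it applies
to viability-only samples with no measured post-treatment expression.

## Preprocessing

Vehicle (DMSO) controls are matched to treatment wells by (batch ID, bead
ID); one control may serve several treatments.  Pairs whose profiles
correlate at Pearson rho <= 0.75 are dropped as likely mislabeled wells.
Genes are standardized to zero mean and unit variance with the population
(divide-by-n) convention, recorded in the transform's metadata.  The first
principal component of the pooled standardized training data is removed as
a coarse batch/source correction; standardization happens first (the
source description is ambiguous on the order, and deflating standardized
data is the convention we fix).  Both transforms store their fit
provenance and refuse matrices with a different gene count, so held-out
rows always receive training statistics.

Continuous sensitivity (AAC, area above the dose-response curve, in [0,1])
is binarized per drug by a waterfall rule: sort AAC descending; if the
sorted curve is nearly linear in rank (|Pearson rho| >= 0.95 against rank)
the cutoff is the median, otherwise it is the AAC at maximum perpendicular
distance from the chord joining the extreme points; values strictly above
the cutoff are "sensitive", ties at the cutoff go to non-sensitive.  The
exact waterfall variant used upstream of the original data is not
published; threshold and branch rule are exposed as arguments.  Drugs are
retained when they have at least 8 perturbed cell lines and at least 20%
sensitive screened cell lines.  Concentration selection uses the modal
tested concentration (ties to the lower value), with closest-by-log10
fallback.

## Evaluation protocol

`make_splits` reproduces the grouped, stratified, repeated 5-fold x 20
protocol (100 splits): all samples of a cell line stay in one fold;
perturbation-source cell lines are folded separately and pooled into
training and validation only, so test folds contain exclusively
viability-only cell lines; singleton folds are stratified by responder
ratio (round-robin within class strata, per-fold positive counts within
one of balance).  For repeat r, fold f is the test fold and fold
(f+1) mod k the validation fold — the rotation rule is ours; validation
folds may contain pair cell lines, which the protocol's pooling wording
permits.

AUROC is the Mann-Whitney ordering probability (ties half); AUPR uses the
step-wise (non-interpolated) average-precision convention — conventions
differ between libraries, so this is recorded here.  Both delegate to
scikit-learn and are cross-checked in the tests against exhaustive pair
counting and threshold enumeration.  Method comparison uses the one-sided
Wilcoxon signed-rank test in both directions at alpha = 0.05, zero
differences discarded, exact null for n <= 25 without ties and the
continuity-corrected normal approximation otherwise (scipy), validated
against full 2^n sign enumeration.

ERVR (effect-to-replicate variance ratio) summarizes perturbation signal:
the mean over genes of the across-pair variance of the effect `x2 - x1`,
divided by the mean over genes of the pooled within-group variance of
replicate vehicle controls (sample variances, pooled by degrees of
freedom).  The published definition lives in unavailable supplementary
material; this reconstruction is documented here and both halves are
plain functions that can be swapped.  A zero denominator with nonzero
numerator reports infinity rather than raising.

## Synthetic data generator

The generator emulates the statistical structure the model assumes, with
known ground truth: per-cell-line latents `z1 ~ N(0, I_k)` (k = 5 by
default), an exact linear latent effect `z2 = z1 + W* z1 + b*` with
`W*, b*` scaled by `effect_scale`, a fixed decoder (random linear map with
orthonormal rows, optionally followed by `tanh(g.)/g` at small gain
g = 0.2 so both well-specified (g = 0) and mildly misspecified regimes are
reachable), i.i.d. per-gene noise (sd 0.1), replicate controls scattered
(sd 0.1) around each control profile with shared batch/bead identifiers,
and Bernoulli labels from a logistic rule on `[z1, z2 - z1]` (gain 3 by
default; the rule can be restricted to the baseline or difference block).
AAC is an affine map of the logistic score into [0.05, 0.95], so waterfall
binarization recovers the labels when the label signal is strong.  Default
cohort sizes (8 perturbed cell lines x 2 pairs, 60 viability-only cell
lines, 3 replicates per control, 4 batches) mirror the small-drug end of
the real cohorts; `n_genes` defaults to 100 and scales to the 973 landmark
genes.  `make_sweep` varies effect scale and perturbed-cell-line count on
a grid with deterministic per-point seeds and an optionally shared decoder.

What the generator does *not* emulate: bead-level deconvolution artifacts,
dose-response curve shapes, realistic batch-effect structure, or
gene-gene correlation beyond the low-rank latent map.  Passing tests
therefore show correctness and sample-efficiency of the machinery on data
from (or near) the model family, not performance on real screens.

## Problem sizes used by the tests and the acceptance script

Simulation-based checks are scaled to desk size as the package's own
experiment design: parameter recovery uses 2 true latent dimensions, 20
genes, 1000 pairs at gene noise 0.02 and 150 epochs (the learned
perturbation reduces post-treatment RMSE to ~5-10% of the identity
baseline; the configured success margin is a ratio below 0.8); the
signal/size sweep uses a 3x3 grid of effect scale {0.5, 1, 2} x perturbed
cell lines {8, 16, 32} with held-out-cell-line ΔRMSE, correlated against
realized ERVR x NCL.  ELBO bound checks average 1e4 single-sample
estimates on 1-gene, 1-latent models against 1201-point trapezoid
quadrature on [-14, 14].  Closed-form KL is checked against 1e5-sample
Monte Carlo; gradients against central finite differences (h = 1e-5) at
relative tolerance 1e-3.

## Known limitations

* One noise draw per expectation during training; no importance-weighted
  or multi-sample bounds.
* The classifier and perturbation are linear by design; deeper variants
  and flow posteriors are intentionally out of scope.
* Training on CPU with autograd is adequate for the desk-scale problems
  here but not for 973-gene, hundred-latent production fits.
* The ERVR reconstruction and the waterfall branch rule are documented
  package conventions, not verified replicas of the upstream definitions.
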