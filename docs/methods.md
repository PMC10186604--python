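# Methods

## The problem setting

Untargeted LC–MS screening yields a samples × features table of peak
intensities (features named `M<mz>T<rt>` by mass-to-charge and retention
time). In routine screening archives there are no pooled QC samples and no
controlled collection, so the table carries strong technical structure:
per-sample multiplicative dilution, per-batch multiplicative offsets that can
dominate total variance, and batch-wise missingness. The task is to regress a
phenotype — age in years — on such a table, and to identify which features
carry the signal.

## The ratio network

The regression model makes itself robust to per-sample scale instead of
relying on an external normalization:

1. **Compression layer.** A linear map from the p input features to
   `n_compress = 12` nodes; no activation, no normalization. Each node is a
   learned linear score over the metabolome (e.g. an age score, a baseline
   score).
2. **Ratio layer.** All unique pairwise quotients of the 12 nodes, in
   lexicographic pair order; width n(n−1)/2 = 66. A quotient of two linear
   scores cancels any factor common to both, so a sample's dilution drops out
   of every ratio whose numerator and denominator scale together.
3. **Dense head.** BatchNorm + ReLU on the ratios, then two hidden linear
   layers of 33 units (each BatchNorm + ReLU + dropout) and a single linear
   output node.

Training: mini-batch Adam (β = 0.9/0.999), MSE loss, learning rate 3e-4,
batch size 500, 1000 epochs, dropout 0.1, per-layer L2 weight decay
(0.5 on the compression weights, 0.1 and 0.01 on the hidden layers, 0 on the
output). The large first-layer decay pushes the compression weights toward
dense, small-magnitude scores, which stabilizes the ratios. The ensemble
estimator refits this architecture K times (default 25 at desk scale;
configurable into the hundreds) from seeds derived deterministically from one
base seed, and averages the per-sample predictions; the member spread gives a
standard error.

Everything is implemented in numpy with hand-written backpropagation (linear,
batch-norm, dropout, ratio layers; Adam with per-parameter-group decay), so
fits are bit-reproducible from the seed on a fixed platform.

### Numerical choices

* **Division stabilization.** Denominators are replaced by
  `sign(d)·max(|d|, ε)` with `ratio_epsilon = 1e-6` by default (sign(0)
  treated as +1). With ε = 0 and `first_layer_bias=False` the
  pre-normalization ratio activations are exactly scale-invariant — that mode
  exists for verification; the default keeps the offset and ε > 0 for
  training stability. The clamp's derivative is taken as 0 inside the
  clamped region.
* **Batch normalization** uses mini-batch statistics during training
  (running estimates updated with momentum 0.1, unbiased variance) and the
  frozen running statistics at prediction, so prediction is deterministic and
  order-invariant.
* **Weight decay** is added to the gradient (coupled L2) and applied to
  weight matrices only, not to offsets or batch-norm parameters.
* **Target centering.** The training target is centered at the training-mean
  age, stored as an additive output offset. Without it, reaching the ~29-year
  output scale through a 3e-4 learning rate consumes most of a short training
  budget; with it the optimizer only learns deviations. Predictions are
  returned on the original year scale.
* **Checkpoint policy** defaults to the final epoch (training is run long
  enough to converge); `best_dev` keeps the parameters from the epoch with
  the lowest development loss instead. The development partition never
  contributes gradients.
* **Dropout placement.** Dropout acts on the input features and after each
  post-ratio hidden activation. It is deliberately *not* applied between the
  compression and ratio layers: zeroing a compression node would put a zero
  in 11 denominators.
* **Desk-scale training.** The validation experiments (`ratioage.validation`)
  train with 200 epochs of batches of 100 on ~800 training samples, keeping
  gradient steps per sample comparable to the full-scale recipe
  (1000 epochs × batches of 500 on ~8000 samples).

### The dense control

`build_dense_net` replaces the ratio layer with a plain linear 12 → 66 layer,
leaving widths, normalization, dropout and training identical. The comparison
between the two on diluted, unnormalized cohorts isolates what the ratio
operation itself contributes (`validation.dilution_advantage`).

## Preprocessing

Order of operations: fourth-root transform → sex filter → PCA sample-outlier
removal → batch-missingness filter → robust-subset selection and row
normalization (when used; the network itself runs on unnormalized fourth-root
data). All rank computations use average ranks; all quantiles use linear
interpolation between order statistics.

* **Fourth root** stabilizes variance across intensities spanning orders of
  magnitude; it is monotone, so rank-based stages are unaffected.
* **Batch-missingness filter** removes a feature iff its missing fraction
  *strictly* exceeds 20 % in at least one batch.
* **PCA outliers.** A sample is removed when, on any of the first 12
  component score vectors, its absolute deviation from the component median
  exceeds 1.5 × the 95th percentile of those absolute deviations. The rule is
  single-pass (survivors are not re-screened). An alternative reading —
  quantile of the raw scores instead of the deviations — is exposed via
  `deviation_quantile=False`; the deviation reading is the default because a
  threshold "away from the median" is naturally a quantile of distances.
* **Robust subset.** Features are rank-stable anchors if their median
  within-sample rank lies within the [20 %, 80 %] quantiles of all features'
  median ranks *and* their max−min rank range lies within the same quantiles
  of all ranges (bounds inclusive). With all features tied everywhere, every
  feature sits exactly on both bounds and all are selected — a deterministic
  degenerate-tie policy.
* **Row normalization** divides each sample by its robust-subset sum; it
  cancels per-sample positive scaling exactly and errors (naming the sample)
  on a zero divisor.
* **Quantile normalization** forces each sample's sorted vector onto the mean
  sorted vector, averaging ties; it requires complete data, is idempotent,
  and preserves within-sample order.
* **Imputation** (for PCA, learners and the network) fills missing entries
  with the per-feature per-batch minimum observed value (half-minimum
  optional), falling back to the global per-feature minimum for batches with
  no observation.
* **Split**: random 80/10/10 train/development/test partition, sizes within
  one sample of the targets, reproducible from the seed.

## Attribution

Shapley values are estimated model-agnostically. For ≤ 12 features the exact
subset enumeration is used (2^p coalition evaluations, averaged over the full
background). Above that, antithetic permutation sampling: each sampled feature
ordering is walked forwards and backwards, switching one feature at a time
from background to sample value, with the model output averaged over the full
background at each step. The telescoping sum makes additivity
(baseline + row sum = prediction) exact for any number of permutations; more
permutations only reduce the variance of the per-feature split. The background
is a seeded random subsample of training data (default 100 samples) and
attributions are computed on test-partition samples. Because the estimator is
linear in the model, averaging per-member matrices (computed with shared
permutations) equals attributing the ensemble mean.

Global importance is the per-feature variance (denominator n−1) of the
ensemble-averaged attribution column. Concordance compares, per feature, the
sign of Spearman(attribution, intensity) with the sign of
Spearman(intensity, age): agreement means the model reads the feature the way
the raw trend points; disagreement flags an inverse reading (interaction or
normalizing role); |ρ| < 0.1 is labelled "weak" and constant features
"incomputable" rather than silently dropped.

## Univariate screen

Per feature, tie-corrected Spearman ρ against age with missing values
pairwise-excluded. p-values use the t approximation
t = ρ√((n−2)/(1−ρ²)) for n ≥ 10 and the exact rank-permutation null below
that. Multiplicity is controlled with the Benjamini–Hochberg step-up computed
over the features with a computable p-value. Age-decile profiles bin samples
into ten equal-count age bins, take per-feature decile means, standardize them
across deciles (denominator n−1), and order features by average-linkage
hierarchical clustering for display.

## The synthetic generator

The generator produces cohorts with the statistical structure of routine
screening data, with every stochastic component driven by its own child
stream of one seed (so switching one component off leaves all others
bit-identical):

* **Ages**: shifted lognormal, `age = 15 + LogNormal(μ, σ)` truncated to
  [15, 95] by resampling, with (μ, σ) solved in closed form to hit the target
  mean 28.9 y and SD 9.2 y of the remainder above the 15-year shift. The
  result is right-skewed (skewness ≈ 1) with a dense 21–29 y core; the
  `age_skew` knob scales σ for sensitivity checks (≠ 1 trades off the moment
  match).
* **Intensities**: `log x = log b_j + β_j·z + e`, with baselines `b_j`
  lognormal around 1e5 spanning ~3 orders of magnitude, z the standardized
  age, and e Gaussian log-noise (SD 0.5). Informative features get a nonzero
  β whose sign comes from the planted truth and whose magnitude is solved
  from the target Spearman ρ via the Gaussian-copula relation
  ρ_S = (6/π)·asin(r/2) — multiplicative biology that survives the
  fourth-root/ratio treatment downstream.
* **Technical effects**: per-sample lognormal dilution with mean 1 and CV
  `dilution_cv` (default 0.3); per-(batch, feature) lognormal offsets with
  log-SD `batch_shift_sd` (default 0.5, enough for batch structure to
  dominate the leading PCA components); batches are contiguous acquisition
  blocks.
* **Missingness**: missing completely at random per (feature, batch) with a
  rate drawn uniformly from `missing_rate_range` (default 0–10 %), encoded as
  NaN — explicitly distinct from zero.

Defaults (1000 samples, 300 features, 20 batches, 20 informative features
with |ρ| targets 0.3–0.6, 30 % of them negative) are the benchmark study
conditions. The paper-scale archive is two orders of magnitude larger; the
defaults are chosen to stress the method, not to reproduce any specific
cohort's numbers.

**What the generator does not emulate** — and hence what passing tests do not
show about real data: retention-time drift at the peak level (batch structure
is purely multiplicative), correlated feature blocks (adducts, isotopes,
in-source fragments of one metabolite), age-correlated *confounders*
(demography, medication), heteroscedastic detector noise, and
intensity-dependent (non-random) missingness. Recovery rates on synthetic
cohorts are an upper bound on what identical settings would achieve on
instrument data.

## Known limitations

* The ratio-vs-dense comparison has limited statistical power at desk scale:
  with moderate dilution (CV 0.3, further compressed by the fourth-root
  transform to ~0.075 on the modelled scale) the per-seed RMSE difference is
  small relative to seed-to-seed spread. The advantage becomes systematic as
  dilution grows and in the exact-invariance mode (`first_layer_bias=False`,
  `ratio_epsilon=0`), where the cancellation is algebraic rather than
  approximate.

* Training the ensemble is CPU-bound numpy; paper-scale runs (K in the
  hundreds, 10⁴ samples) are hours, not minutes.
* The permutation Shapley estimator's per-feature split (not its additivity)
  depends on the permutation budget; ranks of closely scored features can
  swap between seeds. Absolute attribution scales depend on the background
  choice; only ranks and signs should be interpreted.
* BH control of the univariate screen assumes the per-feature tests' null
  p-values are valid; with n < 10 samples the exact permutation p-values are
  discrete and conservative.
* The screening harness treats learners as black boxes with a deliberately
  small tuning grid (5 candidates per hyperparameter); its grid is indicative,
  not a tuned benchmark.
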