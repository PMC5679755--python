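# Methods

`mirsig` implements the development protocol for a serum circulating-miRNA
diagnostic classifier of invasive epithelial ovarian cancer: small-RNA
read counts are normalized to tags per million (TPM), batch-adjusted,
filtered, and split; three variable-selection strategies feed a
multilayer-perceptron restart search and a zoo of baseline classifiers;
the winning signature is recalibrated to RT-qPCR delta-Cq inputs and
pruned by global sensitivity analysis; performance is judged by
nonparametric ROC inference. Because the original serum cohorts are not
shipped with the package, every stage is exercised on synthetic cohorts
with planted ground truth, so that recovery of the truth — not
reproduction of any particular study's numbers — is what the test suite
certifies.

## Outcome definition

Samples are labelled by pathology stratum (healthy control, benign lesion,
borderline tumor, stage I/II invasive, stage III/IV invasive). The
diagnostic target is binary: invasive cancer (stage I/II or III/IV) versus
everything else. Borderline tumors are clinically indolent and are grouped
with the non-invasive class. A predicted probability strictly greater than
0.5 calls invasive cancer.

## Synthetic cohort model

`generate_counts` draws negative-binomial read counts with

```
log10 E[TPM_fs] = baseline_f + classEffect_fs + m_f * shift_b(s)
E[count_fs]     = 10^log10TPM / 1e6 * librarySize_s
Var[count]      = mu + dispersion * mu^2
```

* `baseline_f ~ U(0, 3)` log10-TPM — a skewed abundance distribution in
  which roughly a third of miRNAs fall below the 10-TPM detection
  threshold, as in serum small-RNA data.
* A planted signature (default 14 miRNAs, drawn from the mid-abundance
  window) carries a class effect in invasive samples only: half
  up-regulated with linear fold change drawn from (2, 3), half
  down-regulated from (1/3, 1/2). The ranges must avoid the (0.8, 1.2)
  null band so a planted feature is selectable by construction.
* Batch effects are additive on the log10 scale with feature-specific
  multipliers `m_f ~ N(1, 0.3)` and batch shifts `shift_b ~ N(0, 0.15)` —
  the location/scale structure the batch-adjustment step assumes.
* Nine stable reference miRNAs (high abundance, quarter dispersion, zero
  class and batch effect) are planted for the reference-gene machinery.
* Defaults: 180 samples, 1,500 features, 3 batches, class mix
  15:45:21:53:45 over the five strata (the composition of a 179-subject
  discovery population), library size U(5e6, 15e6) reads — roughly the
  10M reads/sample of serum small-RNA sequencing.
* Dispersion defaults to 0.2; overdispersion is ubiquitous in small-RNA
  counts, which is why the model is negative binomial rather than Poisson.

CA125 is simulated lognormal with the invasive-class location shift solved
from the binormal identity `AUC = Phi(delta / sqrt 2)`; the default target
AUC is 0.74, a deliberately mediocre comparator. Benign, borderline and
control samples share one distribution.

The qPCR generator measures linear TPM as
`Cq = 38 - log2(TPM + 1) + N(0, 0.3)` (reference assays: sd 0.1), marks
reactions above 37 cycles undetected, and populates QC annotations
(amplification efficiency, melt flag, per-assay negative-control Cq) so
that configurable fractions of reactions violate each downstream QC rule
in disjoint cells; the generator reports the exact expected removal counts
so the filter can be checked cell-for-cell.

What the generator does **not** emulate: read-level structure (adapters,
UMIs, isomiRs), replicate measurements, compositional coupling between
features, heavy-tailed library-size failures, and assay-specific qPCR
efficiencies entering the Cq slope. Passing tests therefore demonstrate
that the pipeline recovers planted structure under its own model
assumptions, not that it would perform identically on real sera.

## Preprocessing

* **TPM**: counts / total mapped reads x 1e6 (linear scale). Zero library
  sizes are an error naming the sample.
* **Prevalence filter**: keep miRNAs with TPM >= 10 in at least 50% of
  samples of *every* dataset (dataset = study batch). The boundary is
  inclusive (>= 10 counts as detected).
* **Log transform**: log10(TPM + 1). The +1 pseudocount anchors zero and
  is applied exactly once; double transformation is refused.
* **Batch adjustment**: parametric empirical-Bayes location/scale
  adjustment on the log scale with no outcome covariate. Per feature the
  data are standardized against the library-weighted grand mean and pooled
  variance; per-batch location (normal prior) and scale (inverse-gamma
  prior, moment-matched) effects are shrunk by the iterative
  conditional-posterior solution and removed. Two numerical choices are
  documented rather than silent: constant features pass through unchanged
  with a warning, and each feature is re-centred on its original grand
  mean after back-transformation (EB shrinkage would otherwise leave a
  sub-1e-3 offset). Because shrinkage leaves a residual of the order of
  the batch-mean sampling noise, a second application still moves values
  by a few percent of the data spread — the adjustment is only
  approximately idempotent, and the test suite asserts exactly that.
  Running adjustment without an outcome covariate can attenuate group
  signal when strata are unbalanced across batches; the simulated cohorts
  assign batches independently of class, which mitigates this by design.
* **Split**: stratified randomization by pathology class at ratio 0.75
  (135/45 at the default cohort size), seed-reproducible, with a
  per-stratum count report. Strata smaller than two samples go wholly to
  training with a warning.

## Variable selection

* **Significance filter**: per-miRNA Welch t-test (unequal variances — the
  safer default when only "t-test" is specified) of invasive vs rest on
  pooled post-adjustment log expression, Benjamini-Hochberg adjustment,
  keep p < 0.05 AND q < 0.05.
* **Fold-change filter**: linear fold change of arithmetic mean TPM
  (invasive / non-invasive) computed within each batch-dataset on
  unadjusted TPM; keep miRNAs with FC < 0.8 in every dataset or FC > 1.2
  in every dataset (strict inequalities; FC exactly 1.2 is excluded).
  Features with a zero non-invasive mean are skipped with a warning.
* **CFS**: correlation-based feature-subset selection maximizing
  `M(S) = k r_cf / sqrt(k + k(k-1) r_ff)` where `r_cf` is the mean
  absolute feature-class correlation and `r_ff` the mean absolute
  feature-feature correlation of the subset. The original formulation
  discretizes continuous attributes; here the point-biserial correlation
  magnitude is used directly — simpler and deterministic. Search is
  best-first forward from the empty set, terminating after 5 consecutive
  non-improving expansions; ties break by feature index; constant features
  have correlation 0 by convention.
* **Reference-gene stability**: per-feature decomposition into intra-group
  variance (after removing per-sample loading effects) and inter-group
  difference, the latter shrunk by `gamma^2 / (gamma^2 + sigma^2/n)` with
  `gamma^2` the across-feature variance of group differences; stability is
  the mean over groups of |shrunken difference| plus its posterior SE
  (lower = more stable). The ranking is invariant to per-feature location
  shifts and to per-sample global shifts. Note the method attributes
  group-level shifts common to all features to loading, so a constant
  feature has exactly zero stability only when the panel as a whole
  carries no group effect.

## The neural-network search

A single-hidden-layer perceptron on per-feature standardized inputs
(train-set mean/SD; required for stable quasi-Newton optimization). Per
restart the architecture is sampled: hidden size uniform on
`[ceil(n/3), ceil(1.5 n)]` for n inputs (ceilings, since no rounding rule
is inherent in the bound), hidden and output link functions independently
uniform on {linear, logistic, tanh, exponential}. Weights are fitted by
BFGS on the exact back-propagated gradient; the loss is cross-entropy for
a logistic output and squared error otherwise, plus an L2 penalty of 1e-3
which bounds the otherwise divergent separable-data optimum. Convergence:
max-norm gradient < 1e-6 or 500 iterations. The BFGS loop is implemented
natively (dense inverse-Hessian update, Armijo backtracking, update
skipped when the curvature condition fails) because the generic
library optimizer's per-iteration overhead dominates at this problem size.
Exponential activations clip their argument at +-30; non-logistic outputs
are clipped into [0, 1] to honour the probability contract.

Across restarts the network with the best selection-set AUC is retained;
ties break toward the smaller hidden layer, then the earlier restart.
Restart r derives its RNG from (seed, r), so enlarging the restart budget
extends, rather than reshuffles, the search — the retained AUC is
non-decreasing in the number of restarts.

**Selection policy.** The historical protocol retains the network that
performs best on the *test* set; that leaks the test set into model
choice, so the default here is an internal validation split (25% of
training, stratified) for retention, with the test set reserved for
reporting. The leaky policy remains available as
`selection_policy="test_set"` so the optimism of test-set
selection can itself be measured. Default restart budget is 200 (minutes
on one core at the default cohort size); the full-scale budget of 5,000
is available via `mirsig run-all --full-scale`.

**Sensitivity pruning.** Feature sensitivity is the ratio of the
selection-set error (1 - AUC) with that feature replaced by its training
mean to the full-model error. The minimum-sensitivity feature is dropped,
the network retrained by a fresh, smaller search on the reduced set
(60 restarts in the pipeline default — a skimpier retraining budget makes
the acceptance decision noisy and can stall pruning early), and the step
accepted while the selection AUC stays
within the tolerance (default 0.05) of the incumbent best; a failing step
is reverted and pruning stops. On redundant planted signatures with a
reasonably sized selection set this typically halves a 14-miRNA input set
without measurable AUC loss. The accept/reject decision compares AUCs on
the selection set, so with a small selection set (a few dozen samples,
where one AUC standard error approaches the tolerance) pruning is
noise-limited and can stop early; the shipped pruning check therefore uses
a 240-sample cohort with a dedicated selection split.

## Baseline classifiers

All trained on log expression of the selected features with fixed
hyperparameters: backward-stepwise LDA retaining variables with partial
F >= 5 (for two groups the partial F equals the squared OLS t statistic of
the group indicator regression, which is how it is computed); backward
stepwise logistic regression at p < 0.15 including second-order
interactions when the term budget allows (terms <= n/3, to avoid fitting
more parameters than a third of the sample); Gaussian naive Bayes with
empirical priors; an SVM grid over linear, polynomial (2nd/3rd) and RBF
kernels with gamma 0.1–1.0 in 0.1 steps, chosen by training AUC; elastic
net as classification-via-regression with mixing parameter 0.001 (the two
per-class regressions have equal and opposite coefficients by symmetry);
and a 100-tree random forest considering `int(1 + log2 p)` features per
split. Stepwise procedures are native; base learners delegate to
scikit-learn/statsmodels. Omitted baselines (MARS, LAD tree, functional
tree, K2 Bayesian network) are out of scope by design.

## Evaluation

* **AUC** by the tie-corrected Mann-Whitney identity (ties count 1/2);
  variance, 95% CI and the paired two-marker comparison by the DeLong
  structural-components method.
* **Youden cutoff**: argmax of sensitivity + specificity - 1 over the
  threshold sweep; ties resolve toward higher specificity (a screening
  context favours fewer false positives).
* **Confusion reporting** at the strict p > 0.5 rule, with exact fractions
  and 1-dp percentages rounded half away from zero (so 23/120 prints as
  19.2%).
* **Fisher's exact test**, two-sided by the probability-mass convention
  (sum of tables no more probable than the observed one). Note: for the
  2x2 comparisons this package was validated against, continuity-corrected
  chi-square gives visibly different 3-decimal roundings than the exact
  test; the exact convention is used throughout.
* **Tiered screening**: combined call = primary positive OR secondary
  positive among primary negatives. Tiered sensitivity can only rise and
  specificity only fall relative to the primary test — the report shows
  both confusions and the deltas.
* **Wilcoxon matched-pairs signed-rank**: zero differences dropped; exact
  null distribution by convolution over sign assignments (midranks
  doubled to stay integral) for n <= 25, normal approximation with tie
  correction above.
* **Sample size for AUC superiority**: smallest per-arm n with
  `z_{alpha/2} sqrt(V0) + z_power sqrt(V1) <= AUC_alt - AUC_null` using
  Hanley-McNeil variances at the null and alternative; an optional
  comparator correlation r reduces the difference variance by
  `2 r sqrt(V V')`. The returned total also applies the 3x training
  multiplier. Published study sizes computed with other variance
  approximations will differ; the Monte-Carlo check in the test suite
  validates this variant against direct binormal simulation.

## qPCR bridge

QC removes reactions in rule order — melt-curve flag, amplification
efficiency < 1.6 (strict), Cq within 5 cycles of the assay's negative
control — logging counts per rule. Undetected reactions are imputed at the
37-cycle floor, and detected Cqs above 37 are clamped to it (extending the
imputation rule keeps the abundance map monotone). Two delta-Cq
normalizations are provided, both with the sign convention
`dCq = reference - target` (higher = more abundant): per-sample global
mean over universally detected assays, and the mean of a two-assay
reference pair chosen by the stability ranking. Recalibration is a fresh
restart search on the signature's delta-Cq features; external platforms
(e.g. microarray) are bridged by z-scoring each signature feature against
the external cohort and re-expressing it on the model's training scale,
which preserves within-feature rank order and hence ROC ordering under
per-feature affine platform differences.

## Numerical and edge-case conventions

Seeds propagate explicitly: the pipeline seed derives the split, search,
Cq-generation and pruning seeds; identical configuration reproduces the
report bundle bit-for-bit. Degenerate cases are errors, not silences: a
class or batch below its minimum size, an empty dataset list, a missing
model feature (named in the exception), probabilities outside [0, 1],
negative contingency cells, a signature with fewer than two assays on the
qPCR platform. Models serialize to portable JSON; reloaded networks
reproduce predictions bit-identically.

## Problem sizes used by the shipped checks

The test suite and `scripts/acceptance.py` run the protocol at the default
cohort size (180 x 1,500, 3 batches) with a 200-restart search budget,
5-seed medians for the recovery and pruning properties, a 240-sample
cohort for the pruning protocol (so the held-out third of the data is
large enough for stable AUC estimates), 1,000 simulations for CI coverage,
and exhaustive enumeration for the exact-test oracles. These sizes were
chosen so the full protocol demonstrates its properties at desk scale; the
search budget and cohort size scale up by configuration
(`restarts=5000`, `SimulationConfig(...)`) without code changes.

## Known limitations

* The synthetic generator's fidelity limits what green tests prove about
  real serum cohorts (see above); in particular the planted signature is
  conditionally independent given class, which flatters all selectors.
* The stepwise logistic baseline falls back to a ridge-regularized fit
  under complete separation and then stops eliminating, which can retain
  more terms than a cleaner dataset would.
* Reference-gene stability values are comparable within a panel, not
  across panels; only the ranking is used.
* The batch adjustment assumes the location/scale model; batch-by-class
  interactions are neither simulated nor corrected.
* Baseline models other than the network are not serialized to the
  portable model format.
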