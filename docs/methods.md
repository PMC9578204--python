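# Methods

## The question

Given a binary-outcome study with N samples and a classifier, two
resampling estimators of predictive accuracy are compared:

* **Exhaustive leave-t-out CV.** One balanced k-fold partition is drawn;
  every unordered choice of t folds serves once as the test set, giving
  C(k, t) rounds. Defaults k=10, t=2 → 45 rounds, train on 8 folds (80%),
  test on 2 (20%).
* **MCCV.** S splits are drawn independently; each takes a uniform random
  ⌊0.8·N⌋-subset (without replacement) as training data. For a paired
  comparison S defaults to C(k, t) so both arms evaluate the same number
  of splits at the same train/test sizes.

The estimand is the same in both arms — the expected test accuracy of a
model trained on an 80% subsample — but the two estimators differ in how
their splits are correlated: CV rounds share the folds of a single
partition, MCCV splits are independent. The experiment measures whether
this matters in practice.

## Paired experiment design

Each of `n_outer_sims` outer simulations draws a fresh data realization
(from the generator, or a random subsample of a supplied CSV pool — the
protocol used for real cohorts, e.g. 150-row subsamples drawn 100 times).
Both arms evaluate every registered classifier on that same realization;
the per-arm mean of each metric across splits is one paired observation.
Across simulations we report, per method and metric:

* d = mean(MCCV arm) − mean(CV arm);
* two-sided paired t-test, t = d̄·√n / s_d, plus the Wilcoxon signed-rank
  test as the non-parametric fallback;
* Shapiro–Wilk and D'Agostino (skewness/kurtosis) normality tests on the
  paired differences; D'Agostino needs n ≥ 8 and is reported as missing
  below that;
* classic mean-centred Levene test of equal variance between arms;
* per-arm means and sample SDs (n−1 denominator).

No multiple-testing correction is applied across methods; the per-method
p-values are reported as-is and should be read descriptively.

With unstratified splits in both arms, the marginal distribution of a
single train set is identical between arms (a uniform random 80%-subset),
so E[d] = 0 by symmetry; the directional checks in the test suite are
therefore stochastic statements about small-sample fluctuation at a fixed
seed, not about a systematic advantage. A `stratify` flag is available in
the resampling layer for outcome-stratified folds and splits, but is off
by default; enabling it in one arm only is the main mechanism by which a
systematic d ≠ 0 can arise in practice.

Degenerate splits (training set containing a single outcome class) cannot
be fit by most classifiers; they are dropped from the affected arm's mean
and logged. If more than 10% of an arm's splits are dropped (configurable),
that (simulation, method) pair is excluded entirely with a warning, keeping
the pairing aligned.

### Edge cases in the summary

* All paired differences exactly zero → t = 0, p = 1 (flagged).
* Constant non-zero difference (s_d = 0, detected up to float rounding) →
  t reported as ±∞ with p = 0 and a `constant_difference` flag.
* Constant arms → Levene undefined, reported as NaN with a flag.

## Synthetic data generator

The generator emulates a screening-study feature table. Defaults follow
the study design the package reproduces:

| parameter | default | meaning |
|---|---|---|
| n_features | 20 | 1 signal normal (σ=2) + 11 nuisance normals (σ ~ U(0.5, 20)) + 4 bounded counts (Binomial(m, p), m ~ U{3..8}, p ~ U(0.1, 0.9)) + 4 binaries (p ~ U(0.1, 0.9)) |
| β₀ | −1.6 | logistic intercept; with β₁=0.1, σ=2 the implied prevalence is ≈ 0.17 |
| β₁ | 0.1 | slope on the signal feature; 0.001 ≈ no signal, 0.05 weak |

The outcome is Y ~ Bernoulli(expit(β₀ + β₁x₁)). The "multinomial"-style
bounded-count features are implemented as Binomial(m, p) on integer support
0..m, since a categorical law with a single probability parameter is not
well defined. With fewer than 20 features the composition truncates in the
order signal → normals → counts → binaries (so the 20-feature design is
nested); above 20 the extra slots are further nuisance normals.

Feature-spec parameters (σ_k, m, p) are drawn once per `GeneratorConfig`
and held fixed across that config's simulations; feature values and
outcomes are redrawn each simulation. This reads "repeated simulations of
one stated design" literally and keeps the design constant within an
experiment.

What the generator does **not** emulate: feature correlation (all columns
are independent), missing data, measurement error, or continuous outcomes.
Passing tests on this generator demonstrate the resampling comparison
machinery, not classifier performance on any real cohort.

`expected_prevalence(beta0, beta1, sigma)` computes E[expit(β₀+β₁X)] for
X ~ N(0, σ) by adaptive quadrature (absolute tolerance < 1e−6) and serves
as the independent oracle for prevalence-recovery tests.

## Classifier registry

Methods are small named wrappers over scikit-learn estimators: `lda`,
`glm` (unpenalized logistic regression), `bayes` (Gaussian naive Bayes),
`knn`, `tree` (CART), `rf`, `svm_linear`, `sgb` (stochastic gradient
boosting, subsample 0.8), plus optional `cart` (bagged trees) and
`svm_poly`. Tuning grids are deliberately small and identical across both
resampling arms so the comparison is fair:

* knn: n_neighbors ∈ {5, 7, 9}
* tree: ccp_alpha ∈ {0, 0.01, 0.05}
* svm_linear: C ∈ {0.25, 0.5, 1}
* svm_poly: degree ∈ {2, 3}
* sgb: n_estimators ∈ {50, 100} × max_depth ∈ {1, 2}

Selection uses a nested inner 10-fold CV on the training rows only, scored
by accuracy, ties broken by the smallest grid index; the winner is refit on
the full training rows. Methods without a grid skip the inner CV. Inner
folds that end up single-class are skipped in scoring; if no inner fold is
usable the first grid entry is used. Probabilistic methods classify at the
0.5 threshold (sklearn's `predict`). Count/binary features enter as
numeric codes without one-hot expansion, matching the generator's
encoding. Stochastic estimators (rf, sgb, cart, tree) receive a seed
derived from the experiment's hierarchical stream, so runs are exactly
reproducible.

## Stabilization in S

`run_stability` estimates the Monte Carlo noise of the MCCV accuracy
estimate as a function of S: for each replicate a fresh data realization is
drawn and one long split stream of max(S) splits is evaluated; the
estimate at each smaller S is the mean over the first S splits (prefix
sharing — so the S-comparison isolates the number of simulations rather
than fresh split noise). The spread at each S is the sample SD of the
replicate estimates.

Because each replicate also redraws the data, the spread contains a
data-realization component that does not shrink with S; the decline from
small to large S reflects the Monte-Carlo split component only. Default 20
replicates. The practical rule encoded by `recommend_S` is S = 3000 for
N < 300 and S = 2000 for N ≥ 300 (boundary at 300 inclusive in the second
branch); for very small N (≈100) consistency can require S up to ≈5000.

## Numerical and design choices

* Fold sizes differ by at most one; the remainder goes to the lowest fold
  labels after shuffling. Leave-t-out rounds are ordered lexicographically
  by test-fold labels, so result tables are reproducible without storing
  plans. Train size is ⌊train_fraction·N⌋ with a 1e−9 epsilon guarding the
  floor against float error.
* All randomness flows from one master seed through
  `SeedSequence(master, spawn_key=(purpose, sim, ...))` child streams;
  evaluation order cannot change any result. Integer seeds handed to
  sklearn are reduced below 2³¹.
* F1 uses positive label 1 with the 0/0 → 0 convention; accuracy and F1
  are computed per split and macro-averaged over a plan's splits.
* Serialized split plans are JSON with an explicit `"index_base": 0` field.

## Problem sizes in the test suite

The suite runs the paired experiment at N=200 with 30 outer simulations
and 4 fast methods, and the stabilization study at N=100 with S ∈ {50,
800} and 20 replicates — large enough for the directional and shrinkage
properties to be visible, small enough for a desk-scale run. Larger sweeps
(N up to 1200, S up to 12,000, the full method registry) are available
through the same APIs and the CLI.

## Known limitations

* LVQ and boosted logistic regression are not in the registry (no
  canonical scikit-learn equivalents); the comparison question does not
  depend on any particular method list.
* The directional d-checks are stochastic at a fixed seed; with
  unstratified arms the expected d is 0 (see above), so individual seeds
  can produce small negative d for some methods.
* CSV pools are subsampled uniformly without replacement per simulation;
  no grouped, blocked or time-series resampling is provided.
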