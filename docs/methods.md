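# Methods

This note documents the statistical procedures implemented in `housenet`,
the assumptions behind them, the defaults and why they were chosen, and
what the synthetic-data experiments do and do not demonstrate.

## Cohort model and roles

The analysis table holds one row per participant and nine variables: six
housing-quality indicator scores (role `housing`), a depressive-symptom
total (role `outcome`; an integer 0–30 from a 10-item inventory scored
0–3), and two covariates (role `covariate`): an SES-adversity composite
and age in years. Missing cells are NaN; downstream statistics never see a
masked value.

## Inclusion and missing data

* **Inclusion rule.** A participant enters the analysis cohort iff at least
  a fraction `min_complete_fraction` (default **0.5**) of the six housing
  items is observed. Only housing columns drive retention. The filter is
  idempotent.
* **MAR diagnostics.** Included and excluded participants are compared on
  fully observed covariates: group means, standardized mean difference
  (included − excluded over pooled SD), Welch t test. `bias_indicated` is
  raised when any |SMD| > 0.1 (a conventional imbalance threshold).
  This diagnoses *observable* selection bias; truly MNAR mechanisms are
  indistinguishable from MAR on these diagnostics.
* **Imputation.** Chained equations with predictive mean matching for every
  variable: missing cells are initialized from the observed marginal, then
  columns are revisited in fixed left-to-right order, each regressed (OLS,
  intercept) on all other current columns, and refilled from a donor pool
  of the **5** observed rows with the nearest predictions. Defaults:
  **m = 5** imputations, **10** iterations — conventional chained-equations
  settings. PMM is used uniformly because donor-based draws automatically
  respect bounds and ordinal support; its cost is that an imputed value
  carries the donor's own conditional noise (error scale √2 × residual SD),
  which is the correct behaviour for preserving distributions but means
  single imputed values are not conditional-mean predictions.

## Selection model and stabilized weights

A binary selection indicator S (1 = all housing items complete at baseline;
derivable from the pre-imputation mask when not supplied) is modelled by
maximum-likelihood logistic regression on age and SES risk. Stabilized
weights are `w_i = mean(S) / P̂(S=1|x_i)`. Two application modes exist
because the analysis sample (≥50% complete, imputed) is wider than the
S = 1 subsample:

* `analyzed` (default): every analyzed row gets the stabilized formula at
  its own covariates — coherent with weighting the imputed analysis sample;
* `selected`: rows with S = 0 get weight 0 and drop out of weighted
  statistics — the strict IPW reading.

No weight truncation is applied by default; symmetric quantile truncation
is available. A fitted probability ≤ 1e−6 among weighted rows aborts with
advice to truncate. Perfect separation and single-class S are rejected
explicitly.

## Weighted Spearman correlations

Each column is converted to mid-ranks (ties → average rank) computed
*unweighted* on the analyzed rows; each pair's entry is the weighted
Pearson correlation of the two rank vectors (weighted means, variances and
covariance with total weight ΣW). With uniform weights this reduces
exactly to classical Spearman. Weights enter only the Pearson step: this
is the simplest construction that preserves the equal-weights reduction,
at the cost of a second-order bias in the rank transform under strong
selection (the first-order IPW correction dominates in all experiments).
Per-imputation matrices are pooled entry-wise on the Fisher-z scale.
Pooled/weighted rank matrices need not be positive definite, so an
eigenvalue-clipping repair (floor **1e−6**, rescaled to unit diagonal,
iterated; bitwise no-op on PD input) precedes estimation.

## Network estimation (EBICglasso)

`glasso_fit` maximizes `log det κ − tr(R κ) − λ Σ_{i≠j}|κ_ij|` by
Friedman-style block coordinate descent on the covariance, compiled with
numba. Convergence: successive precision estimates differ by < **1e−6**
(max absolute entry); the inner lasso tolerance is 10× tighter (capped at
1e−9). Off-diagonal soft-thresholding yields exact structural zeros. The
solver matches the p = 2 closed form and a generic penalized-likelihood
maximizer at p = 3 to ~1e−7 in the entries, and a 100-penalty 9-node path
costs ~5 ms, which is what makes bootstrap re-estimation of the whole path
affordable.

The penalty path is log-spaced over **100** values from λ_max (the largest
off-diagonal |r|, where the model is empty) down to λ_max × **0.01**.
Model selection minimizes `EBIC = −2ℓ + E log n + 4 E γ log p` with
γ = **0.5** (the conventional "moderate/conservative" hyperparameter), and
ties resolve to the larger penalty (sparser model). `n` is the count of
analyzed rows; since stabilized weights average ≈ 1, the effective sample
size is close to n (a Σw-based alternative is configurable). An edge is
"nonzero" when |P_ij| > 1e−10 (float hygiene). Note the lasso active set
is not exactly monotone in λ: on noisy inputs a borderline edge
(|κ| ~ 1e−3) may flicker out as λ decreases; on realistic cohort inputs
the emitted paths are monotone.

## Centralities

On the signed weighted network: expected influence `Σ_j P_ij` (one-step,
signed), strength `Σ_j |P_ij|`, and shortest-path betweenness/closeness
with edge length `1/|P_ij|` (strong edges are short; the standard
psychometric-network convention — the sign is dropped only for distances).
Betweenness is reported unnormalized (raw pair counts); closeness uses the
reachable-set form `|R(i)| / Σ_{j∈R(i)} dist(i,j)`, 0 for isolated nodes.
Raw values are emitted with optional z-scored columns, since conventions
differ on standardization.

## Resampling

* **Edge accuracy.** Nonparametric bootstrap, default **B = 1,000** row
  resamples with replacement; each resample re-runs weights (refitting the
  selection model when S is present, so weight-estimation uncertainty
  propagates) → weighted Spearman → PD repair → the full EBICglasso path.
  Per-edge 95% percentile CIs. Resamples with a zero-variance column are
  redrawn (bounded retries).
* **Edge-difference tests.** Two edges differ at level α (default 0.05)
  iff the empirical (α/2, 1−α/2) interval of the bootstrap distribution of
  their difference excludes 0; no multiplicity correction by default (the
  convention for these tests), Bonferroni optional. Requires ≥ 5/α
  resamples.
* **Centrality stability.** Case-drop bootstrap over drop proportions
  0.05–0.95 in steps of 0.05 (the grid extends beyond the conventional
  0.75 cap so large CS values are representable), **B = 1,000** subsamples
  per proportion by default; Pearson correlation over nodes between
  subsample and full-sample centralities. CS(metric) = the largest grid
  proportion d such that every d′ ≤ d keeps ≥ **95%** of subsamples at
  correlation ≥ **0.7** — the standard correlation-stability convention;
  degenerate subsamples (constant centralities, empty networks) count as
  failures. CS > 0.25 is the usual minimum, CS > 0.5 preferred.

All resampling is bit-reproducible under a fixed seed; the pipeline's run
seed fans out to per-stage seeds through numpy seed sequences keyed by
fixed stage indices, so stages can be re-run in isolation.

## The synthetic cohort: what it does and does not emulate

The generator plants a 9-node precision matrix directly (so partial
correlations — the estimand — are known exactly), draws latent multivariate
normals, and maps each column through a Gaussian copula (probability
integral transform + target quantile function), preserving Spearman
structure up to ordinal ties. Defaults:

* planted edges spanning magnitudes −0.30 … +0.21 — the range such
  networks exhibit in practice — with the strongest negative edge
  size–age, strongest positive edge depressive symptoms–SES risk, and a
  positively connected housing cluster anchored on feelings;
* marginals: housing scores as symmetric beta on 1–5 (the indicator
  scaling is not standardized in the literature; bounded continuous is
  documented as an assumption), depressive total as a right-skewed
  negative-binomial quantile clipped to 0–30 (mean 4.30, SD 3.02), SES
  risk as a small adversity count, age truncated-normal 15–44 (mean 28.36,
  SD 4.67);
* MAR missingness: logistic in standardized drivers (age, SES risk), with
  the intercept calibrated by root-finding to hit the requested overall
  rate (pipeline default 10%);
* selection: logistic in standardized age (−0.5) and SES risk (+0.5) with
  intercept 1.0 (≈70% selected) — strong enough that unweighted selected
  samples are visibly biased.

Pre-missingness values and true selection probabilities are retained as
hidden truth for the test harness only. What passing tests therefore show:
the pipeline recovers a *sparse Gaussian-copula* truth and corrects
*correctly specified logistic* selection. Real cohorts need not be
Gaussian-copula, their true networks need not be sparse (a dense
conditional structure would make every edge nonzero), and real selection
can be misspecified or MNAR — none of which these experiments probe.

## Problem sizes used in validation

Recovery and bootstrap experiments run at the study-scale n = 9,669 (20
seeds for support recovery: pooled sensitivity/specificity ≥ 0.9 at
planted |pcor| ≥ 0.15, sign agreement ≥ 95% at ≥ 0.1); IPW correction at
n = 50,000 (10 seeds); oracle equivalence over 25 random PD inputs × 3
penalties for p ∈ {2, 3}; centrality oracles over 50 random networks of
≤ 6 nodes. The acceptance script uses bootstrap B = 1,000 and case-drop
B = 200 per proportion — the case-drop count is scaled down from 1,000 as
a package choice, since CS is a coarse grid statistic whose Monte-Carlo
error at B = 200 is well below one grid step.

## Known limitations

* Cross-sectional, undirected conditional associations only; no causal or
  longitudinal claims.
* Rubin's-rules variance pooling is deliberately absent: uncertainty comes
  from the bootstrap, and the m imputations enter only through the pooled
  correlation matrix (single-completed-dataset mode is available).
* The Gaussian likelihood is applied to rank-based correlations — standard
  EBICglasso practice, but the EBIC "n" is then an approximation.
* Polychoric/polyserial correlations, mixed graphical models, bridge
  centralities and community detection are out of scope.
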