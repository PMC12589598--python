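# housenet

Partial-correlation network analysis of housing-quality indicators and
depressive symptoms, built as a tested, reusable pipeline.

## The problem

Epidemiological studies increasingly summarize poor housing as a single
composite score, which hides *which* aspects of housing (size, temperature,
facilities, decorations, problems such as damp and mould, or subjective
feelings towards the home) actually carry the association with mental
health. A psychometric network treats each indicator, the depressive-symptom
total, and key covariates (SES adversity, age) as nodes, and estimates the
*conditional* association between every pair of variables given all the
others. The resulting edge weights and node centralities identify which
indicators are most influential — information a composite score cannot give.

Cohort data of this kind is access-controlled, so the package ships a
first-class synthetic-cohort generator with a known ("planted") sparse
partial-correlation structure, realistic bounded/ordinal marginals, MAR
missingness and a logistic selection mechanism. Every pipeline stage is
validated against that known truth.

## The model

For variables with precision (inverse covariance) matrix κ, the edge weight
between nodes *i* and *j* is the partial correlation

    P_ij = −κ_ij / √(κ_ii κ_jj),

zero iff the variables are conditionally independent (given Gaussianity).
The pipeline estimates a sparse κ̂ by the graphical lasso — maximizing
`log det κ − tr(R κ) − λ Σ_{i≠j} |κ_ij|` over positive-definite κ for the
sample correlation R — over a log-spaced path of penalties λ, and selects λ
by the extended Bayesian information criterion

    EBIC = −2ℓ(κ̂) + E log n + 4 E γ log p,       γ = 0.5,

where E is the number of nonzero edges; γ = 0.5 is the conventional
"moderate" setting that excludes weak edges. The input R is a **weighted
Spearman** correlation matrix: mid-ranks per column, then weighted Pearson
on the ranks, with stabilized inverse-probability-of-selection weights
`w_i = mean(S) / P̂(S=1 | x_i)` from a logistic model of the selection
indicator S on age and SES risk. Missing indicator scores are completed by
chained-equations imputation with predictive mean matching; the per-imputation
correlation matrices are pooled on the Fisher-z scale.

Uncertainty and robustness come from resampling: nonparametric bootstrap
(95% percentile CIs per edge and pairwise edge-difference tests) and
case-drop bootstrap summarized by the correlation-stability coefficient
(CS): the largest fraction of participants that can be dropped while
subsample centralities still correlate ≥ 0.7 with the full-sample
centralities in ≥ 95% of subsamples (CS > 0.25 minimally acceptable).

## Worked example

```python
from housenet.pipeline import PipelineConfig, run_pipeline

cfg = PipelineConfig(synthetic_n=9669, bootstrap_B=200, casedrop_B=50,
                     output_dir="run1", seed=7)
summary = run_pipeline(cfg)["summary"]
```

This simulates a study-scale cohort (n = 9,669) from the default planted
9-node network, imposes MAR missingness and selection, then runs
filter → MAR report → imputation (m = 5) → IPW → pooled weighted Spearman →
EBICglasso (γ = 0.5) → centralities → bootstraps. The printed summary (seed 7):

```
n_analyzed        9620
edge weights      36 possible, 12 nonzero
                  mean 0.011, SD 0.077, range −0.260 … +0.178
top edges         size–age            −0.260
                  problems–feelings   +0.178
                  depressive–SES risk +0.151
CS coefficients   expected influence 0.90, strength 0.90,
                  betweenness 0.75, closeness 0.90
expected influence  feelings +0.416 > depressive symptoms +0.338 > problems +0.259
```

Reading this: of the 36 possible edges among 9 nodes, the conservative
EBIC selection retains 12; the strongest conditional associations are the
planted ones (smaller houses among older mothers; depressive symptoms with
SES adversity; feelings towards the home with problems in the home), and
"feelings" carries the greatest summed signed connectivity (expected
influence). The CS values say the centrality orderings survive dropping up
to ~90% of cases, far above the 0.25 acceptability floor.

The same run is available from the shell:

```bash
housenet simulate --n 9669 --seed 7 --missing-rate 0.1 --selection --out cohort.csv
housenet run --input cohort.csv --seed 7 --gamma 0.5 --boots 200 --out run1
housenet report run1
```

Every run directory contains the resolved config (`config.resolved.json`),
edge list and adjacency CSVs, centrality table, bootstrap and stability
CSVs, and a machine-readable `summary.json`.

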