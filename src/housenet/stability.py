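"""Bootstrap accuracy and stability of the estimated network.

Two resampling schemes, both re-running the full estimation (weights ->
weighted Spearman -> EBICglasso) on every resample:

* nonparametric bootstrap (rows drawn with replacement) for edge-weight
  accuracy: per-edge 95% percentile confidence intervals and pairwise
  edge-weight difference tests;
* case-drop bootstrap (subsampling without replacement at increasing drop
  proportions) for centrality stability, summarized by the correlation
  stability (CS) coefficient: the largest drop proportion at which the
  subsample centralities still correlate at least 0.7 with the full-sample
  centralities in at least 95% of subsamples.  CS > 0.25 is the
  conventional minimum for interpreting a centrality ordering, CS > 0.5
  preferred.

When the dataset carries a selection indicator, each resample refits the
selection model and recomputes stabilized weights, so weight-estimation
uncertainty propagates into the intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .association import nearest_positive_definite, weighted_spearman_matrix
from .centrality import METRICS, centrality_table
from .datatypes import IndicatorDataset, WeightVector
from .ggm import GGMNetwork, estimate_network
from .selection import fit_selection_model, stabilized_weights

DEFAULT_DROP_GRID = tuple(np.round(np.arange(0.05, 0.951, 0.05), 2))


def _estimate_once(
    data: IndicatorDataset,
    weights: Optional[WeightVector],
    gamma: float,
    n_lambdas: int,
    lambda_min_ratio: float,
    refit_weights: bool,
    selection_predictors: Optional[Sequence[str]],
) -> GGMNetwork:
    """One full pass: (re)weight -> weighted Spearman -> PD repair -> EBICglasso."""
    w = weights
    if refit_weights and data.selection is not None and data.selection.nunique() == 2:
        model = fit_selection_model(
            data, selection_predictors if selection_predictors else ("age", "ses_risk")
        )
        w = stabilized_weights(model, data, mode=weights.mode if weights else "analyzed")
    corr = weighted_spearman_matrix(data, w)
    corr = nearest_positive_definite(corr)
    net, _ = estimate_network(
        corr, n=data.n, gamma=gamma, n_lambdas=n_lambdas, lambda_min_ratio=lambda_min_ratio
    )
    return net


@dataclass
class BootstrapResult:
    """Per-edge bootstrap distributions and 95% CIs."""

    edge_labels: list[tuple[str, str]]
    point_estimates: np.ndarray  # (n_edges,)
    samples: np.ndarray  # (B, n_edges)
    ci_level: float
    seed: int
    scheme: str = "nonparametric"

    @property
    def n_resamples(self) -> int:
        return self.samples.shape[0]

    @property
    def bootstrap_mean(self) -> np.ndarray:
        return self.samples.mean(axis=0)

    @property
    def ci(self) -> np.ndarray:
        """(n_edges, 2) lower/upper empirical percentile bounds."""
        alpha = 1.0 - self.ci_level
        lo = np.quantile(self.samples, alpha / 2, axis=0)
        hi = np.quantile(self.samples, 1 - alpha / 2, axis=0)
        return np.column_stack([lo, hi])

    def to_frame(self) -> pd.DataFrame:
        ci = self.ci
        return pd.DataFrame(
            {
                "node_a": [a for a, _ in self.edge_labels],
                "node_b": [b for _, b in self.edge_labels],
                "estimate": self.point_estimates,
                "boot_mean": self.bootstrap_mean,
                "ci_lo": ci[:, 0],
                "ci_hi": ci[:, 1],
            }
        )


def bootstrap_edges(
    data: IndicatorDataset,
    weights: Optional[WeightVector] = None,
    B: int = 1000,
    seed: int = 0,
    gamma: float = 0.5,
    n_lambdas: int = 100,
    lambda_min_ratio: float = 0.01,
    ci_level: float = 0.95,
    refit_weights: bool = True,
    selection_predictors: Optional[Sequence[str]] = None,
    max_retries: int = 20,
) -> BootstrapResult:
    """Nonparametric bootstrap of all edge weights.

    Each of the ``B`` resamples draws n rows with replacement and re-runs
    the full estimation at the same gamma and path settings.  A resample
    that produces a zero-variance column is redrawn (bounded retries).
    Deterministic under a fixed seed.
    """
    if B < 2:
        raise ValueError("B must be >= 2")
    if not data.is_complete:
        raise ValueError("bootstrap requires a completed dataset")
    full = _estimate_once(
        data, weights, gamma, n_lambdas, lambda_min_ratio, refit_weights,
        selection_predictors,
    )
    p = full.p
    iu = np.triu_indices(p, k=1)
    edge_labels = [(full.labels[i], full.labels[j]) for i, j in zip(*iu)]

    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(0xB007,)))
    n = data.n
    samples = np.empty((B, len(edge_labels)))
    for b in range(B):
        for attempt in range(max_retries + 1):
            idx = rng.integers(0, n, size=n)
            sub = data.take_rows(idx)
            try:
                net = _estimate_once(
                    sub, weights, gamma, n_lambdas, lambda_min_ratio, refit_weights,
                    selection_predictors,
                )
                break
            except ValueError:
                if attempt == max_retries:
                    raise RuntimeError(
                        f"resample {b}: no valid draw within {max_retries} retries"
                    )
        samples[b] = net.weights[iu]
    return BootstrapResult(
        edge_labels=edge_labels,
        point_estimates=full.weights[iu],
        samples=samples,
        ci_level=ci_level,
        seed=seed,
    )


def edge_difference_test(
    boot: BootstrapResult, alpha: float = 0.05, bonferroni: bool = False
) -> pd.DataFrame:
    """Pairwise bootstrap difference test between edge weights.

    Edges e and f differ significantly iff the empirical
    (alpha/2, 1-alpha/2) interval of the bootstrap distribution of
    ``w_e - w_f`` excludes zero.  Returns a symmetric boolean matrix with a
    False diagonal, indexed by edge names "a--b".
    """
    if boot.n_resamples < int(np.ceil(5.0 / alpha)):
        raise ValueError(
            f"need >= {int(np.ceil(5.0 / alpha))} resamples for alpha={alpha}"
        )
    names = [f"{a}--{b}" for a, b in boot.edge_labels]
    m = len(names)
    if bonferroni:
        alpha = alpha / (m * (m - 1) / 2)
    sig = np.zeros((m, m), dtype=bool)
    s = boot.samples
    for e in range(m):
        diff = s[:, e, None] - s[:, e + 1 :]
        if diff.shape[1] == 0:
            continue
        lo = np.quantile(diff, alpha / 2, axis=0)
        hi = np.quantile(diff, 1 - alpha / 2, axis=0)
        out = (lo > 0) | (hi < 0)
        sig[e, e + 1 :] = out
        sig[e + 1 :, e] = out
    return pd.DataFrame(sig, index=names, columns=names)


@dataclass
class StabilityResult:
    """Case-drop correlation distributions per drop proportion and metric."""

    drop_grid: tuple[float, ...]
    metrics: tuple[str, ...]
    correlations: dict[str, np.ndarray] = field(repr=False)  # metric -> (n_drops, B)
    seed: int = 0
    cor_threshold: float = 0.7
    prob: float = 0.95

    def frac_above(self, metric: str, cor_threshold: Optional[float] = None) -> np.ndarray:
        """Fraction of subsamples with correlation >= threshold, per drop level.

        Undefined correlations (constant centralities in a subsample) count
        as failures.
        """
        thr = self.cor_threshold if cor_threshold is None else cor_threshold
        c = self.correlations[metric]
        with np.errstate(invalid="ignore"):
            return np.mean(np.where(np.isnan(c), -np.inf, c) >= thr, axis=1)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for m in self.metrics:
            c = self.correlations[m]
            fr = self.frac_above(m)
            for i, d in enumerate(self.drop_grid):
                rows.append(
                    {
                        "metric": m,
                        "drop": d,
                        "mean_cor": float(np.nanmean(c[i])) if np.isfinite(c[i]).any() else np.nan,
                        "frac_above_threshold": float(fr[i]),
                    }
                )
        return pd.DataFrame(rows)


def casedrop_bootstrap(
    data: IndicatorDataset,
    weights: Optional[WeightVector] = None,
    metrics: Sequence[str] = METRICS,
    drop_grid: Sequence[float] = DEFAULT_DROP_GRID,
    B: int = 1000,
    seed: int = 0,
    gamma: float = 0.5,
    n_lambdas: int = 100,
    lambda_min_ratio: float = 0.01,
    refit_weights: bool = True,
    selection_predictors: Optional[Sequence[str]] = None,
) -> StabilityResult:
    """Case-drop bootstrap of node centralities.

    For each drop proportion d the network and centralities are recomputed
    on ``B`` subsamples of size ``round((1-d) n)`` drawn without
    replacement, and the Pearson correlation (over nodes) with the
    full-sample centralities is recorded.  Proportions whose subsample
    would fall below p+1 rows are skipped with a warning.
    """
    if not data.is_complete:
        raise ValueError("case-drop bootstrap requires a completed dataset")
    full = _estimate_once(
        data, weights, gamma, n_lambdas, lambda_min_ratio, refit_weights,
        selection_predictors,
    )
    full_cent = centrality_table(full, metrics)
    n, p = data.n, full.p

    usable = []
    for d in drop_grid:
        size = int(round((1 - d) * n))
        if size >= p + 1:
            usable.append(float(d))
        else:
            import warnings

            warnings.warn(
                f"drop proportion {d} leaves only {size} rows (< p+1 = {p + 1}); skipped"
            )
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(0xCA5E,)))
    cors = {m: np.full((len(usable), B), np.nan) for m in metrics}
    for i, d in enumerate(usable):
        size = int(round((1 - d) * n))
        for b in range(B):
            idx = rng.choice(n, size=size, replace=False)
            sub = data.take_rows(idx)
            try:
                net = _estimate_once(
                    sub, weights, gamma, n_lambdas, lambda_min_ratio, refit_weights,
                    selection_predictors,
                )
            except ValueError:
                continue  # degenerate subsample counts as a failed resample
            cent = centrality_table(net, metrics)
            for m in metrics:
                x, y = full_cent[m].to_numpy(), cent[m].to_numpy()
                if x.std() > 0 and y.std() > 0:
                    cors[m][i, b] = float(np.corrcoef(x, y)[0, 1])
    return StabilityResult(
        drop_grid=tuple(usable),
        metrics=tuple(metrics),
        correlations=cors,
        seed=seed,
    )


def cs_coefficient(
    result: StabilityResult,
    cor_threshold: float = 0.7,
    prob: float = 0.95,
) -> dict[str, float]:
    """Correlation stability coefficient per metric.

    CS(metric) is the largest drop proportion d in the grid such that at
    every grid proportion d' <= d, at least ``prob`` of the subsamples
    correlate >= ``cor_threshold`` with the full-sample centralities; 0 if
    no proportion qualifies.
    """
    if len(result.drop_grid) < 2:
        raise ValueError("stability result must cover at least 2 drop proportions")
    out = {}
    for m in result.metrics:
        frac = result.frac_above(m, cor_threshold)
        cs = 0.0
        for d, f in zip(result.drop_grid, frac):
            if f >= prob:
                cs = d
            else:
                break
        out[m] = cs
    return out
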