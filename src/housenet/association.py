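"""Weighted Spearman correlation matrices and their conditioning.

The network is estimated from rank correlations: each column is converted
to mid-ranks (ties get average rank) and each pair's entry is the
*weighted* Pearson correlation of the two rank vectors, with the stabilized
IPW weights supplying the weighting.  With uniform weights this reduces
exactly to the classical Spearman matrix.  Ranks themselves are computed
unweighted on the analyzed rows; weights enter only through the Pearson
step.

Weighted or imputation-pooled rank-correlation matrices need not be
positive definite, while the graphical lasso requires a PD input, so a
minimal eigenvalue-clipping repair is provided.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .datatypes import CorrelationMatrix, IndicatorDataset, WeightVector


def _as_frame(data) -> pd.DataFrame:
    if isinstance(data, IndicatorDataset):
        return data.values
    return pd.DataFrame(data)


def weighted_spearman_matrix(
    data,
    weights: Optional[WeightVector] = None,
    columns: Optional[Sequence[str]] = None,
) -> CorrelationMatrix:
    """Weighted Spearman correlation matrix of a complete table.

    Parameters
    ----------
    data
        Complete :class:`IndicatorDataset` or DataFrame (no missing cells).
    weights
        Per-row nonnegative weights; ``None`` means uniform (classical
        Spearman).  Rows with zero weight contribute nothing.
    """
    df = _as_frame(data)
    if columns is not None:
        df = df[list(columns)]
    if df.isna().any().any():
        raise ValueError("weighted Spearman requires a complete table (no missing cells)")
    if weights is None:
        w = np.ones(len(df))
    else:
        w = np.asarray(weights.weights.reindex(df.index), dtype=float)
        if np.isnan(w).any():
            raise ValueError("weights are not aligned with the data rows")
    if (w < 0).any() or w.sum() <= 0:
        raise ValueError("weights must be nonnegative with positive total")

    ranks = np.column_stack([rankdata(df[c].to_numpy(), method="average") for c in df])
    total = w.sum()
    mean = (w[:, None] * ranks).sum(axis=0) / total
    centered = ranks - mean
    cov = (centered * w[:, None]).T @ centered / total
    sd = np.sqrt(np.diag(cov))
    zero = np.flatnonzero(sd <= 0)
    if len(zero):
        names = [df.columns[j] for j in zero]
        raise ValueError(f"zero-variance column(s) under the given weights: {names}")
    corr = cov / np.outer(sd, sd)
    corr = np.clip((corr + corr.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(corr, 1.0)

    n_eff = float(total**2 / (w**2).sum())
    return CorrelationMatrix(
        values=corr,
        labels=list(df.columns),
        n_effective=n_eff,
        provenance={
            "weighted": weights is not None,
            "n_rows": int((w > 0).sum()),
        },
    )


def pool_correlations(matrices: Sequence[CorrelationMatrix]) -> CorrelationMatrix:
    """Pool several correlation matrices element-wise on the Fisher z scale.

    Used to combine the per-imputation weighted Spearman matrices into one
    matrix before network estimation.
    """
    if not matrices:
        raise ValueError("nothing to pool")
    first = matrices[0]
    for m in matrices[1:]:
        if m.labels != first.labels or m.p != first.p:
            raise ValueError("pooled matrices must share labels and dimension")
    if len(matrices) == 1:
        return first

    clip = 1.0 - 1e-12
    zs = [np.arctanh(np.clip(m.values, -clip, clip)) for m in matrices]
    pooled = np.tanh(np.mean(zs, axis=0))
    pooled = (pooled + pooled.T) / 2.0
    np.fill_diagonal(pooled, 1.0)
    n_eff = float(np.mean([m.n_effective for m in matrices]))
    return CorrelationMatrix(
        values=pooled,
        labels=list(first.labels),
        n_effective=n_eff,
        provenance={"pooled_from": len(matrices)},
    )


def nearest_positive_definite(
    corr: CorrelationMatrix, min_eigenvalue: float = 1e-6
) -> CorrelationMatrix:
    """Eigenvalue-clipping repair onto the PD correlation matrices.

    Clips eigenvalues at ``min_eigenvalue`` and rescales to unit diagonal,
    iterating until the minimum eigenvalue clears the floor.  A matrix that
    is already PD is returned unchanged (bitwise no-op).
    """
    v = corr.values
    if np.linalg.eigvalsh(v).min() >= min_eigenvalue:
        return corr
    x = v.copy()
    for _ in range(100):
        lam, q = np.linalg.eigh(x)
        lam = np.maximum(lam, min_eigenvalue)
        x = (q * lam) @ q.T
        d = np.sqrt(np.diag(x))
        x = x / np.outer(d, d)
        x = (x + x.T) / 2.0
        np.fill_diagonal(x, 1.0)
        if np.linalg.eigvalsh(x).min() >= min_eigenvalue * (1 - 1e-9):
            break
    prov = dict(corr.provenance)
    prov["pd_repaired"] = True
    return CorrelationMatrix(
        values=x, labels=list(corr.labels), n_effective=corr.n_effective, provenance=prov
    )
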