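"""Sparse Gaussian graphical model estimation with EBIC model selection.

The network's edges are partial correlations obtained from an L1-penalized
precision matrix: ``glasso_fit`` maximizes

    log det K - tr(R K) - lambda * sum_{i != j} |K_ij|

over positive-definite K for a correlation input R, and the penalty is
chosen from a log-spaced path by minimizing the extended Bayesian
information criterion

    EBIC(K) = -2 l(K) + E log n + 4 E gamma log p,

where ``l = (n/2)(log det K - tr(R K))`` is the Gaussian log-likelihood at
the sample correlation, ``E`` the number of nonzero upper-triangular
entries of K, and ``gamma`` (default 0.5, the conventional "moderate"
setting) penalizes model-space size so weak edges are excluded.  Edge
weights are then ``P_ij = -K_ij / sqrt(K_ii K_jj)``.

Ties in EBIC resolve toward the larger penalty, i.e. the sparser network.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._glasso import glasso_cd
from .datatypes import CorrelationMatrix

#: entries of the precision below this magnitude count as structural zeros
ZERO_TOL = 1e-10


def _corr_values(corr) -> np.ndarray:
    if isinstance(corr, CorrelationMatrix):
        return corr.values
    return np.asarray(corr, dtype=float)


def glasso_fit(
    corr,
    lam: float,
    tol: float = 1e-6,
    max_iter: int = 500,
    return_converged: bool = False,
):
    """L1-penalized precision estimate at a single penalty ``lam``.

    Only the off-diagonal entries carry the penalty; ``lam = 0`` returns the
    unpenalized maximum-likelihood inverse.  Convergence is declared when
    two successive sweeps change the precision by less than ``tol`` in
    maximum absolute entry; hitting ``max_iter`` without converging raises,
    reporting the offending penalty.  The result is exactly symmetric with
    exact zeros where the lasso deactivates an edge.
    """
    r = _corr_values(corr)
    if lam < 0:
        raise ValueError("penalty must be nonnegative")
    eigmin = np.linalg.eigvalsh(r).min()
    if eigmin <= 0:
        raise ValueError(
            "input correlation matrix is not positive definite "
            f"(min eigenvalue {eigmin:.3e}); apply nearest_positive_definite first"
        )
    if lam == 0:
        k = np.linalg.inv(r)
        k = (k + k.T) / 2.0
        return (k, True) if return_converged else k
    k, _, converged = glasso_cd(r, float(lam), float(tol), int(max_iter))
    if not converged and not return_converged:
        raise RuntimeError(
            f"graphical lasso did not converge within {max_iter} sweeps at lambda={lam}"
        )
    off_small = (np.abs(k) < ZERO_TOL) & ~np.eye(k.shape[0], dtype=bool)
    k[off_small] = 0.0
    return (k, converged) if return_converged else k


def glasso_objective(k: np.ndarray, r: np.ndarray, lam: float) -> float:
    """Penalized log-likelihood maximized by :func:`glasso_fit`."""
    sign, logdet = np.linalg.slogdet(k)
    if sign <= 0:
        return -np.inf
    off = k.copy()
    np.fill_diagonal(off, 0.0)
    return float(logdet - np.trace(r @ k) - lam * np.abs(off).sum())


def edge_count(precision: np.ndarray, tol: float = ZERO_TOL) -> int:
    """Number of nonzero upper-triangular off-diagonal precision entries."""
    iu = np.triu_indices_from(precision, k=1)
    return int((np.abs(precision[iu]) > tol).sum())


def ebic_score(precision: np.ndarray, corr, n: int, gamma: float = 0.5) -> float:
    """Extended BIC of a fitted precision given the sample correlation and n."""
    r = _corr_values(corr)
    p = r.shape[0]
    if n <= p:
        raise ValueError(f"sample size n={n} must exceed dimension p={p}")
    sign, logdet = np.linalg.slogdet(precision)
    if sign <= 0:
        raise ValueError("precision must be positive definite")
    loglik = (n / 2.0) * (logdet - np.trace(r @ precision))
    e = edge_count(precision)
    return float(-2.0 * loglik + e * np.log(n) + 4.0 * e * gamma * np.log(p))


@dataclass
class RegularizationPath:
    """Per-penalty diagnostics of one EBICglasso path."""

    lambdas: np.ndarray
    precisions: list[np.ndarray]
    edge_counts: np.ndarray
    ebic: np.ndarray
    converged: np.ndarray

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "lambda": self.lambdas,
                "edges": self.edge_counts,
                "ebic": self.ebic,
                "converged": self.converged,
            }
        )


@dataclass
class GGMNetwork:
    """Partial-correlation network selected by EBIC."""

    labels: list[str]
    weights: np.ndarray  # p x p, symmetric, zero diagonal
    lambda_: float
    ebic: float
    gamma: float
    n: int
    precision: np.ndarray = field(repr=False, default=None)

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if not np.allclose(w, w.T, atol=1e-10):
            raise ValueError("edge-weight matrix must be symmetric")
        if np.abs(np.diag(w)).max() > 1e-12:
            raise ValueError("edge-weight matrix must have zero diagonal")
        if np.abs(w).max() >= 1.0:
            raise ValueError("partial correlations must lie in (-1, 1)")
        self.weights = w

    @property
    def p(self) -> int:
        return self.weights.shape[0]

    @property
    def n_possible_edges(self) -> int:
        return self.p * (self.p - 1) // 2

    def edge_list(self):
        """Long-format (node_a, node_b, weight) rows over the upper triangle."""
        import pandas as pd

        iu = np.triu_indices(self.p, k=1)
        return pd.DataFrame(
            {
                "node_a": [self.labels[i] for i in iu[0]],
                "node_b": [self.labels[j] for j in iu[1]],
                "weight": self.weights[iu],
            }
        )

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.weights, index=self.labels, columns=self.labels)


def partial_correlations(precision: np.ndarray) -> np.ndarray:
    """Rescale a precision matrix to partial correlations with zero diagonal."""
    d = np.sqrt(np.diag(precision))
    pc = -precision / np.outer(d, d)
    np.fill_diagonal(pc, 0.0)
    pc[np.abs(pc) < ZERO_TOL] = 0.0
    return (pc + pc.T) / 2.0


def estimate_network(
    corr: CorrelationMatrix,
    n: int | None = None,
    gamma: float = 0.5,
    n_lambdas: int = 100,
    lambda_min_ratio: float = 0.01,
    tol: float = 1e-6,
    max_iter: int = 500,
) -> tuple[GGMNetwork, RegularizationPath]:
    """EBICglasso: fit a log-spaced penalty path and select by minimum EBIC.

    The path runs from ``lambda_max`` (the largest off-diagonal |r|, at which
    the solution is empty) down to ``lambda_max * lambda_min_ratio``.  At
    equal EBIC the larger penalty (sparser model) wins.
    """
    r = _corr_values(corr)
    labels = corr.labels if isinstance(corr, CorrelationMatrix) else [
        f"v{i}" for i in range(r.shape[0])
    ]
    if n is None:
        if not isinstance(corr, CorrelationMatrix):
            raise ValueError("sample size n required")
        n = int(round(corr.n_effective))
    p = r.shape[0]
    if n <= p:
        raise ValueError(f"sample size n={n} must exceed dimension p={p}")

    off = np.abs(r - np.diag(np.diag(r)))
    lam_max = float(off.max())
    if lam_max <= 0:
        lam_max = 1e-3  # diagonal input: any penalty gives the empty model
    lambdas = np.geomspace(lam_max, lam_max * lambda_min_ratio, n_lambdas)

    precisions, counts, scores, conv = [], [], [], []
    for lam in lambdas:
        k, converged = glasso_fit(
            r, float(lam), tol=tol, max_iter=max_iter, return_converged=True
        )
        precisions.append(k)
        counts.append(edge_count(k))
        scores.append(ebic_score(k, r, n, gamma))
        conv.append(converged)
    counts = np.asarray(counts)
    scores = np.asarray(scores)

    # argmin with ties resolved toward the largest lambda (path is descending)
    best = int(np.flatnonzero(scores <= scores.min() + 1e-12)[0])
    if not conv[best]:
        raise RuntimeError(
            f"graphical lasso did not converge at the selected penalty "
            f"lambda={lambdas[best]:.6g}"
        )
    k_best = precisions[best]
    net = GGMNetwork(
        labels=list(labels),
        weights=partial_correlations(k_best),
        lambda_=float(lambdas[best]),
        ebic=float(scores[best]),
        gamma=gamma,
        n=int(n),
        precision=k_best,
    )
    path = RegularizationPath(
        lambdas=lambdas,
        precisions=precisions,
        edge_counts=counts,
        ebic=scores,
        converged=np.asarray(conv),
    )
    return net, path


def network_summary(net: GGMNetwork) -> dict:
    """Edge-weight summary over the unique off-diagonal entries.

    Reports the possible and realized edge counts, the mean/SD/min/max of
    all unique edge weights (zeros included, sample SD), and each node's
    strongest edge.
    """
    iu = np.triu_indices(net.p, k=1)
    w = net.weights[iu]
    nonzero = int((np.abs(w) > ZERO_TOL).sum())
    strongest = {}
    for i, lab in enumerate(net.labels):
        row = net.weights[i].copy()
        row[i] = 0.0
        j = int(np.argmax(np.abs(row)))
        strongest[lab] = {"partner": net.labels[j], "weight": float(row[j])}
    return {
        "n_nodes": net.p,
        "possible_edges": net.n_possible_edges,
        "nonzero_edges": nonzero,
        "mean_weight": float(w.mean()) if len(w) else 0.0,
        "sd_weight": float(w.std(ddof=1)) if len(w) > 1 else 0.0,
        "min_weight": float(w.min()) if len(w) else 0.0,
        "max_weight": float(w.max()) if len(w) else 0.0,
        "strongest_edge_per_node": strongest,
        "selected_lambda": net.lambda_,
        "gamma": net.gamma,
        "ebic": net.ebic,
        "n": net.n,
    }
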