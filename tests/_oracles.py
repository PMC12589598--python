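"""Independent oracles used by the test suite.

Everything here is deliberately naive and slow: a generic nonlinear
optimizer for the penalized Gaussian likelihood, the p=2 closed form of the
graphical lasso, and exhaustive path enumeration for shortest-path
centralities.  None of it shares code with the implementations it checks.
"""

from __future__ import annotations

from itertools import permutations

import numpy as np
from scipy import optimize


def random_pd_corr(p: int, rng: np.random.Generator, dof: int | None = None) -> np.ndarray:
    """Random correlation matrix from a Wishart-style draw."""
    a = rng.standard_normal((p, dof if dof else p + 2))
    c = a @ a.T
    d = np.sqrt(np.diag(c))
    return c / np.outer(d, d)


def penalized_loglik(k: np.ndarray, r: np.ndarray, lam: float) -> float:
    sign, logdet = np.linalg.slogdet(k)
    if sign <= 0:
        return -np.inf
    off = k.copy()
    np.fill_diagonal(off, 0.0)
    return float(logdet - np.trace(r @ k) - lam * np.abs(off).sum())


def glasso_bruteforce(r: np.ndarray, lam: float, restarts: int = 6):
    """Maximize the penalized likelihood with Nelder-Mead over the free
    entries, positive-definiteness enforced by an infinite barrier."""
    p = r.shape[0]
    iu = np.triu_indices(p)

    def unpack(x):
        k = np.zeros((p, p))
        k[iu] = x
        return k + np.triu(k, 1).T

    def negobj(x):
        v = penalized_loglik(unpack(x), r, lam)
        return np.inf if not np.isfinite(v) else -v

    x = np.linalg.inv(r)[iu]
    best = None
    for _ in range(restarts):
        res = optimize.minimize(
            negobj, x, method="Nelder-Mead",
            options=dict(maxiter=40000, xatol=1e-11, fatol=1e-13),
        )
        x = res.x
        if best is None or res.fun < best.fun:
            best = res
    return -best.fun, unpack(best.x)


def glasso_closed_form_p2(r12: float, lam: float) -> np.ndarray:
    """Exact 2x2 solution: soft-threshold the off-diagonal covariance."""
    w12 = np.sign(r12) * max(abs(r12) - lam, 0.0)
    w = np.array([[1.0, w12], [w12, 1.0]])
    return np.linalg.inv(w)


# ---------------------------------------------------------------------------
# Exhaustive shortest-path centralities (<= ~7 nodes)
# ---------------------------------------------------------------------------


def _all_shortest_paths(weights: np.ndarray, s: int, t: int):
    """All simple s-t paths of minimal 1/|w| length; (min_length, count, paths)."""
    p = weights.shape[0]
    inner = [v for v in range(p) if v not in (s, t)]
    best = np.inf
    paths = []
    for k in range(len(inner) + 1):
        for mid in permutations(inner, k):
            route = (s, *mid, t)
            length = 0.0
            ok = True
            for a, b in zip(route, route[1:]):
                if abs(weights[a, b]) <= 1e-10:
                    ok = False
                    break
                length += 1.0 / abs(weights[a, b])
            if not ok:
                continue
            if length < best - 1e-12:
                best = length
                paths = [route]
            elif abs(length - best) <= 1e-12:
                paths.append(route)
    return best, len(paths), paths


def betweenness_bruteforce(weights: np.ndarray) -> np.ndarray:
    """Unnormalized betweenness by enumerating every simple path."""
    p = weights.shape[0]
    out = np.zeros(p)
    for s in range(p):
        for t in range(s + 1, p):
            best, count, paths = _all_shortest_paths(weights, s, t)
            if not np.isfinite(best) or count == 0:
                continue
            for v in range(p):
                if v in (s, t):
                    continue
                through = sum(1 for route in paths if v in route)
                out[v] += through / count
    return out


def closeness_bruteforce(weights: np.ndarray) -> np.ndarray:
    """Reachable-set closeness by exhaustive shortest-path lengths."""
    p = weights.shape[0]
    out = np.zeros(p)
    for i in range(p):
        dists = []
        for j in range(p):
            if j == i:
                continue
            best, count, _ = _all_shortest_paths(weights, i, j)
            if np.isfinite(best):
                dists.append(best)
        out[i] = len(dists) / sum(dists) if dists else 0.0
    return out
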