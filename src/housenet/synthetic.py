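"""Synthetic cohorts with a planted sparse partial-correlation structure.

Real cohorts of this kind (a birth cohort of pregnant women reporting six
housing-quality indicators, a 10-item depressive-symptom inventory, an
SES-adversity composite and age) are access-controlled, so every stage of
the pipeline is exercised against cohorts generated here, where the ground
truth is known exactly:

* the dependence structure is a 9-node Gaussian graphical model specified
  through its precision matrix (so the *partial* correlations are planted
  directly);
* marginals are imposed through a Gaussian copula -- latent multivariate
  normal draws are pushed through the probability integral transform and
  each target marginal's quantile function.  The transform is strictly
  monotone per column, so the Spearman structure of the latent field is
  preserved (up to ties introduced by ordinal marginals);
* missingness (MCAR or MAR driven by fully observed covariates) and a
  logistic selection mechanism can then be layered on, with the
  pre-missingness values and the true selection probabilities retained as
  hidden truth for accuracy tests.

All randomness flows from one integer seed through ``numpy`` seed
sequences: each operation spawns child streams keyed by a fixed label, so
adding a new draw site never perturbs existing streams.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .datatypes import IndicatorDataset, VariableMeta

#: Node order used throughout: six housing indicators, the outcome, two covariates.
DEFAULT_LABELS = (
    "size",
    "temperature",
    "facilities",
    "decorations",
    "problems",
    "feelings",
    "depressive_symptoms",
    "ses_risk",
    "age",
)

DEFAULT_ROLES = {
    "size": "housing",
    "temperature": "housing",
    "facilities": "housing",
    "decorations": "housing",
    "problems": "housing",
    "feelings": "housing",
    "depressive_symptoms": "outcome",
    "ses_risk": "covariate",
    "age": "covariate",
}

#: Number of depressive-symptom items and the per-item maximum; the total
#: score is bounded by their product (10 items scored 0-3 -> 0..30).
CCEI_N_ITEMS = 10
CCEI_ITEM_MAX = 3


def _rng(seed: int, label: str) -> np.random.Generator:
    """Counter-based child stream: one label, one independent stream."""
    key = int.from_bytes(label.encode(), "little") % (2**31)
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(key,)))


# ---------------------------------------------------------------------------
# Planted precision structure
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TruePrecisionSpec:
    """Ground-truth precision matrix and the partial correlations it implies."""

    node_labels: tuple[str, ...]
    precision: np.ndarray

    def __post_init__(self) -> None:
        k = np.asarray(self.precision, dtype=float)
        if k.shape != (len(self.node_labels),) * 2:
            raise ValueError("precision shape does not match node count")
        if not np.allclose(k, k.T, atol=1e-12):
            raise ValueError("precision must be symmetric")
        if np.linalg.eigvalsh(k).min() <= 1e-8:
            raise ValueError("precision must be positive definite (min eig > 1e-8)")

    @property
    def p(self) -> int:
        return len(self.node_labels)

    @property
    def implied_pcor(self) -> np.ndarray:
        """Partial correlations: pcor_ij = -kappa_ij / sqrt(kappa_ii * kappa_jj)."""
        k = self.precision
        d = np.sqrt(np.diag(k))
        pc = -k / np.outer(d, d)
        np.fill_diagonal(pc, 0.0)
        return pc

    @property
    def covariance(self) -> np.ndarray:
        return np.linalg.inv(self.precision)

    @property
    def latent_correlation(self) -> np.ndarray:
        c = self.covariance
        d = np.sqrt(np.diag(c))
        return c / np.outer(d, d)

    def edge_support(self, tol: float = 1e-10) -> np.ndarray:
        """Boolean upper-triangle support of the planted network."""
        pc = self.implied_pcor
        return np.abs(pc) > tol


def make_precision_spec(
    p: int,
    edge_set: Sequence[tuple[int, int, float]],
    node_labels: Optional[Sequence[str]] = None,
    jitter_seed: Optional[int] = None,
    jitter_scale: float = 0.0,
    max_distortion: float = 0.05,
    min_eigenvalue: float = 1e-3,
) -> TruePrecisionSpec:
    """Construct a positive-definite precision with requested partial correlations.

    The precision starts as the identity with ``kappa_ij = -r`` at each
    requested pair (so the implied partial correlation is exactly ``r`` when
    no boost is needed).  If the matrix is not positive definite the diagonal
    is boosted, which shrinks every implied partial correlation by a common
    factor; the construction fails if any requested value would be distorted
    by more than ``max_distortion`` (absolute).

    Parameters
    ----------
    jitter_seed, jitter_scale
        Optional uniform jitter applied to the requested partial correlations
        (used to generate families of random planted truths in tests).
    """
    if node_labels is None:
        node_labels = (
            DEFAULT_LABELS if p == len(DEFAULT_LABELS) else tuple(f"v{i}" for i in range(p))
        )
    node_labels = tuple(node_labels)
    if len(node_labels) != p:
        raise ValueError("node_labels length must equal p")

    edges = [(int(i), int(j), float(r)) for i, j, r in edge_set]
    if jitter_seed is not None and jitter_scale > 0:
        rng = _rng(jitter_seed, "pcor-jitter")
        edges = [
            (i, j, r + rng.uniform(-jitter_scale, jitter_scale)) for i, j, r in edges
        ]
    for i, j, r in edges:
        if not (-1 < r < 1):
            raise ValueError(f"requested partial correlation out of (-1,1) at ({i},{j}): {r}")
        if i == j:
            raise ValueError(f"self edge requested at node {i}")

    k = np.eye(p)
    for i, j, r in edges:
        k[i, j] = k[j, i] = -r

    lam_min = np.linalg.eigvalsh(k).min()
    boost = 0.0
    if lam_min <= min_eigenvalue:
        boost = min_eigenvalue - lam_min
        k = k + boost * np.eye(p)

    spec = TruePrecisionSpec(node_labels=node_labels, precision=k)
    pc = spec.implied_pcor
    offending = [
        (i, j, r, pc[i, j]) for i, j, r in edges if abs(pc[i, j] - r) > max_distortion
    ]
    if offending:
        msg = "; ".join(
            f"({i},{j}): requested {r:.3f}, achievable {got:.3f}" for i, j, r, got in offending
        )
        raise ValueError(
            "cannot reach positive definiteness without distorting requested "
            f"partial correlations beyond {max_distortion}: {msg}"
        )
    return spec


#: Planted edges of the default 9-node truth.  Magnitudes span the range a
#: real cohort of this kind exhibits (roughly -0.30 to 0.21): the strongest
#: negative edge ties house size to age, the strongest positive edge ties
#: depressive symptoms to SES risk, and the housing indicators form a
#: positively connected cluster anchored on feelings towards the home, with
#: one weak negative edge (decorations-temperature).
DEFAULT_EDGES: tuple[tuple[str, str, float], ...] = (
    ("size", "age", -0.30),
    ("depressive_symptoms", "ses_risk", 0.21),
    ("feelings", "problems", 0.20),
    ("size", "feelings", 0.17),
    ("size", "facilities", 0.16),
    ("ses_risk", "age", -0.15),
    ("feelings", "depressive_symptoms", 0.12),
    ("problems", "depressive_symptoms", 0.10),
    ("decorations", "temperature", -0.10),
    ("temperature", "facilities", 0.12),
)


def default_precision_spec() -> TruePrecisionSpec:
    """The default planted 9-node truth (see :data:`DEFAULT_EDGES`)."""
    idx = {name: i for i, name in enumerate(DEFAULT_LABELS)}
    edge_set = [(idx[a], idx[b], r) for a, b, r in DEFAULT_EDGES]
    return make_precision_spec(len(DEFAULT_LABELS), edge_set, node_labels=DEFAULT_LABELS)


# ---------------------------------------------------------------------------
# Marginals
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Marginal:
    """One variable's target marginal, expressed through its quantile function."""

    kind: str  # "continuous" | "ordinal-bounded"
    ppf: Callable[[np.ndarray], np.ndarray]
    bounds: tuple[float, float]
    round_to_integer: bool = False

    def __post_init__(self) -> None:
        if self.kind not in ("continuous", "ordinal-bounded"):
            raise ValueError(f"unknown marginal kind {self.kind!r}")
        if self.bounds[0] >= self.bounds[1]:
            raise ValueError(f"invalid marginal bounds {self.bounds}")

    def transform(self, u: np.ndarray) -> np.ndarray:
        x = np.asarray(self.ppf(u), dtype=float)
        x = np.clip(x, *self.bounds)
        if self.round_to_integer:
            x = np.round(x)
        return x


@dataclass(frozen=True)
class MarginalSpec:
    """Target marginal per variable."""

    marginals: dict[str, Marginal]

    def __getitem__(self, name: str) -> Marginal:
        return self.marginals[name]

    def __contains__(self, name: str) -> bool:
        return name in self.marginals


def ccei_marginal(mean: float = 4.30, sd: float = 3.02) -> Marginal:
    """Depressive-symptom total: integer 0..(items x item max), right-skewed.

    The bound is derived from the instrument: 10 items each scored 0-3, so
    the total ranges 0 to 30.  The default shape matches a mean of 4.30 and
    SD of 3.02 via a negative-binomial quantile function.
    """
    upper = CCEI_N_ITEMS * CCEI_ITEM_MAX
    var = sd**2
    if var <= mean:
        raise ValueError("overdispersed marginal requires variance > mean")
    r = mean**2 / (var - mean)
    prob = r / (r + mean)
    dist = stats.nbinom(r, prob)
    return Marginal("ordinal-bounded", dist.ppf, (0.0, float(upper)), round_to_integer=True)


def default_marginals() -> MarginalSpec:
    """Face-valid marginals for the nine study variables.

    Housing indicator scores are bounded continuous (1-5, symmetric beta);
    the depressive-symptom total is the bounded 0-30 ordinal; SES risk is a
    small ordinal adversity count; age is truncated normal on 15-44 years
    with mean 28.36 and SD 4.67.
    """
    housing = Marginal(
        "continuous",
        lambda u: 1.0 + 4.0 * stats.beta(5.0, 5.0).ppf(u),
        (1.0, 5.0),
    )
    ses = Marginal(
        "ordinal-bounded", stats.binom(15, 0.12).ppf, (0.0, 15.0), round_to_integer=True
    )
    a, b = (15.0 - 28.36) / 4.67, (44.0 - 28.36) / 4.67
    age = Marginal(
        "continuous", stats.truncnorm(a, b, loc=28.36, scale=4.67).ppf, (15.0, 44.0)
    )
    marginals = {name: housing for name in DEFAULT_LABELS[:6]}
    marginals["depressive_symptoms"] = ccei_marginal()
    marginals["ses_risk"] = ses
    marginals["age"] = age
    return MarginalSpec(marginals)


# ---------------------------------------------------------------------------
# Cohort simulation
# ---------------------------------------------------------------------------


def simulate_cohort(
    spec: TruePrecisionSpec,
    marginals: MarginalSpec,
    n: int,
    seed: int,
    roles: Optional[dict[str, str]] = None,
) -> IndicatorDataset:
    """Draw a complete cohort of size ``n`` from the planted structure.

    Latent draws are multivariate normal with covariance ``inv(precision)``;
    each column is pushed through the Gaussian copula onto its marginal.
    Deterministic under a fixed seed.  The latent draws are retained on the
    returned dataset (``_latent`` attribute) for rank-preservation checks.
    """
    p = spec.p
    if n < p + 1:
        raise ValueError(f"cohort size n={n} must exceed node count p={p}")
    for name in spec.node_labels:
        if name not in marginals:
            raise ValueError(f"no marginal specified for variable {name!r}")
    if roles is None:
        roles = DEFAULT_ROLES if set(spec.node_labels) <= set(DEFAULT_ROLES) else None
    if roles is None:
        raise ValueError("variable roles required for non-default labels")

    rng = _rng(seed, "cohort-latent")
    corr = spec.latent_correlation
    chol = np.linalg.cholesky(corr)
    z = rng.standard_normal((n, p)) @ chol.T
    u = special.ndtr(z)
    # keep u strictly inside (0,1) so quantile functions stay finite
    eps = np.finfo(float).tiny
    u = np.clip(u, eps, 1 - 1e-16)

    cols = {}
    for j, name in enumerate(spec.node_labels):
        cols[name] = marginals[name].transform(u[:, j])
    values = pd.DataFrame(cols, index=pd.RangeIndex(n))

    meta = [
        VariableMeta(
            name,
            roles[name],
            bounds=marginals[name].bounds,
            ordinal=marginals[name].kind == "ordinal-bounded",
        )
        for name in spec.node_labels
    ]
    ds = IndicatorDataset(values, meta, true_values=values.copy())
    ds._latent = pd.DataFrame(z, columns=list(spec.node_labels), index=values.index)
    return ds


# ---------------------------------------------------------------------------
# Missingness
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MissingnessSpec:
    """MCAR or MAR missingness on target columns.

    For MAR the per-row missingness probability is a logistic function of
    standardized driver covariates; the intercept is calibrated so the
    expected overall rate matches ``overall_rate``.
    """

    mechanism: str  # "MCAR" | "MAR"
    target_variables: tuple[str, ...]
    overall_rate: float
    driver_variables: tuple[str, ...] = ()
    driver_coefficients: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if self.mechanism not in ("MCAR", "MAR"):
            raise ValueError(f"unknown missingness mechanism {self.mechanism!r}")
        if not 0 <= self.overall_rate <= 1:
            raise ValueError("overall_rate must lie in [0, 1]")
        if self.mechanism == "MAR":
            if not self.driver_variables:
                raise ValueError("MAR missingness requires at least one driver variable")
            if len(self.driver_variables) != len(self.driver_coefficients):
                raise ValueError("one coefficient per driver variable required")


def _calibrate_intercept(score: np.ndarray, rate: float) -> float:
    """Solve mean(expit(a + score)) = rate for the intercept a."""
    if rate <= 0:
        return -np.inf
    if rate >= 1:
        return np.inf
    f = lambda a: special.expit(a + score).mean() - rate
    return optimize.brentq(f, -40.0, 40.0)


def impose_missingness(
    data: IndicatorDataset, mspec: MissingnessSpec, seed: int
) -> IndicatorDataset:
    """Blank out target cells under the requested mechanism.

    The pre-missingness values are retained as hidden truth so imputation
    accuracy can be measured against them.
    """
    for t in mspec.target_variables:
        if t not in data.columns:
            raise ValueError(f"unknown target variable {t!r}")
    if mspec.overall_rate == 0:
        return data.replace_values(data.values.copy())

    n = data.n
    if mspec.mechanism == "MCAR":
        score = np.zeros(n)
    else:
        for d in mspec.driver_variables:
            if data.values[d].isna().any():
                raise ValueError(f"MAR driver {d!r} must be fully observed")
        score = np.zeros(n)
        for d, c in zip(mspec.driver_variables, mspec.driver_coefficients):
            col = data.values[d].to_numpy(dtype=float)
            sd = col.std()
            z = (col - col.mean()) / sd if sd > 0 else np.zeros(n)
            score += c * z
    a = _calibrate_intercept(score, mspec.overall_rate)
    prob = special.expit(a + score)

    rng = _rng(seed, "missingness")
    values = data.values.copy()
    truth = data.hidden_truth
    truth = values.copy() if truth is None else truth
    for t in mspec.target_variables:
        hit = rng.random(n) < prob
        values.loc[hit, t] = np.nan
    return IndicatorDataset(
        values,
        data.meta,
        selection=data.selection,
        true_values=truth,
        true_selection_prob=data.hidden_selection_prob,
    )


# ---------------------------------------------------------------------------
# Selection
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SelectionSpec:
    """True logistic selection model P(S=1 | x) on standardized covariates."""

    intercept: float
    coefficients: dict[str, float] = field(default_factory=dict)
    standardize: bool = True


def impose_selection(
    data: IndicatorDataset, sspec: SelectionSpec, seed: int
) -> IndicatorDataset:
    """Draw the selection indicator S from the planted logistic model.

    True selection probabilities are retained as hidden truth for
    weight-accuracy tests.
    """
    n = data.n
    eta = np.full(n, float(sspec.intercept))
    for name, coef in sspec.coefficients.items():
        if name not in data.columns:
            raise ValueError(f"selection covariate {name!r} not in dataset")
        col = data.values[name]
        if col.isna().any():
            raise ValueError(f"selection covariate {name!r} must be fully observed")
        x = col.to_numpy(dtype=float)
        if sspec.standardize:
            sd = x.std()
            x = (x - x.mean()) / sd if sd > 0 else np.zeros(n)
        eta += coef * x
    prob = special.expit(eta)

    rng = _rng(seed, "selection")
    s = (rng.random(n) < prob).astype(int)
    return IndicatorDataset(
        data.values.copy(),
        data.meta,
        selection=pd.Series(s, index=data.values.index),
        true_values=data.hidden_truth,
        true_selection_prob=pd.Series(prob, index=data.values.index),
    )
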