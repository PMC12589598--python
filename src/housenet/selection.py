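"""Selection modelling and stabilized inverse-probability weights.

Participants with complete baseline housing data (selection indicator S=1)
may differ systematically from the rest of the cohort on observed
covariates.  A logistic model of S on age and SES risk yields predicted
selection probabilities; stabilized weights

    w_i = mean(S) / P(S=1 | x_i)

up-weight under-represented covariate profiles while keeping the weight
distribution centered near one.  Two application modes are supported:

``analyzed`` (default)
    every analyzed (post-inclusion, imputed) row receives the stabilized
    formula evaluated at its covariates;
``selected``
    only rows with S=1 carry weight; rows with S=0 get weight zero and drop
    out of weighted statistics.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .datatypes import IndicatorDataset, WeightVector

DEFAULT_PREDICTORS = ("age", "ses_risk")


@dataclass
class SelectionModel:
    """Fitted logistic selection model P(S=1 | predictors)."""

    predictors: tuple[str, ...]
    intercept: float
    coefficients: dict[str, float]
    fitted_prob: pd.Series
    converged: bool
    log_likelihood: float

    def predict(self, data: IndicatorDataset) -> pd.Series:
        """Predicted selection probability at each row's covariates."""
        eta = np.full(data.n, self.intercept)
        for name in self.predictors:
            eta = eta + self.coefficients[name] * data.values[name].to_numpy(dtype=float)
        from scipy.special import expit

        return pd.Series(expit(eta), index=data.values.index)

    def to_json_dict(self) -> dict:
        return {
            "predictors": list(self.predictors),
            "intercept": self.intercept,
            "coefficients": self.coefficients,
            "converged": self.converged,
            "log_likelihood": self.log_likelihood,
        }


def _check_separation(x: pd.DataFrame, s: np.ndarray) -> None:
    """Raise if any single predictor perfectly separates the two classes."""
    for c in x.columns:
        v1, v0 = x.loc[s == 1, c], x.loc[s == 0, c]
        if len(v1) and len(v0) and (v1.min() > v0.max() or v0.min() > v1.max()):
            raise ValueError(f"perfect separation on predictor {c!r}")


def fit_selection_model(
    data: IndicatorDataset, predictors: Sequence[str] = DEFAULT_PREDICTORS
) -> SelectionModel:
    """Maximum-likelihood logistic fit of S on the given predictors.

    Deterministic given the data; coefficients converged to 1e-8.
    """
    if data.selection is None:
        raise ValueError("dataset carries no selection indicator S")
    s = data.selection.to_numpy()
    if len(np.unique(s)) < 2:
        raise ValueError("selection indicator is single-class; cannot fit model")
    for c in predictors:
        if c not in data.columns:
            raise ValueError(f"unknown predictor {c!r}")
        if data.values[c].isna().any():
            raise ValueError(f"predictor {c!r} must be fully observed")
    x = data.values[list(predictors)]
    _check_separation(x, s)

    # Drop constant predictors (intercept absorbs them) so the MLE is unique.
    active = [c for c in predictors if x[c].nunique() > 1]
    design = sm.add_constant(x[active], has_constant="add")
    res = sm.Logit(s, design).fit(disp=0, tol=1e-10, maxiter=200)
    if not res.mle_retvals.get("converged", False):
        raise RuntimeError("logistic selection model failed to converge")

    coefs = {c: 0.0 for c in predictors}
    for c in active:
        coefs[c] = float(res.params[c])
    return SelectionModel(
        predictors=tuple(predictors),
        intercept=float(res.params["const"]),
        coefficients=coefs,
        fitted_prob=pd.Series(res.predict(design), index=data.values.index),
        converged=True,
        log_likelihood=float(res.llf),
    )


def stabilized_weights(
    model: SelectionModel,
    data: IndicatorDataset,
    truncation_quantiles: Optional[tuple[float, float]] = None,
    mode: str = "analyzed",
    min_probability: float = 1e-6,
) -> WeightVector:
    """Stabilized weights mean(S) / P(S=1 | x_i).

    In ``selected`` mode rows with S=0 receive weight 0 (they drop out of
    weighted statistics); in ``analyzed`` mode every row is weighted by the
    formula at its own covariates.  No truncation is applied by default;
    optional symmetric quantile truncation clips the nonzero weights.
    """
    if data.selection is None:
        raise ValueError("dataset carries no selection indicator S")
    s = data.selection.to_numpy()
    marginal = float(s.mean())
    prob = model.predict(data)

    if mode == "selected":
        relevant = prob[s == 1]
    elif mode == "analyzed":
        relevant = prob
    else:
        raise ValueError(f"unknown weight mode {mode!r}")
    if (relevant <= min_probability).any():
        k = int((relevant <= min_probability).sum())
        raise ValueError(
            f"{k} fitted selection probabilities are <= {min_probability}; "
            "weights would explode -- consider truncation_quantiles"
        )

    w = marginal / prob
    if mode == "selected":
        w = w.where(pd.Series(s, index=w.index) == 1, 0.0)
    if truncation_quantiles is not None:
        lo_q, hi_q = truncation_quantiles
        if not (0 <= lo_q < hi_q <= 1):
            raise ValueError("truncation quantiles must satisfy 0 <= lo < hi <= 1")
        nz = w > 0
        lo, hi = w[nz].quantile(lo_q), w[nz].quantile(hi_q)
        w = w.where(~nz, w.clip(lower=lo, upper=hi))
    return WeightVector(
        weights=w,
        marginal_prob=marginal,
        mode=mode,
        truncation_quantiles=truncation_quantiles,
    )


def uniform_weights(data: IndicatorDataset) -> WeightVector:
    """Unit weight per row -- the no-IPW degenerate case."""
    return WeightVector(
        weights=pd.Series(1.0, index=data.values.index),
        marginal_prob=1.0,
        mode="analyzed",
    )
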