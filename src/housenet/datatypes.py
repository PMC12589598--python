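"""Core containers shared across the pipeline.

The central object is :class:`IndicatorDataset`, a participant-by-variable
table in which every column carries a *role*:

``housing``
    one of the poor-housing-quality indicator scores (size, temperature,
    facilities, decorations, problems, feelings towards the home);
``outcome``
    the depressive-symptom total (CCEI, integer 0--30) -- exactly one
    column may carry this role;
``covariate``
    adjustment variables entering the network and the selection model
    (SES risk, age).

Missing cells are stored as NaN; downstream statistics only ever see NaN
there.  Synthetic cohorts may additionally carry *hidden truth* (the
pre-missingness values and the true selection probabilities).  Hidden truth
is deliberately kept off the normal accessor paths: pipeline stages never
read it, only test harnesses comparing estimates against the planted
ground truth do.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

ROLES = ("housing", "outcome", "covariate")


@dataclass(frozen=True)
class VariableMeta:
    """Name, role and admissible range of one variable."""

    name: str
    role: str
    bounds: Optional[tuple[float, float]] = None
    ordinal: bool = False

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValueError(
                f"role for {self.name!r} must be one of {ROLES}, got {self.role!r}"
            )
        if self.bounds is not None and self.bounds[0] > self.bounds[1]:
            raise ValueError(f"invalid bounds for {self.name!r}: {self.bounds}")


class IndicatorDataset:
    """Participant x variable table with roles, missingness mask and optional
    selection indicator.

    Parameters
    ----------
    values
        DataFrame of shape (n, p); NaN marks a missing cell.
    meta
        One :class:`VariableMeta` per column, in column order or keyed by name.
    selection
        Optional 0/1 Series (the selection indicator S), aligned with rows.
    true_values, true_selection_prob
        Hidden truth for synthetic cohorts; never consumed by pipeline stages.
    """

    def __init__(
        self,
        values: pd.DataFrame,
        meta: Sequence[VariableMeta] | dict[str, VariableMeta],
        selection: Optional[pd.Series] = None,
        true_values: Optional[pd.DataFrame] = None,
        true_selection_prob: Optional[pd.Series] = None,
    ) -> None:
        if isinstance(meta, dict):
            meta_map = dict(meta)
        else:
            meta_map = {m.name: m for m in meta}
        unknown = set(values.columns) - set(meta_map)
        missing = set(meta_map) - set(values.columns)
        if unknown or missing:
            raise ValueError(
                f"role metadata does not cover the table: columns without meta "
                f"{sorted(unknown)}, meta without columns {sorted(missing)}"
            )
        outcomes = [m.name for m in meta_map.values() if m.role == "outcome"]
        if len(outcomes) != 1:
            raise ValueError(
                f"exactly one outcome column required, found {outcomes}"
            )
        self.values = values.astype(float).copy()
        self.meta = {c: meta_map[c] for c in values.columns}
        if selection is not None:
            selection = pd.Series(selection, index=values.index).astype(int)
            bad = set(selection.unique()) - {0, 1}
            if bad:
                raise ValueError(f"selection indicator must be 0/1, found {bad}")
        self.selection = selection
        self._true_values = true_values
        self._true_selection_prob = true_selection_prob
        self._check_bounds()

    # -- structure ---------------------------------------------------------

    @property
    def n(self) -> int:
        return len(self.values)

    @property
    def p(self) -> int:
        return self.values.shape[1]

    @property
    def columns(self) -> list[str]:
        return list(self.values.columns)

    def columns_with_role(self, role: str) -> list[str]:
        return [c for c, m in self.meta.items() if m.role == role]

    @property
    def housing_columns(self) -> list[str]:
        return self.columns_with_role("housing")

    @property
    def outcome_column(self) -> str:
        return self.columns_with_role("outcome")[0]

    @property
    def covariate_columns(self) -> list[str]:
        return self.columns_with_role("covariate")

    @property
    def mask(self) -> pd.DataFrame:
        """Boolean missingness mask (True = missing)."""
        return self.values.isna()

    @property
    def is_complete(self) -> bool:
        return not bool(self.values.isna().any().any())

    # -- hidden truth (test harness only) ----------------------------------

    @property
    def hidden_truth(self) -> Optional[pd.DataFrame]:
        """Pre-missingness values, if this is a synthetic cohort.

        Reserved for test harnesses; pipeline stages must not read it.
        """
        return self._true_values

    @property
    def hidden_selection_prob(self) -> Optional[pd.Series]:
        """True P(S=1 | x) used to draw the selection indicator, if synthetic."""
        return self._true_selection_prob

    # -- helpers -----------------------------------------------------------

    def _check_bounds(self) -> None:
        for c, m in self.meta.items():
            if m.bounds is None:
                continue
            col = self.values[c].dropna()
            lo, hi = m.bounds
            if len(col) and (col.min() < lo - 1e-9 or col.max() > hi + 1e-9):
                raise ValueError(
                    f"column {c!r} violates bounds {m.bounds}: observed range "
                    f"[{col.min()}, {col.max()}]"
                )

    def replace_values(
        self,
        values: pd.DataFrame,
        *,
        selection: Optional[pd.Series] = "inherit",  # type: ignore[assignment]
        keep_truth: bool = True,
    ) -> "IndicatorDataset":
        """Return a copy of this dataset with a new value table."""
        if isinstance(selection, str) and selection == "inherit":
            selection = None
            if self.selection is not None:
                selection = self.selection.reindex(values.index)
        tv = self._true_values
        tp = self._true_selection_prob
        if keep_truth:
            if tv is not None:
                tv = tv.reindex(values.index)
            if tp is not None:
                tp = tp.reindex(values.index)
        else:
            tv, tp = None, None
        return IndicatorDataset(
            values, self.meta, selection=selection,
            true_values=tv, true_selection_prob=tp,
        )

    def subset_rows(self, index: Iterable) -> "IndicatorDataset":
        idx = pd.Index(index)
        return self.replace_values(self.values.loc[idx])

    def take_rows(self, positions: np.ndarray) -> "IndicatorDataset":
        """Positional row resample (rows may repeat); the index is reset.

        Selection indicator and hidden truth are carried along row-wise, so
        bootstrap resamples stay internally aligned.
        """
        pos = np.asarray(positions)
        values = self.values.iloc[pos].reset_index(drop=True)
        selection = None
        if self.selection is not None:
            selection = self.selection.iloc[pos].reset_index(drop=True)
        tv = self._true_values
        if tv is not None:
            tv = tv.iloc[pos].reset_index(drop=True)
        tp = self._true_selection_prob
        if tp is not None:
            tp = tp.iloc[pos].reset_index(drop=True)
        return IndicatorDataset(
            values, self.meta, selection=selection,
            true_values=tv, true_selection_prob=tp,
        )

    def __repr__(self) -> str:  # pragma: no cover
        sel = "with S" if self.selection is not None else "no S"
        return f"IndicatorDataset(n={self.n}, p={self.p}, {sel})"


@dataclass
class CorrelationMatrix:
    """Symmetric correlation matrix with provenance.

    ``n_effective`` is the Kish effective sample size (sum w)^2 / sum w^2 of
    the weights that produced the matrix (equal to the row count when the
    weights are uniform).
    """

    values: np.ndarray
    labels: list[str]
    n_effective: float
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("correlation matrix must be square")
        if len(self.labels) != v.shape[0]:
            raise ValueError("label count does not match matrix dimension")
        if not np.allclose(v, v.T, atol=1e-10):
            raise ValueError("correlation matrix must be symmetric")
        if not np.allclose(np.diag(v), 1.0, atol=1e-10):
            raise ValueError("correlation matrix must have unit diagonal")
        if np.any(np.abs(v) > 1 + 1e-10):
            raise ValueError("correlation entries must lie in [-1, 1]")
        self.values = v

    @property
    def p(self) -> int:
        return self.values.shape[0]

    @property
    def is_positive_definite(self) -> bool:
        return bool(np.linalg.eigvalsh(self.values).min() > 0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)


@dataclass
class WeightVector:
    """Per-participant stabilized inverse-probability weights.

    ``weights`` is aligned with the dataset rows the vector was built for.
    ``marginal_prob`` is mean(S) on the estimation sample.  ``mode`` records
    whether rows with S=0 were zeroed out ("selected") or every analyzed row
    received the stabilized formula at its covariates ("analyzed").
    """

    weights: pd.Series
    marginal_prob: float
    mode: str = "analyzed"
    truncation_quantiles: Optional[tuple[float, float]] = None

    def __post_init__(self) -> None:
        if (self.weights < 0).any():
            raise ValueError("stabilized weights must be nonnegative")
        if self.mode not in ("analyzed", "selected"):
            raise ValueError(f"unknown weight mode {self.mode!r}")

    @property
    def nonzero_mean(self) -> float:
        nz = self.weights[self.weights > 0]
        return float(nz.mean()) if len(nz) else float("nan")

    def to_numpy(self) -> np.ndarray:
        return self.weights.to_numpy(dtype=float)
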