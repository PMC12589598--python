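"""Cohort CSV dialect and run-artifact writers.

Cohorts travel as plain CSV: header row of variable names, one row per
participant, empty cell = missing, UTF-8.  An optional ``S`` column holds
the selection indicator.  Variable roles and bounds live in a JSON sidecar
(written next to the CSV as ``<name>.meta.json``) or are supplied
explicitly on read.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .datatypes import IndicatorDataset, VariableMeta

SELECTION_COLUMN = "S"


def _meta_to_dict(meta: dict[str, VariableMeta]) -> dict:
    return {
        name: {
            "role": m.role,
            "bounds": list(m.bounds) if m.bounds is not None else None,
            "ordinal": m.ordinal,
        }
        for name, m in meta.items()
    }


def _meta_from_dict(d: dict) -> list[VariableMeta]:
    return [
        VariableMeta(
            name,
            spec["role"],
            bounds=tuple(spec["bounds"]) if spec.get("bounds") else None,
            ordinal=bool(spec.get("ordinal", False)),
        )
        for name, spec in d.items()
    ]


def write_cohort_csv(data: IndicatorDataset, path) -> None:
    """Write the cohort plus its ``.meta.json`` sidecar."""
    path = Path(path)
    out = data.values.copy()
    if data.selection is not None:
        out[SELECTION_COLUMN] = data.selection
    out.to_csv(path, index=False)
    sidecar = {
        "variables": _meta_to_dict(data.meta),
        "has_selection": data.selection is not None,
    }
    path.with_suffix(path.suffix + ".meta.json").write_text(
        json.dumps(sidecar, indent=2)
    )


def read_cohort_csv(path, roles: Optional[dict] = None) -> IndicatorDataset:
    """Read a cohort CSV; roles come from the sidecar unless supplied.

    ``roles`` maps column name to either a role string or a dict with
    ``role`` / ``bounds`` / ``ordinal`` keys.  Non-numeric cells and columns
    without a role are reported with their coordinates.
    """
    path = Path(path)
    df = pd.read_csv(path)
    if df.empty:
        raise ValueError(f"{path}: empty cohort file")

    selection = None
    if SELECTION_COLUMN in df.columns:
        selection = df[SELECTION_COLUMN]
        df = df.drop(columns=[SELECTION_COLUMN])

    for c in df.columns:
        col = pd.to_numeric(df[c], errors="coerce")
        bad = col.isna() & df[c].notna()
        if bad.any():
            row = int(bad.idxmax())
            raise ValueError(
                f"{path}: non-numeric cell at row {row}, column {c!r}: {df[c][row]!r}"
            )
        df[c] = col

    if roles is None:
        sidecar = path.with_suffix(path.suffix + ".meta.json")
        if not sidecar.exists():
            raise ValueError(f"{path}: no roles supplied and no sidecar {sidecar.name}")
        meta = _meta_from_dict(json.loads(sidecar.read_text())["variables"])
    else:
        meta = []
        for c in df.columns:
            if c not in roles:
                raise ValueError(f"{path}: no role supplied for column {c!r}")
            spec = roles[c]
            if isinstance(spec, str):
                meta.append(VariableMeta(c, spec))
            else:
                meta.append(
                    VariableMeta(
                        c,
                        spec["role"],
                        bounds=tuple(spec["bounds"]) if spec.get("bounds") else None,
                        ordinal=bool(spec.get("ordinal", False)),
                    )
                )
        extra = set(roles) - set(df.columns)
        if extra:
            raise ValueError(f"{path}: role map names unknown column(s) {sorted(extra)}")
    return IndicatorDataset(df, meta, selection=selection)


def write_matrix_csv(values: np.ndarray, labels, path) -> None:
    pd.DataFrame(values, index=labels, columns=labels).to_csv(path, index_label="node")


def write_json(obj: dict, path) -> None:
    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.bool_,)):
            return bool(o)
        raise TypeError(f"not JSON serializable: {type(o)}")

    Path(path).write_text(json.dumps(obj, indent=2, default=default, sort_keys=True))
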