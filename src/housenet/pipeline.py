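"""End-to-end orchestration: cohort -> filter -> MAR report -> imputation ->
IPW -> pooled weighted Spearman -> EBICglasso -> centralities -> bootstraps.

A :class:`PipelineConfig` fully determines a run; every run writes the
resolved config next to its outputs so it can be reproduced exactly.  The
single run seed fans out to per-stage seeds through numpy seed sequences
keyed by a fixed stage index (documented in ``STAGE_SEEDS``), so any stage
can be re-run in isolation with the same stream.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import synthetic
from .association import (
    nearest_positive_definite,
    pool_correlations,
    weighted_spearman_matrix,
)
from .centrality import METRICS, centrality_table
from .datatypes import IndicatorDataset
from .ggm import estimate_network, network_summary
from .io import read_cohort_csv, write_cohort_csv, write_json, write_matrix_csv
from .missingness import impute_chained, inclusion_filter, mar_diagnostics
from .selection import fit_selection_model, stabilized_weights, uniform_weights
from .stability import (
    DEFAULT_DROP_GRID,
    bootstrap_edges,
    casedrop_bootstrap,
    cs_coefficient,
    edge_difference_test,
)

log = logging.getLogger("housenet")

#: stage name -> spawn index used to derive that stage's seed from the run seed
STAGE_SEEDS = {
    "simulate": 1,
    "missingness": 2,
    "selection": 3,
    "impute": 4,
    "bootstrap": 5,
    "casedrop": 6,
}


def stage_seed(run_seed: int, stage: str) -> int:
    """Derived per-stage integer seed (stable, below 2**31)."""
    ss = np.random.SeedSequence(entropy=run_seed, spawn_key=(STAGE_SEEDS[stage],))
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class PipelineConfig:
    """Fully resolved settings of one analysis run.

    Defaults follow the study settings where stated: 50% housing-item
    completeness for inclusion, EBIC gamma 0.5, 1,000 bootstrap resamples
    with 95% CIs, stabilized IPW with age and SES risk as selection
    predictors.
    """

    # input: either a cohort CSV or a synthetic cohort
    input_csv: Optional[str] = None
    roles: Optional[dict] = None
    synthetic_n: int = 9669
    synthetic_missing_rate: float = 0.10
    synthetic_missing_mechanism: str = "MAR"
    synthetic_selection: bool = True

    # stages
    min_complete_fraction: float = 0.5
    n_imputations: int = 5
    imputation_iterations: int = 10
    pool_imputations: bool = True
    ipw: bool = True
    selection_predictors: tuple[str, ...] = ("age", "ses_risk")
    weight_mode: str = "analyzed"
    gamma: float = 0.5
    n_lambdas: int = 100
    lambda_min_ratio: float = 0.01
    bootstrap_B: int = 1000
    casedrop_B: int = 1000
    drop_grid: tuple[float, ...] = DEFAULT_DROP_GRID
    cs_cor_threshold: float = 0.7
    cs_prob: float = 0.95
    ci_level: float = 0.95
    metrics: tuple[str, ...] = METRICS

    seed: int = 0
    output_dir: str = "housenet_run"
    run_bootstrap: bool = True
    run_casedrop: bool = True

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        names = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - names
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        for key in ("selection_predictors", "drop_grid", "metrics"):
            setattr(cfg, key, tuple(getattr(cfg, key)))
        return cfg

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for key in ("selection_predictors", "drop_grid", "metrics"):
            d[key] = list(d[key])
        return d


def _load_input(config: PipelineConfig) -> IndicatorDataset:
    if config.input_csv is not None:
        data = read_cohort_csv(config.input_csv, roles=config.roles)
        log.info("read cohort %s: n=%d, p=%d", config.input_csv, data.n, data.p)
        return data
    spec = synthetic.default_precision_spec()
    marginals = synthetic.default_marginals()
    data = synthetic.simulate_cohort(
        spec, marginals, config.synthetic_n, seed=stage_seed(config.seed, "simulate")
    )
    if config.synthetic_selection:
        sspec = synthetic.SelectionSpec(
            intercept=1.0, coefficients={"age": -0.5, "ses_risk": 0.5}
        )
        data = synthetic.impose_selection(
            data, sspec, seed=stage_seed(config.seed, "selection")
        )
    if config.synthetic_missing_rate > 0:
        mspec = synthetic.MissingnessSpec(
            mechanism=config.synthetic_missing_mechanism,
            target_variables=tuple(data.housing_columns) + (data.outcome_column,),
            overall_rate=config.synthetic_missing_rate,
            driver_variables=("age", "ses_risk"),
            driver_coefficients=(0.3, 0.5),
        )
        data = synthetic.impose_missingness(
            data, mspec, seed=stage_seed(config.seed, "missingness")
        )
    log.info("simulated cohort: n=%d, p=%d", data.n, data.p)
    return data


def _derive_selection_indicator(data: IndicatorDataset) -> IndicatorDataset:
    """S = 1 iff all housing indicators are complete (pre-imputation)."""
    s = (~data.values[data.housing_columns].isna().any(axis=1)).astype(int)
    return IndicatorDataset(
        data.values,
        data.meta,
        selection=s,
        true_values=data.hidden_truth,
        true_selection_prob=data.hidden_selection_prob,
    )


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full analysis and write all artifacts to ``output_dir``.

    Returns the in-memory artifacts (network, centralities, summaries).
    Any stage failure aborts with the stage name attached.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_json(config.to_dict(), out / "config.resolved.json")

    artifacts: dict = {"config": config}
    stage = "input"
    try:
        data = _load_input(config)
        write_cohort_csv(data, out / "cohort.csv")

        stage = "inclusion_filter"
        filtered = inclusion_filter(data, config.min_complete_fraction)
        log.info("inclusion filter: %d of %d rows retained", filtered.n, data.n)

        stage = "mar_diagnostics"
        mar = mar_diagnostics(
            data,
            compare_on=[c for c in data.covariate_columns if not data.values[c].isna().any()],
            min_complete_fraction=config.min_complete_fraction,
        )
        mar.table.to_csv(out / "mar_report.csv")
        write_json(mar.to_json_dict(), out / "mar_report.json")
        artifacts["mar_report"] = mar

        stage = "selection_indicator"
        if filtered.selection is None:
            filtered = _derive_selection_indicator(filtered)

        stage = "imputation"
        if filtered.is_complete:
            completed = [filtered]
            log.info("no missing cells; imputation skipped")
        else:
            completed = impute_chained(
                filtered,
                n_imputations=config.n_imputations,
                n_iterations=config.imputation_iterations,
                seed=stage_seed(config.seed, "impute"),
            )
            log.info("imputed %d completed datasets", len(completed))
        if not config.pool_imputations:
            completed = completed[:1]

        stage = "selection_weights"
        if config.ipw and filtered.selection is not None and filtered.selection.nunique() == 2:
            model = fit_selection_model(completed[0], config.selection_predictors)
            weights = stabilized_weights(model, completed[0], mode=config.weight_mode)
            write_json(model.to_json_dict(), out / "selection_model.json")
            artifacts["selection_model"] = model
        else:
            weights = uniform_weights(filtered)
            log.info("IPW disabled or S unavailable; uniform weights")
        weights.weights.rename("weight").to_csv(out / "weights.csv", index_label="row")
        artifacts["weights"] = weights

        stage = "correlation"
        mats = [weighted_spearman_matrix(d, weights) for d in completed]
        pooled = pool_correlations(mats)
        pooled = nearest_positive_definite(pooled)
        write_matrix_csv(pooled.values, pooled.labels, out / "correlation.csv")
        artifacts["correlation"] = pooled

        stage = "network"
        net, path = estimate_network(
            pooled,
            n=completed[0].n,
            gamma=config.gamma,
            n_lambdas=config.n_lambdas,
            lambda_min_ratio=config.lambda_min_ratio,
        )
        summary = network_summary(net)
        write_matrix_csv(net.weights, net.labels, out / "adjacency.csv")
        net.edge_list().to_csv(out / "edges.csv", index=False)
        path.to_frame().to_csv(out / "regularization_path.csv", index=False)
        log.info(
            "network: %d/%d nonzero edges at lambda=%.4g",
            summary["nonzero_edges"], summary["possible_edges"], net.lambda_,
        )
        artifacts["network"] = net
        artifacts["network_summary"] = summary

        stage = "centrality"
        cent = centrality_table(net, config.metrics, zscore=True)
        cent.to_csv(out / "centrality.csv")
        artifacts["centrality"] = cent

        analysis = completed[0]
        boot_summary = None
        if config.run_bootstrap:
            stage = "bootstrap_edges"
            boot = bootstrap_edges(
                analysis,
                weights,
                B=config.bootstrap_B,
                seed=stage_seed(config.seed, "bootstrap"),
                gamma=config.gamma,
                n_lambdas=config.n_lambdas,
                lambda_min_ratio=config.lambda_min_ratio,
                ci_level=config.ci_level,
            )
            boot.to_frame().to_csv(out / "bootstrap_edges.csv", index=False)
            diff = edge_difference_test(boot)
            diff.to_csv(out / "edge_difference.csv")
            artifacts["bootstrap"] = boot
            artifacts["edge_difference"] = diff
            ci = boot.ci
            boot_summary = {
                "B": boot.n_resamples,
                "edges_ci_excluding_zero": int(((ci[:, 0] > 0) | (ci[:, 1] < 0)).sum()),
            }

        cs = None
        if config.run_casedrop:
            stage = "casedrop_bootstrap"
            stab = casedrop_bootstrap(
                analysis,
                weights,
                metrics=config.metrics,
                drop_grid=config.drop_grid,
                B=config.casedrop_B,
                seed=stage_seed(config.seed, "casedrop"),
                gamma=config.gamma,
                n_lambdas=config.n_lambdas,
                lambda_min_ratio=config.lambda_min_ratio,
            )
            stab.to_frame().to_csv(out / "stability.csv", index=False)
            cs = cs_coefficient(stab, config.cs_cor_threshold, config.cs_prob)
            write_json(cs, out / "cs_coefficients.json")
            artifacts["stability"] = stab
            artifacts["cs"] = cs

        stage = "summary"
        ei = cent["expected_influence"].sort_values(ascending=False)
        run_summary = {
            "seed": config.seed,
            "n_input": data.n,
            "n_analyzed": analysis.n,
            "edge_weights": {
                k: summary[k]
                for k in (
                    "possible_edges", "nonzero_edges", "mean_weight",
                    "sd_weight", "min_weight", "max_weight",
                )
            },
            "selected_lambda": net.lambda_,
            "gamma": config.gamma,
            "top_edges": net.edge_list()
            .assign(abs_weight=lambda d: d.weight.abs())
            .nlargest(5, "abs_weight")
            .drop(columns="abs_weight")
            .to_dict(orient="records"),
            "expected_influence_ranking": {k: float(v) for k, v in ei.items()},
            "cs_coefficients": cs,
            "bootstrap": boot_summary,
            "mar_bias_indicated": mar.bias_indicated,
        }
        write_json(run_summary, out / "summary.json")
        artifacts["summary"] = run_summary
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    return artifacts
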