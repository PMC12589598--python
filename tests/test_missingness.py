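"""Inclusion rule, included-vs-excluded diagnostics, and PMM imputation."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

import housenet as hn
from housenet.datatypes import VariableMeta


def _toy_dataset(housing_rows, outcome=None):
    """Six housing columns from per-row observation patterns (None = missing)."""
    n = len(housing_rows)
    cols = {f"h{i}": [row[i] for row in housing_rows] for i in range(6)}
    cols["dep"] = outcome if outcome is not None else [1.0] * n
    meta = [VariableMeta(f"h{i}", "housing") for i in range(6)]
    meta.append(VariableMeta("dep", "outcome"))
    return hn.IndicatorDataset(pd.DataFrame(cols, dtype=float), meta)


class TestInclusionFilter:
    def test_half_complete_retained_and_below_excluded(self):
        data = _toy_dataset(
            [
                [1, 2, 3, None, None, None],  # 3/6 observed -> retained
                [1, 2, None, None, None, None],  # 2/6 -> excluded
                [1, 2, 3, 4, 5, 6],  # complete -> retained
            ]
        )
        out = hn.inclusion_filter(data, 0.5)
        assert list(out.values.index) == [0, 2]

    def test_fully_observed_cohort_unchanged(self, small_cohort):
        for threshold in (0.01, 0.5, 1.0):
            out = hn.inclusion_filter(small_cohort, threshold)
            pd.testing.assert_frame_equal(out.values, small_cohort.values)

    def test_idempotent(self):
        data = _toy_dataset([[1, 2, 3, None, None, None], [1, None] + [None] * 4])
        once = hn.inclusion_filter(data, 0.5)
        twice = hn.inclusion_filter(once, 0.5)
        pd.testing.assert_frame_equal(once.values, twice.values)

    def test_outcome_missingness_does_not_drive_retention(self):
        data = _toy_dataset([[1, 2, 3, 4, 5, 6]], outcome=[None])
        out = hn.inclusion_filter(data, 1.0)
        assert out.n == 1

    def test_invalid_threshold_rejected(self, small_cohort):
        with pytest.raises(ValueError):
            hn.inclusion_filter(small_cohort, 0.0)


class TestMARDiagnostics:
    def _cohort_with_missingness(self, mechanism, n=20_000, seed=0):
        spec = hn.default_precision_spec()
        data = hn.simulate_cohort(spec, hn.default_marginals(), n, seed=seed)
        # rate chosen so the excluded group is large enough for stable SMDs
        if mechanism == "MCAR":
            mspec = hn.MissingnessSpec("MCAR", tuple(data.housing_columns), 0.35)
        else:
            mspec = hn.MissingnessSpec(
                "MAR", tuple(data.housing_columns), 0.35, ("ses_risk",), (1.5,)
            )
        return hn.impose_missingness(data, mspec, seed=seed + 1)

    def test_mcar_shows_no_bias(self):
        data = self._cohort_with_missingness("MCAR")
        report = hn.missingness.mar_diagnostics(data, ["age", "ses_risk"])
        assert report.table["smd"].abs().max() < 0.05
        assert not report.bias_indicated

    def test_planted_mar_flags_ses_bias(self):
        data = self._cohort_with_missingness("MAR")
        report = hn.missingness.mar_diagnostics(data, ["age", "ses_risk"])
        assert abs(report.table.loc["ses_risk", "smd"]) > 0.1
        assert report.bias_indicated

    def test_empty_excluded_group_flagged_undefined(self, small_cohort):
        report = hn.missingness.mar_diagnostics(small_cohort, ["age"])
        assert np.isnan(report.table.loc["age", "smd"])
        assert not report.bias_indicated


class TestImputeChained:
    def test_complete_data_passes_through(self, small_cohort):
        out = hn.impute_chained(small_cohort, n_imputations=3, seed=1)
        assert len(out) == 3
        for d in out:
            pd.testing.assert_frame_equal(d.values, small_cohort.values)

    def test_deterministic_under_seed(self, small_cohort):
        mspec = hn.MissingnessSpec("MCAR", ("size", "feelings"), 0.2)
        data = hn.impose_missingness(small_cohort, mspec, seed=5)
        a = hn.impute_chained(data, n_imputations=2, seed=9)
        b = hn.impute_chained(data, n_imputations=2, seed=9)
        for x, y in zip(a, b):
            pd.testing.assert_frame_equal(x.values, y.values)

    def test_observed_cells_never_altered(self, small_cohort):
        mspec = hn.MissingnessSpec("MCAR", ("size",), 0.3)
        data = hn.impose_missingness(small_cohort, mspec, seed=5)
        out = hn.impute_chained(data, n_imputations=1, seed=6)[0]
        obs = ~data.mask["size"]
        assert (out.values.loc[obs, "size"] == data.values.loc[obs, "size"]).all()
        assert out.is_complete

    def test_pmm_imputes_onto_observed_support(self, small_cohort):
        mspec = hn.MissingnessSpec("MCAR", ("depressive_symptoms",), 0.3)
        data = hn.impose_missingness(small_cohort, mspec, seed=15)
        out = hn.impute_chained(data, n_imputations=2, seed=16)
        observed = set(data.values["depressive_symptoms"].dropna())
        for d in out:
            imputed = set(d.values.loc[data.mask["depressive_symptoms"], "depressive_symptoms"])
            assert imputed <= observed

    def test_near_deterministic_pair_recovers_hidden_truth(self):
        # latent r = 0.99 between two variables; a single missing cell should
        # land near its hidden truth in nearly all replicates.  A donor-based
        # imputation carries the donor's own conditional noise, so the error
        # scale is sqrt(2) x the conditional residual SD -- far below the
        # marginal SD (1.0 here); we require the error to stay within half a
        # marginal SD, i.e. the imputation tracks the conditional mean rather
        # than the marginal distribution.
        spec = hn.make_precision_spec(3, [(0, 1, 0.99)], node_labels=("a", "b", "c"))
        roles = {"a": "housing", "b": "housing", "c": "outcome"}
        from scipy.stats import norm

        marg = hn.MarginalSpec(
            {n: hn.Marginal("continuous", norm().ppf, (-6.0, 6.0)) for n in "abc"}
        )
        data = hn.simulate_cohort(spec, marg, 5_000, seed=77, roles=roles)
        resid_sd = float(
            np.sqrt(1.0 / np.linalg.inv(np.cov(data._latent.to_numpy().T))[0, 0])
        )
        marginal_sd = float(data.values["a"].std())
        assert resid_sd < 0.2 * marginal_sd  # the pair really is near-deterministic
        values = data.values.copy()
        truth = values.iloc[0]["a"]
        values.iloc[0, values.columns.get_loc("a")] = np.nan
        masked = data.replace_values(values)
        errors = []
        for rep in range(100):
            out = hn.impute_chained(masked, n_imputations=1, n_iterations=3, seed=rep)[0]
            errors.append(abs(out.values.iloc[0]["a"] - truth))
        hits = sum(e <= 0.5 * marginal_sd for e in errors)
        assert hits >= 90
        assert np.median(errors) <= 3 * resid_sd

    def test_mcar_imputation_preserves_rank_structure(self):
        spec = hn.default_precision_spec()
        diffs = []
        for seed in range(10):
            data = hn.simulate_cohort(spec, hn.default_marginals(), 10_000, seed=100 + seed)
            mspec = hn.MissingnessSpec(
                "MCAR", tuple(data.housing_columns) + ("depressive_symptoms",), 0.2
            )
            masked = hn.impose_missingness(data, mspec, seed=200 + seed)
            completed = hn.impute_chained(masked, n_imputations=1, seed=300 + seed)[0]
            full = spearmanr(data.values.to_numpy()).statistic
            imp = spearmanr(completed.values.to_numpy()).statistic
            diffs.append(np.abs(full - imp).max())
        assert max(diffs) < 0.05

    def test_fully_missing_column_named_in_error(self, small_cohort):
        values = small_cohort.values.copy()
        values["temperature"] = np.nan
        data = small_cohort.replace_values(values)
        with pytest.raises(ValueError, match="temperature"):
            hn.impute_chained(data, seed=1)
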