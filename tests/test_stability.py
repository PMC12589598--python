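"""Bootstrap CIs, edge-difference tests, case-drop stability and the CS
coefficient."""

import numpy as np
import pytest

import housenet as hn
from housenet.stability import StabilityResult, cs_coefficient


def _cohort_with_edges(edges, n=2000, seed=0, labels=None):
    p = max(max(i, j) for i, j, _ in edges) + 1
    labels = labels or [f"v{i}" for i in range(p)]
    spec = hn.make_precision_spec(p, edges, node_labels=labels)
    from scipy.stats import norm

    marg = hn.MarginalSpec(
        {l: hn.Marginal("continuous", norm().ppf, (-6.0, 6.0)) for l in labels}
    )
    roles = {l: "housing" for l in labels[:-1]}
    roles[labels[-1]] = "outcome"
    return hn.simulate_cohort(spec, marg, n, seed=seed, roles=roles)


class TestBootstrapEdges:
    def test_bit_reproducible_under_seed(self, small_cohort):
        a = hn.bootstrap_edges(small_cohort, B=20, seed=5, n_lambdas=20)
        b = hn.bootstrap_edges(small_cohort, B=20, seed=5, n_lambdas=20)
        assert np.array_equal(a.samples, b.samples)
        assert np.array_equal(a.point_estimates, b.point_estimates)

    def test_strong_edge_ci_excludes_zero(self):
        data = _cohort_with_edges([(0, 1, 0.4), (1, 2, 0.15)], n=2000, seed=1)
        boot = hn.bootstrap_edges(data, B=100, seed=2, n_lambdas=30)
        idx = boot.edge_labels.index(("v0", "v1"))
        lo, hi = boot.ci[idx]
        assert lo > 0

    def test_null_edge_bootstrap_mean_near_zero(self):
        data = _cohort_with_edges([(0, 1, 0.4), (1, 2, 0.15)], n=2000, seed=3)
        boot = hn.bootstrap_edges(data, B=100, seed=4, n_lambdas=30)
        idx = boot.edge_labels.index(("v0", "v2"))  # planted zero
        assert abs(boot.bootstrap_mean[idx]) < 0.03

    def test_ci_ordering_invariant(self, small_cohort):
        boot = hn.bootstrap_edges(small_cohort, B=25, seed=6, n_lambdas=20)
        ci = boot.ci
        assert (ci[:, 0] <= ci[:, 1]).all()


class TestEdgeDifferenceTest:
    def test_self_comparison_never_significant(self, small_cohort):
        boot = hn.bootstrap_edges(small_cohort, B=110, seed=7, n_lambdas=20)
        sig = hn.edge_difference_test(boot)
        assert not np.diag(sig.to_numpy()).any()
        assert np.array_equal(sig.to_numpy(), sig.to_numpy().T)

    def test_clearly_different_edges_flagged(self):
        data = _cohort_with_edges([(0, 1, 0.4), (1, 2, 0.05)], n=2000, seed=8)
        boot = hn.bootstrap_edges(data, B=150, seed=9, n_lambdas=30)
        sig = hn.edge_difference_test(boot)
        assert sig.loc["v0--v1", "v1--v2"]

    def test_equal_planted_edges_rarely_flagged(self):
        hits = 0
        for seed in range(10):
            data = _cohort_with_edges([(0, 1, 0.3), (1, 2, 0.3)], n=2000, seed=100 + seed)
            boot = hn.bootstrap_edges(data, B=120, seed=200 + seed, n_lambdas=30)
            sig = hn.edge_difference_test(boot)
            hits += bool(sig.loc["v0--v1", "v1--v2"])
        assert hits <= 1

    def test_too_few_resamples_rejected(self, small_cohort):
        boot = hn.bootstrap_edges(small_cohort, B=50, seed=10, n_lambdas=20)
        with pytest.raises(ValueError):
            hn.edge_difference_test(boot, alpha=0.05)


class TestCasedropBootstrap:
    def test_zero_drop_correlates_perfectly(self, small_cohort):
        res = hn.casedrop_bootstrap(
            small_cohort,
            metrics=("expected_influence", "strength"),
            drop_grid=(0.0, 0.3),
            B=5,
            seed=11,
            n_lambdas=20,
        )
        assert np.allclose(res.correlations["expected_influence"][0], 1.0)

    def test_bit_reproducible_under_seed(self, small_cohort):
        kwargs = dict(
            metrics=("strength",), drop_grid=(0.2, 0.5), B=6, seed=12, n_lambdas=20
        )
        a = hn.casedrop_bootstrap(small_cohort, **kwargs)
        b = hn.casedrop_bootstrap(small_cohort, **kwargs)
        assert np.array_equal(
            a.correlations["strength"], b.correlations["strength"], equal_nan=True
        )

    def test_tiny_subsample_proportions_skipped(self, small_cohort):
        with pytest.warns(UserWarning, match="skipped"):
            res = hn.casedrop_bootstrap(
                small_cohort,
                metrics=("strength",),
                drop_grid=(0.5, 0.999),
                B=3,
                seed=13,
                n_lambdas=20,
            )
        assert res.drop_grid == (0.5,)

    def test_strong_structure_is_stable_at_quarter_drop(self):
        data = _cohort_with_edges(
            [(0, 1, 0.35), (1, 2, 0.3), (2, 3, 0.25), (0, 3, -0.2), (1, 3, 0.15)],
            n=4000,
            seed=14,
        )
        res = hn.casedrop_bootstrap(
            data,
            metrics=("expected_influence",),
            drop_grid=(0.25,),
            B=40,
            seed=15,
            n_lambdas=30,
        )
        assert res.frac_above("expected_influence")[0] >= 0.95

    def test_pure_noise_centralities_unstable(self):
        data = _cohort_with_edges([(0, 1, 0.0)], n=1500, seed=16)  # independence
        res = hn.casedrop_bootstrap(
            data,
            metrics=("strength",),
            drop_grid=(0.5,),
            B=40,
            seed=17,
            n_lambdas=20,
        )
        c = res.correlations["strength"][0]
        # mostly nan (empty networks) or small correlations
        assert res.frac_above("strength")[0] < 0.5


class TestCSCoefficient:
    def _result(self, frac_by_drop, B=100):
        """Hand-built stability table: per drop, the fraction of subsamples
        whose correlation clears 0.7."""
        drops = tuple(sorted(frac_by_drop))
        cors = np.empty((len(drops), B))
        for i, d in enumerate(drops):
            k = int(round(frac_by_drop[d] * B))
            cors[i, :k] = 0.9
            cors[i, k:] = 0.1
        return StabilityResult(
            drop_grid=drops, metrics=("strength",), correlations={"strength": cors}
        )

    def test_perfectly_stable_gives_grid_max(self):
        res = self._result({d: 1.0 for d in (0.1, 0.3, 0.5, 0.7, 0.9)})
        assert cs_coefficient(res)["strength"] == 0.9

    def test_never_stable_gives_zero(self):
        res = self._result({0.1: 0.5, 0.3: 0.2})
        assert cs_coefficient(res)["strength"] == 0.0

    def test_hand_built_table_definition(self):
        # passes at 0.05..0.30, fails at 0.35 -> CS = 0.30
        frac = {round(d, 2): 1.0 for d in np.arange(0.05, 0.31, 0.05)}
        frac[0.35] = 0.80
        frac[0.40] = 1.0  # later recovery must NOT count
        res = self._result(frac)
        assert cs_coefficient(res)["strength"] == 0.30

    def test_exact_prob_boundary_counts_as_pass(self):
        res = self._result({0.1: 0.95, 0.2: 0.94})
        assert cs_coefficient(res, prob=0.95)["strength"] == 0.1

    def test_monotone_in_threshold_and_prob(self, small_cohort):
        res = hn.casedrop_bootstrap(
            small_cohort,
            metrics=("expected_influence",),
            drop_grid=(0.1, 0.3, 0.5, 0.7),
            B=15,
            seed=18,
            n_lambdas=20,
        )
        for metric in res.metrics:
            loose = cs_coefficient(res, cor_threshold=0.5, prob=0.8)[metric]
            mid = cs_coefficient(res, cor_threshold=0.7, prob=0.8)[metric]
            tight = cs_coefficient(res, cor_threshold=0.7, prob=0.95)[metric]
            assert loose >= mid >= tight

    def test_single_drop_proportion_rejected(self):
        res = self._result({0.1: 1.0})
        with pytest.raises(ValueError):
            cs_coefficient(res)
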