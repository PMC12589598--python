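"""Graphical lasso, EBIC, path selection and network summaries."""

import numpy as np
import pytest

import housenet as hn
from housenet.datatypes import CorrelationMatrix
from housenet.ggm import (
    ZERO_TOL,
    ebic_score,
    edge_count,
    glasso_fit,
    glasso_objective,
    partial_correlations,
)

from _oracles import glasso_bruteforce, glasso_closed_form_p2, random_pd_corr


class TestGlassoFit:
    def test_zero_penalty_is_unpenalized_inverse(self):
        rng = np.random.default_rng(1)
        r = random_pd_corr(5, rng)
        k = glasso_fit(r, 0.0)
        assert np.allclose(k, np.linalg.inv(r), atol=1e-10)

    def test_penalty_above_max_correlation_gives_diagonal(self):
        r = np.array([[1, 0.4, 0.2], [0.4, 1, -0.3], [0.2, -0.3, 1.0]])
        k = glasso_fit(r, 0.4)
        assert edge_count(k) == 0
        assert np.allclose(np.diag(k), 1.0, atol=1e-6)

    def test_two_node_closed_form_across_penalties(self):
        rng = np.random.default_rng(2)
        for _ in range(25):
            r12 = float(rng.uniform(-0.9, 0.9))
            r = np.array([[1.0, r12], [r12, 1.0]])
            for lam in (0.0, 0.05, 0.2):
                k = glasso_fit(r, lam, tol=1e-9)
                assert np.allclose(k, glasso_closed_form_p2(r12, lam), atol=1e-6)

    def test_three_node_matches_generic_optimizer(self):
        rng = np.random.default_rng(3)
        for _ in range(5):
            r = random_pd_corr(3, rng)
            for lam in (0.05, 0.2):
                k = glasso_fit(r, lam, tol=1e-9)
                obj_oracle, k_oracle = glasso_bruteforce(r, lam, restarts=4)
                assert glasso_objective(k, r, lam) == pytest.approx(obj_oracle, abs=1e-4)
                assert np.abs(k - k_oracle).max() < 1e-3

    def test_result_exactly_symmetric_with_exact_zeros(self):
        rng = np.random.default_rng(4)
        r = random_pd_corr(6, rng)
        k = glasso_fit(r, 0.3)
        assert np.array_equal(k, k.T)
        off = k[~np.eye(6, dtype=bool)]
        assert np.all((off == 0) | (np.abs(off) > ZERO_TOL))

    def test_non_pd_input_directs_to_repair(self):
        v = np.array([[1.0, 0.9, 0.0], [0.9, 1.0, 0.9], [0.0, 0.9, 1.0]])
        with pytest.raises(ValueError, match="nearest_positive_definite"):
            glasso_fit(v, 0.1)

    def test_negative_penalty_rejected(self):
        with pytest.raises(ValueError):
            glasso_fit(np.eye(2), -0.1)


class TestEbicScore:
    def _setup(self):
        rng = np.random.default_rng(5)
        r = random_pd_corr(4, rng)
        k = glasso_fit(r, 0.1)
        return r, k

    def test_gamma_zero_equals_classical_bic(self):
        r, k = self._setup()
        n = 500
        sign, logdet = np.linalg.slogdet(k)
        loglik = (n / 2) * (logdet - np.trace(r @ k))
        bic = -2 * loglik + edge_count(k) * np.log(n)
        assert ebic_score(k, r, n, gamma=0.0) == pytest.approx(bic, abs=1e-10)

    def test_empty_model_independent_of_gamma(self):
        r, _ = self._setup()
        k = glasso_fit(r, 1.0)  # diagonal
        assert edge_count(k) == 0
        vals = {ebic_score(k, r, 500, gamma=g) for g in (0.0, 0.25, 0.5, 1.0)}
        assert len(vals) == 1
        sign, logdet = np.linalg.slogdet(k)
        assert vals.pop() == pytest.approx(-2 * (500 / 2) * (logdet - np.trace(r @ k)))

    def test_gamma_difference_is_linear_in_edges(self):
        r, k = self._setup()
        e, p = edge_count(k), r.shape[0]
        d = ebic_score(k, r, 500, 0.5) - ebic_score(k, r, 500, 0.25)
        assert d == pytest.approx(4 * e * 0.25 * np.log(p), abs=1e-10)

    def test_small_n_rejected(self):
        r, k = self._setup()
        with pytest.raises(ValueError):
            ebic_score(k, r, n=4)


class TestEstimateNetwork:
    def test_identity_correlation_gives_empty_network(self):
        corr = CorrelationMatrix(np.eye(9), list("abcdefghi"), 1000)
        net, _ = hn.estimate_network(corr, n=1000)
        assert np.all(net.weights == 0)
        assert net.n_possible_edges == 36

    def test_two_node_weight_is_soft_thresholded_correlation(self):
        corr = CorrelationMatrix(
            np.array([[1.0, 0.6], [0.6, 1.0]]), ["a", "b"], 10_000
        )
        net, path = hn.estimate_network(corr, n=10_000, gamma=0.5)
        # for p=2 the glasso solution is W12 = r - lambda, whose partial
        # correlation is exactly r - lambda
        assert edge_count(net.precision) == 1
        assert net.weights[0, 1] > 0
        assert net.weights[0, 1] == pytest.approx(0.6 - net.lambda_, abs=1e-6)

    def test_monotone_sparsity_along_path(self, planted_spec, marginals):
        # edge count weakly increases as lambda descends.  On realistic
        # cohort correlation matrices the path is exactly monotone; on very
        # noisy random inputs the lasso active set may drop a single
        # borderline edge (a known property of the solution path), so there
        # we only require boundedness of the flicker.
        for seed in range(3):
            data = hn.simulate_cohort(planted_spec, marginals, 2000, seed=seed)
            corr = hn.weighted_spearman_matrix(data)
            _, path = hn.estimate_network(corr, n=data.n, n_lambdas=40)
            assert np.all(np.diff(path.edge_counts) >= 0)  # lambdas descend
        rng = np.random.default_rng(6)
        for _ in range(5):
            corr = CorrelationMatrix(random_pd_corr(7, rng, dof=40), list("abcdefg"), 500)
            _, path = hn.estimate_network(corr, n=500, n_lambdas=40)
            assert np.all(np.diff(path.edge_counts) >= -1)

    def test_gamma_half_no_denser_than_gamma_zero(self):
        rng = np.random.default_rng(7)
        corr = CorrelationMatrix(random_pd_corr(8, rng, dof=12), list("abcdefgh"), 300)
        net_cons, _ = hn.estimate_network(corr, n=300, gamma=0.5)
        net_lib, _ = hn.estimate_network(corr, n=300, gamma=0.0)
        assert edge_count(net_cons.weights) <= edge_count(net_lib.weights)

    def test_ebic_tie_breaks_to_sparser_model(self):
        # identity input: EBIC equal (empty) along the whole path -> pick
        # the largest penalty
        corr = CorrelationMatrix(np.eye(3), list("abc"), 100)
        net, path = hn.estimate_network(corr, n=100)
        assert net.lambda_ == path.lambdas[0]


class TestNetworkSummary:
    def test_empty_nine_node_network(self):
        corr = CorrelationMatrix(np.eye(9), [f"v{i}" for i in range(9)], 1000)
        net, _ = hn.estimate_network(corr, n=1000)
        s = hn.network_summary(net)
        assert s["possible_edges"] == 36
        assert s["nonzero_edges"] == 0
        assert s["mean_weight"] == 0.0

    def test_single_edge_arithmetic(self):
        w = np.zeros((3, 3))
        w[0, 1] = w[1, 0] = 0.2
        net = hn.GGMNetwork(
            labels=list("abc"), weights=w, lambda_=0.1, ebic=0.0, gamma=0.5, n=100
        )
        s = hn.network_summary(net)
        assert s["possible_edges"] == 3
        assert s["nonzero_edges"] == 1
        assert s["mean_weight"] == pytest.approx(0.2 / 3)
        assert s["max_weight"] == pytest.approx(0.2)
        assert s["strongest_edge_per_node"]["a"] == {"partner": "b", "weight": 0.2}

    def test_min_max_bracket_every_edge(self, clean_cohort):
        corr = hn.weighted_spearman_matrix(clean_cohort)
        net, _ = hn.estimate_network(corr, n=clean_cohort.n)
        s = hn.network_summary(net)
        iu = np.triu_indices(net.p, k=1)
        assert s["min_weight"] <= net.weights[iu].min()
        assert s["max_weight"] >= net.weights[iu].max()


class TestPartialCorrelations:
    def test_matches_definition(self):
        rng = np.random.default_rng(8)
        k = np.linalg.inv(random_pd_corr(4, rng))
        pc = partial_correlations(k)
        for i in range(4):
            for j in range(4):
                if i != j:
                    assert pc[i, j] == pytest.approx(
                        -k[i, j] / np.sqrt(k[i, i] * k[j, j])
                    )
        assert np.all(np.diag(pc) == 0)
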