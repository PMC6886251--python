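import numpy as np
import pytest

from weakde import (L21Params, RankingModel, build_similarity, fit_l21,
                    l21_objective, make_targets, rank_genes)
from weakde.l21 import median_pairwise_distance

from conftest import triple_loop_objective


def random_instance(seed, n=4, m=6, c=2):
    rng = np.random.default_rng(seed)
    x = rng.normal(size=(n, m))
    labels = rng.integers(0, c, size=m)
    while len(set(labels.tolist())) < c:
        labels = rng.integers(0, c, size=m)
    y, _ = make_targets(labels)
    s = build_similarity(x, labels, t=float(rng.uniform(0.5, 2.0)))
    return x, labels, y, s


class TestSimilarity:
    def test_identical_same_label_is_one(self):
        x = np.column_stack([np.ones(3), np.ones(3)])
        s = build_similarity(x, np.array([0, 0]), t=1.0)
        assert s[0, 1] == pytest.approx(1.0)

    def test_cross_class_is_zero(self):
        x = np.column_stack([np.zeros(3), np.zeros(3)])
        s = build_similarity(x, np.array([0, 1]), t=1.0)
        assert s[0, 1] == 0.0 and s[1, 0] == 0.0

    def test_distance_equal_bandwidth(self):
        x = np.array([[0.0, 2.0]])
        s = build_similarity(x, np.array([0, 0]), t=2.0)
        assert s[0, 1] == pytest.approx(np.exp(-1.0), abs=1e-12)

    def test_nonpositive_bandwidth_rejected(self):
        with pytest.raises(ValueError):
            build_similarity(np.zeros((2, 2)), np.array([0, 0]), t=0.0)


class TestObjective:
    def test_zero_coefficients_give_sample_count(self):
        x, labels, y, s = random_instance(0)
        val = l21_objective(np.zeros((4, 2)), np.zeros(2), x, y, s, 1.0, 1.0)
        # each indicator column has unit norm, so the fit term sums to m
        assert val == pytest.approx(x.shape[1])

    def test_plain_rss_when_unregularized(self):
        x, labels, y, s = random_instance(1)
        rng = np.random.default_rng(5)
        w, b = rng.normal(size=(4, 2)), rng.normal(size=2)
        val = l21_objective(w, b, x, y, s, 0.0, 0.0)
        rss = sum(float(np.sum((w.T @ x[:, i] + b - y[:, i]) ** 2))
                  for i in range(x.shape[1]))
        assert val == pytest.approx(rss, rel=1e-12)

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_triple_loop_oracle(self, seed):
        x, labels, y, s = random_instance(seed)
        rng = np.random.default_rng(seed + 100)
        w, b = rng.normal(size=(4, 2)), rng.normal(size=2)
        lam, gamma = float(rng.uniform(0, 2)), float(rng.uniform(0, 2))
        expected = triple_loop_objective(w, b, x, y, s, lam, gamma)
        assert l21_objective(w, b, x, y, s, lam, gamma) == pytest.approx(
            expected, abs=1e-10)

    def test_dimension_mismatch_rejected(self):
        x, labels, y, s = random_instance(2)
        with pytest.raises(ValueError):
            l21_objective(np.zeros((5, 2)), np.zeros(2), x, y, s, 1.0, 1.0)

    @pytest.mark.parametrize("seed", range(4))
    def test_laplacian_trace_identity(self, seed):
        # (1/2)ΣΣ‖Wᵀxi − Wᵀxj‖² Sij = tr(Wᵀ X L Xᵀ W)
        x, labels, y, s = random_instance(seed, n=5, m=7)
        rng = np.random.default_rng(seed)
        w = rng.normal(size=(5, 2))
        lap = np.diag(s.sum(axis=1)) - s
        trace_form = float(np.trace(w.T @ x @ lap @ x.T @ w))
        pair_form = 0.5 * sum(
            float(np.sum((w.T @ x[:, i] - w.T @ x[:, j]) ** 2)) * s[i, j]
            for i in range(7) for j in range(7))
        assert trace_form == pytest.approx(pair_form, abs=1e-8)


class TestFit:
    def test_reduces_to_least_squares(self):
        x, labels, y, s = random_instance(3, n=4, m=8)
        model = fit_l21(x, y, s, L21Params(lam=0.0, gamma=0.0, max_iter=3))
        xc = x - x.mean(axis=1, keepdims=True)
        yc = y - y.mean(axis=1, keepdims=True)
        wls = np.linalg.lstsq(xc.T, yc.T, rcond=None)[0]
        np.testing.assert_allclose(model.w, wls, atol=1e-6)

    def test_huge_penalty_kills_all_rows(self):
        x, labels, y, s = random_instance(4)
        model = fit_l21(x, y, s, L21Params(gamma=1e6, max_iter=50))
        assert model.row_norms.max() < 1e-3

    @pytest.mark.parametrize("seed", range(5))
    def test_objective_trace_nonincreasing(self, seed):
        x, labels, y, s = random_instance(seed, n=6, m=9)
        model = fit_l21(x, y, s, L21Params(lam=0.5, gamma=1.0, max_iter=40))
        tr = np.array(model.objective_trace)
        assert np.all(np.diff(tr) <= 1e-9 * np.maximum(1.0, np.abs(tr[:-1])))

    def test_dual_and_direct_solvers_agree(self):
        # the sample-space (Woodbury) solve is an algebraic rewriting of
        # the gene-space normal equations: iterates must coincide
        rng = np.random.default_rng(9)
        n, m = 40, 8
        x = rng.normal(size=(n, m))
        labels = np.array([0] * 4 + [1] * 4)
        y, _ = make_targets(labels)
        s = build_similarity(x, labels, t=median_pairwise_distance(x))
        kw = dict(lam=0.7, gamma=2.0, max_iter=15, tol=1e-15)
        m_dual = fit_l21(x, y, s, L21Params(solver="dual", **kw))
        m_direct = fit_l21(x, y, s, L21Params(solver="direct", **kw))
        np.testing.assert_allclose(m_dual.w, m_direct.w, atol=1e-8)
        np.testing.assert_allclose(m_dual.objective_trace,
                                   m_direct.objective_trace, rtol=1e-10)

    def test_signal_confined_to_first_gene_ranks_first(self):
        rng = np.random.default_rng(11)
        m = 20
        labels = np.array([0] * 10 + [1] * 10)
        x = rng.normal(scale=0.3, size=(5, m))
        x[0] = np.where(labels == 1, 3.0, -3.0) + rng.normal(scale=0.3, size=m)
        y, _ = make_targets(labels)
        s = build_similarity(x, labels, t=median_pairwise_distance(x))
        model = fit_l21(x, y, s)
        assert rank_genes(model)[0] == 0

    def test_penalty_monotonically_shrinks_row_norms(self):
        x, labels, y, s = random_instance(6, n=5, m=10)
        prev = None
        for gamma in [0.1, 1.0, 10.0, 100.0]:
            model = fit_l21(x, y, s, L21Params(gamma=gamma, max_iter=60,
                                               tol=1e-10))
            total = model.row_norms.sum()
            if prev is not None:
                assert total <= prev + 1e-6
            prev = total


class TestRanking:
    def test_descending_row_norms(self):
        model = RankingModel(w=np.array([[0.1], [3.0], [0.5]]), b=np.zeros(1))
        assert rank_genes(model).tolist() == [1, 2, 0]

    def test_ties_keep_original_order(self):
        model = RankingModel(w=np.ones((4, 1)), b=np.zeros(1))
        assert rank_genes(model).tolist() == [0, 1, 2, 3]
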