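import numpy as np
import pytest
from scipy.stats import rankdata

from weakde import ExpressionMatrix, baseline_select, kfold_cv, pr_aupr, roc_auc


def mann_whitney_auc(scores, labels):
    scores = np.asarray(scores, float)
    labels = np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    ranks = rankdata(scores)
    u = ranks[labels == 1].sum() - len(pos) * (len(pos) + 1) / 2
    return u / (len(pos) * len(neg))


def brute_force_aupr(scores, labels):
    """Step integral over every distinct threshold, descending."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels)
    n_pos = labels.sum()
    area, prev_recall = 0.0, 0.0
    for t in sorted(set(scores), reverse=True):
        pred = scores >= t
        tp = int((pred & (labels == 1)).sum())
        recall = tp / n_pos
        precision = tp / pred.sum()
        area += (recall - prev_recall) * precision
        prev_recall = recall
    return area


class TestROC:
    def test_perfect_ranking(self):
        _, auc = roc_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        assert auc == 1.0

    def test_reversed_ranking(self):
        _, auc = roc_auc([0.1, 0.2, 0.8, 0.9], [1, 1, 0, 0])
        assert auc == 0.0

    def test_four_point_worked_example(self):
        # pairs: 3 of 4 concordant
        _, auc = roc_auc([0.9, 0.8, 0.7, 0.6], [1, 0, 1, 0])
        assert auc == pytest.approx(0.75)

    def test_curve_endpoints(self):
        pts, _ = roc_auc([0.9, 0.8, 0.7, 0.6], [1, 0, 1, 0])
        np.testing.assert_allclose(pts[0], [0.0, 0.0])
        np.testing.assert_allclose(pts[-1], [1.0, 1.0])

    @pytest.mark.parametrize("seed", range(10))
    def test_equals_mann_whitney(self, seed):
        rng = np.random.default_rng(seed)
        scores = rng.normal(size=40)
        labels = rng.integers(0, 2, size=40)
        while len(set(labels.tolist())) < 2:
            labels = rng.integers(0, 2, size=40)
        _, auc = roc_auc(scores, labels)
        assert auc == pytest.approx(mann_whitney_auc(scores, labels),
                                    abs=1e-10)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(1)
        scores = rng.normal(size=30)
        labels = rng.integers(0, 2, size=30)
        labels[:2] = [0, 1]
        _, a1 = roc_auc(scores, labels)
        _, a2 = roc_auc(np.exp(3 * scores), labels)
        assert a1 == pytest.approx(a2, abs=1e-12)

    def test_one_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([0.1, 0.2], [1, 1])


class TestPR:
    def test_perfect_ranking(self):
        _, aupr = pr_aupr([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        assert aupr == pytest.approx(1.0)

    def test_four_point_matches_threshold_enumeration(self):
        scores = [0.9, 0.8, 0.7, 0.6]
        labels = [1, 0, 1, 0]
        _, aupr = pr_aupr(scores, labels)
        assert aupr == pytest.approx(
            brute_force_aupr(scores, labels), abs=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_random_instances_match_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        scores = rng.normal(size=25)
        labels = rng.integers(0, 2, size=25)
        labels[:2] = [0, 1]
        _, aupr = pr_aupr(scores, labels)
        assert aupr == pytest.approx(brute_force_aupr(scores, labels),
                                     abs=1e-10)

    def test_low_scores_degenerate_gracefully(self):
        # every positive scored at the bottom: curve still well defined
        _, aupr = pr_aupr([0.1, 0.2, 0.8, 0.9], [1, 1, 0, 0])
        assert 0.0 <= aupr <= 1.0


class TestKFoldCV:
    def test_constant_predictor_near_half_on_balanced(self):
        labels = np.array([0, 1] * 20)

        def fp(train, test):
            return np.zeros(len(test)), np.zeros(len(test), dtype=int)

        rep = kfold_cv(np.arange(40), labels, fp, k=10, seed=0)
        assert rep.mean_accuracy == pytest.approx(0.5, abs=0.05)

    def test_oracle_predictor_is_perfect(self):
        labels = np.array([0, 1] * 20)

        def fp(train, test):
            return labels[test].astype(float), labels[test]

        rep = kfold_cv(np.arange(40), labels, fp, k=10, seed=0)
        assert rep.fold_accuracies == [1.0] * 10
        assert rep.auc == 1.0

    def test_same_seed_reproduces_folds(self):
        rng = np.random.default_rng(2)
        labels = rng.integers(0, 2, size=50)
        labels[:2] = [0, 1]
        calls = []

        def fp(train, test):
            calls.append(tuple(test))
            return rng.normal(size=len(test)), labels[test]

        kfold_cv(np.arange(50), labels, fp, k=5, seed=7)
        first = list(calls)
        calls.clear()
        kfold_cv(np.arange(50), labels, fp, k=5, seed=7)
        assert calls == first

    def test_k_below_two_rejected(self):
        with pytest.raises(ValueError):
            kfold_cv(np.arange(4), np.array([0, 1, 0, 1]),
                     lambda a, b: (np.zeros(len(b)), np.zeros(len(b))), k=1,
                     seed=0)


class TestBaselineSelect:
    def _mat(self, rows):
        rows = np.asarray(rows, float)
        m = rows.shape[1]
        return ExpressionMatrix(rows, [f"g{i}" for i in range(rows.shape[0])],
                                [f"s{i}" for i in range(m)],
                                np.array([20] * (m // 2) + [175] * (m - m // 2)))

    def test_variance_picks_varying_gene(self):
        x = self._mat([[5, 5, 5, 5], [1, 9, 1, 9]])
        assert baseline_select(x, None, "variance", 1) == ["g1"]

    def test_chi2_two_by_two_table_statistic(self):
        # gene expressed in all 10 disease samples, none of 10 normals:
        # contingency (10,0 / 0,10) has chi-square 20
        from weakde.evaluation import _chi2_median_binarized
        vals = np.array([[0.0] * 10 + [1.0] * 10])
        y01 = np.array([0] * 10 + [1] * 10)
        stat = _chi2_median_binarized(vals, y01)
        assert stat[0] == pytest.approx(20.0)

    def test_chi2_ranks_separating_gene_first(self):
        rng = np.random.default_rng(0)
        sep = np.array([0.0] * 5 + [10.0] * 5)
        noise = rng.uniform(size=(4, 10))
        x = self._mat(np.vstack([noise[:2], sep, noise[2:]]))
        labels = np.array([0] * 5 + [1] * 5)
        assert baseline_select(x, labels, "chi2", 1) == ["g2"]

    def test_select_all_is_identity_set(self):
        x = self._mat(np.arange(12.0).reshape(3, 4))
        assert set(baseline_select(x, None, "variance", 3)) == \
            {"g0", "g1", "g2"}

    def test_unknown_method_rejected(self):
        x = self._mat(np.ones((2, 4)))
        with pytest.raises(ValueError):
            baseline_select(x, None, "pca", 1)
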