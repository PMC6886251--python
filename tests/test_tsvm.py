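import numpy as np
import pytest

from weakde import (TSVMParams, decision_values, fit_svm, fit_tsvm,
                    linear_gram, predict_disease_genes, rbf_gram)
from weakde.tsvm import check_kkt

from conftest import slsqp_dual_objective


def blobs(seed, n_pos=30, n_neg=30, sep=2.0, scale=0.5):
    rng = np.random.default_rng(seed)
    pts = np.vstack([rng.normal(size=(n_pos, 2)) * scale + sep,
                     rng.normal(size=(n_neg, 2)) * scale - sep])
    y = np.concatenate([np.ones(n_pos), -np.ones(n_neg)])
    return pts, y


class TestFitSVM:
    def test_two_point_hand_solution(self):
        # k = I, y = (+1, −1): dual is max 2a − a², so α = (1, 1) at C ≥ 1,
        # f = (+1, −1), bias 0
        k = np.eye(2)
        y = np.array([1.0, -1.0])
        model = fit_svm(k, y, c=100.0)
        np.testing.assert_allclose(model.alpha, [1.0, 1.0], atol=1e-6)
        assert model.bias == pytest.approx(0.0, abs=1e-6)
        np.testing.assert_allclose(decision_values(model, k), [1.0, -1.0],
                                   atol=1e-6)

    def test_duplicated_points_leave_decision_unchanged(self):
        pts, y = blobs(0, n_pos=6, n_neg=6)
        k = pts @ pts.T
        m1 = fit_svm(k, y, c=1.0)
        pts2 = np.vstack([pts, pts])
        y2 = np.concatenate([y, y])
        m2 = fit_svm(pts2 @ pts2.T, y2, c=1.0)
        f1 = decision_values(m1, pts @ pts.T)
        f2 = decision_values(m2, pts @ pts2.T)
        np.testing.assert_allclose(np.sign(f1), np.sign(f2))
        np.testing.assert_allclose(f1, f2, atol=1e-3)

    @pytest.mark.parametrize("seed", range(5))
    def test_dual_objective_matches_independent_qp(self, seed):
        pts, y = blobs(seed, n_pos=8, n_neg=8)
        k = pts @ pts.T
        model = fit_svm(k, y, c=1.0)
        v = model.alpha * model.y
        impl = model.alpha.sum() - 0.5 * v @ k @ v
        oracle = slsqp_dual_objective(k, y, 1.0)
        assert impl == pytest.approx(oracle, abs=1e-6)

    @pytest.mark.parametrize("seed", range(5))
    def test_kkt_conditions_hold(self, seed):
        pts, y = blobs(seed, sep=1.0)
        k = pts @ pts.T
        model = fit_svm(k, y, c=1.0)
        check_kkt(model, k)
        assert abs(model.alpha @ model.y) < 1e-8 * max(1.0, model.alpha.sum())

    def test_one_class_rejected(self):
        with pytest.raises(ValueError):
            fit_svm(np.eye(3), np.ones(3), 1.0)

    def test_indefinite_kernel_repaired_with_warning(self):
        k = np.array([[1.0, 2.0], [2.0, 1.0]])  # eigenvalues 3, −1
        with pytest.warns(UserWarning, match="indefinite"):
            fit_svm(k, np.array([1.0, -1.0]), 1.0)


class TestDecisionValues:
    def test_zero_kernel_rows_return_bias(self):
        pts, y = blobs(1, n_pos=5, n_neg=5)
        model = fit_svm(pts @ pts.T, y, c=1.0)
        f = decision_values(model, np.zeros((3, 10)))
        np.testing.assert_allclose(f, model.bias)

    def test_free_support_vector_on_unit_margin(self):
        pts, y = blobs(2, sep=1.2)
        k = pts @ pts.T
        model = fit_svm(k, y, c=1.0)
        f = decision_values(model, k)
        free = (model.alpha > 1e-6) & (model.alpha < 1.0 - 1e-6)
        assert free.any()
        np.testing.assert_allclose(np.abs(f[free]), 1.0, atol=1e-5)

    def test_misaligned_shapes_rejected(self):
        pts, y = blobs(3, n_pos=4, n_neg=4)
        model = fit_svm(pts @ pts.T, y, c=1.0)
        with pytest.raises(ValueError):
            decision_values(model, np.zeros((2, 7)))


class TestFitTSVM:
    def test_no_unlabeled_reduces_to_svm(self):
        pts, y = blobs(4, n_pos=6, n_neg=6)
        k = pts @ pts.T
        tm = fit_tsvm(k, y, TSVMParams(c=1.0))
        sm = fit_svm(k, y, c=1.0)
        np.testing.assert_allclose(decision_values(tm.base, k),
                                   decision_values(sm, k), atol=1e-6)

    def test_unlabeled_duplicates_recover_their_labels(self):
        pts, y = blobs(5, n_pos=8, n_neg=8, sep=2.5)
        all_pts = np.vstack([pts, pts])
        k = all_pts @ all_pts.T
        tm = fit_tsvm(k, y, TSVMParams(c=1.0, pos_fraction=0.5))
        np.testing.assert_array_equal(tm.transduced_labels, y)

    def test_transduction_beats_labeled_only_on_blobs(self):
        # with 10% labeled points, the label-switching transduction should
        # recover ≥95% of the planted blob labels and, averaged over
        # seeds, strictly beat the labeled-only SVM on the same draws
        acc_t, acc_s = [], []
        for seed in range(20):
            pts, truth = blobs(seed, n_pos=40, n_neg=40, sep=1.2, scale=0.8)
            lab = np.concatenate([np.arange(4), 40 + np.arange(4)])
            unl = np.setdiff1d(np.arange(80), lab)
            order = np.concatenate([lab, unl])
            k = pts[order] @ pts[order].T
            tm = fit_tsvm(k, truth[lab], TSVMParams(c=1.0, pos_fraction=0.5))
            acc_t.append(np.mean(tm.transduced_labels == truth[unl]))
            base = fit_svm(k[:8, :8], truth[lab], 1.0)
            acc_s.append(np.mean(
                np.sign(decision_values(base, k[8:, :8])) == truth[unl]))
        assert np.mean(acc_t) >= 0.95
        assert np.mean(acc_t) > np.mean(acc_s)

    def test_positive_count_follows_pos_fraction(self):
        pts, y = blobs(6, n_pos=10, n_neg=10)
        extra = np.random.default_rng(6).normal(size=(25, 2))
        all_pts = np.vstack([pts, extra])
        k = all_pts @ all_pts.T
        tm = fit_tsvm(k, y, TSVMParams(c=1.0, pos_fraction=0.3))
        n_pos = int(np.sum(tm.transduced_labels > 0))
        assert abs(n_pos - 0.3 * 25) <= 1

    def test_invalid_pos_fraction_rejected(self):
        with pytest.raises(ValueError):
            TSVMParams(pos_fraction=1.5)


class TestPredictions:
    def test_ranked_by_decision_value(self):
        pts, y = blobs(7, n_pos=6, n_neg=6, sep=2.5)
        unl = np.vstack([pts[:3] + 0.01, pts[-3:] - 0.01])
        all_pts = np.vstack([pts, unl])
        k = all_pts @ all_pts.T
        tm = fit_tsvm(k, y, TSVMParams(c=1.0, pos_fraction=0.5))
        rows = predict_disease_genes(tm, [f"g{i}" for i in range(6)])
        vals = [r[1] for r in rows]
        assert vals == sorted(vals, reverse=True)
        top_ids = {r[0] for r in rows[:3]}
        assert top_ids == {"g0", "g1", "g2"}  # near-duplicates of positives

    def test_id_count_mismatch_rejected(self):
        pts, y = blobs(8, n_pos=4, n_neg=4)
        tm = fit_tsvm(pts @ pts.T, y, TSVMParams(c=1.0))
        with pytest.raises(ValueError):
            predict_disease_genes(tm, ["a", "b"])


class TestComparisonKernels:
    def test_linear_gram_is_inner_product(self):
        rng = np.random.default_rng(9)
        a = rng.normal(size=(4, 6))
        np.testing.assert_allclose(linear_gram(a), a @ a.T)

    def test_rbf_gram_unit_diagonal_and_range(self):
        rng = np.random.default_rng(10)
        a = rng.normal(size=(5, 6))
        k = rbf_gram(a)
        np.testing.assert_allclose(np.diag(k), 1.0)
        assert (k >= 0).all() and (k <= 1.0 + 1e-12).all()
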