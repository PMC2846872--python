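"""Kernel, dual solution, DJ elimination criterion and the RFE loop."""

import numpy as np
import pytest
from sklearn.svm import SVC

from panelrfe import (
    AccuracyReport,
    KernelConfig,
    dj_scores,
    evaluate,
    make_partitions,
    predict,
    rbf_kernel,
    rfe_run,
    train_svm,
)
from panelrfe.svm_rfe import dj_objective_change

from conftest import two_feature_cohort


def random_two_class(rng, n=30, d=5):
    X = rng.normal(size=(n, d))
    y = np.where(rng.random(n) < 0.5, 1, -1)
    y[0], y[1] = 1, -1  # both classes guaranteed
    return X, y


class TestRBFKernel:
    def test_unit_diagonal_and_closed_form(self):
        x = np.array([[0.3, -1.2, 4.0]])
        assert rbf_kernel(x, x, gamma=2.0)[0, 0] == pytest.approx(1.0)
        K = rbf_kernel([[0.0, 0.0]], [[1.0, 1.0]], gamma=0.5)
        assert K[0, 0] == pytest.approx(np.exp(-1.0))

    @pytest.mark.parametrize("seed", range(5))
    def test_kernel_matrix_positive_semidefinite(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(12, 4))
        K = rbf_kernel(X, X, gamma=rng.uniform(0.1, 3.0))
        assert np.allclose(K, K.T)
        assert np.all((K > 0) & (K <= 1.0))
        assert np.linalg.eigvalsh(K).min() > -1e-10

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            rbf_kernel(np.zeros((2, 3)), np.zeros((2, 3)), gamma=-1.0)
        with pytest.raises(ValueError, match="mismatch"):
            rbf_kernel(np.zeros((2, 3)), np.zeros((2, 4)), gamma=1.0)


class TestTrainedSVM:
    @pytest.mark.parametrize("seed", range(4))
    def test_dual_constraints_hold(self, seed):
        rng = np.random.default_rng(seed)
        X, y = random_two_class(rng)
        config = KernelConfig(C=rng.uniform(0.5, 5.0))
        model = train_svm(X, y, config)
        assert abs(np.dot(model.alphas, model.y)) < 1e-6
        assert np.all(model.alphas >= -1e-12)
        assert np.all(model.alphas <= config.C + 1e-12)
        assert set(np.flatnonzero(model.alphas > 0)) <= set(
            model.support_indices.tolist()
        )

    def test_separable_points_classified_perfectly(self):
        X = np.array([[0.0, 0.0], [0.0, 1.0], [4.0, 4.0], [4.0, 5.0]])
        y = np.array([1, 1, -1, -1])
        model = train_svm(X, y)
        assert np.array_equal(predict(model, X), y)

    def test_xor_separable_with_rbf(self):
        X = np.array([[0.0, 0.0], [1.0, 1.0], [0.0, 1.0], [1.0, 0.0]])
        y = np.array([1, 1, -1, -1])
        model = train_svm(X, y, KernelConfig(C=100.0, standardize=False,
                                             gamma=1.0))
        assert np.array_equal(predict(model, X), y)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            train_svm(np.zeros((4, 2)), np.ones(4))

    def test_decision_matches_reference_solver(self):
        """Our support-vector expansion reproduces the solver's own
        decision function."""
        rng = np.random.default_rng(3)
        X, y = random_two_class(rng, n=40)
        model = train_svm(X, y, KernelConfig(standardize=False, gamma=0.3,
                                             C=2.0))
        clf = SVC(C=2.0, kernel="rbf", gamma=0.3).fit(X, y)
        Xnew = rng.normal(size=(15, 5))
        np.testing.assert_allclose(
            model.decision_values(Xnew), clf.decision_function(Xnew),
            atol=1e-8,
        )

    def test_dimension_mismatch_rejected(self):
        rng = np.random.default_rng(0)
        X, y = random_two_class(rng)
        model = train_svm(X, y)
        with pytest.raises(ValueError, match="features"):
            predict(model, np.zeros((3, 4)))


class TestAccuracyReport:
    def test_printed_formula(self):
        report = AccuracyReport(tp=40, tn=45, m=90)
        assert report.P == pytest.approx(85 / 90)

    def test_evaluate_and_label_flip_complement(self):
        rng = np.random.default_rng(8)
        X, y = random_two_class(rng, n=50)
        model = train_svm(X, y)
        report = evaluate(model, X, y)
        flipped = evaluate(model, X, -y)
        assert report.tp + report.tn + flipped.tp + flipped.tn == 50
        assert flipped.P == pytest.approx(1.0 - report.P)


class TestDJScores:
    @pytest.mark.parametrize("seed", range(6))
    def test_downdate_equals_full_recomputation(self, seed):
        """The multiplicative RBF downdate reproduces, to 1e-10, DJ computed
        by rebuilding the kernel on data with the feature deleted."""
        rng = np.random.default_rng(seed)
        X, y = random_two_class(rng, n=25, d=6)
        model = train_svm(X, y, KernelConfig(C=rng.uniform(0.5, 3.0)))
        sv = model.support_indices
        Xsv = model.X[sv]
        a = (model.alphas * model.y)[sv]
        K = rbf_kernel(Xsv, Xsv, model.gamma_)
        scores = dj_scores(model)
        for i in range(6):
            Xdel = np.delete(Xsv, i, axis=1)
            oracle = dj_objective_change(
                a, K, rbf_kernel(Xdel, Xdel, model.gamma_)
            )
            assert scores[i] == pytest.approx(oracle, abs=1e-10)

    @pytest.mark.parametrize("seed", range(4))
    def test_linear_kernel_dj_is_half_squared_weight(self, seed):
        """With a linear kernel the objective change of deleting feature i
        collapses algebraically to w_i^2 / 2, w = sum alpha_k y_k x_k."""
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(10, 4))
        w_true = np.array([1.5, 0.0, -2.0, 0.3])
        y = np.where(X @ w_true + 0.2 * rng.normal(size=10) > 0, 1, -1)
        if len(np.unique(y)) < 2:
            y[0] = -y[0]
        clf = SVC(C=1.0, kernel="linear").fit(X, y)
        alphas = np.zeros(len(y))
        alphas[clf.support_] = np.abs(clf.dual_coef_[0])
        a = alphas * y
        w = (a[:, None] * X).sum(axis=0)
        K = X @ X.T
        for i in range(4):
            Xdel = np.delete(X, i, axis=1)
            dj = dj_objective_change(a, K, Xdel @ Xdel.T)
            assert dj == pytest.approx(0.5 * w[i] ** 2, abs=1e-8)

    def test_constant_feature_scores_zero(self):
        rng = np.random.default_rng(1)
        X, y = random_two_class(rng, n=20, d=4)
        X[:, 2] = 7.7
        model = train_svm(X, y)
        assert dj_scores(model)[2] == 0.0


class TestRFERun:
    def test_single_feature_base_case(self, small_cohort):
        plan = make_partitions(small_cohort, ratios=("1:1",), total_count=1,
                               seed=0)
        result = rfe_run(plan.partitions[0], small_cohort, features=["MAO"])
        assert result.elimination_order == [32]
        assert result.best_subset == (32,)

    def test_elimination_order_is_permutation(self, small_cohort, small_plan):
        result = rfe_run(small_plan.partitions[0], small_cohort)
        assert sorted(result.elimination_order) == list(range(1, 42))
        assert len(result.accuracy_curve) == 41
        # best subset is a suffix of the elimination order
        size = len(result.best_subset)
        assert result.best_subset == result.active_set(size)

    def test_best_subset_at_least_full_panel_accuracy(self, small_cohort,
                                                      small_plan):
        result = rfe_run(small_plan.partitions[1], small_cohort)
        assert result.best_accuracy >= result.accuracy_curve[41].P

    def test_scale_invariance_under_standardization(self):
        """Multiplying a raw analyte column by 1000 must not change the
        elimination order when features are z-scored."""
        cohort = two_feature_cohort(n_subjects=30, seed=2)
        plan = make_partitions(cohort, ratios=("1:1",), total_count=1, seed=4)
        base = rfe_run(plan.partitions[0], cohort)
        scaled = cohort.frame.copy()
        scaled["K"] = scaled["K"] * 1000.0
        from panelrfe.simulate import Cohort

        rescaled = Cohort(scaled)
        again = rfe_run(plan.partitions[0], rescaled)
        assert base.elimination_order == again.elimination_order

    def test_informative_feature_survives_to_the_end(self):
        """With one strongly separating analyte and 40 null analytes the
        separating one is eliminated last."""
        cohort = two_feature_cohort(n_subjects=50, shift=5.0, seed=21)
        plan = make_partitions(cohort, ratios=("2:1",), total_count=1, seed=6)
        result = rfe_run(plan.partitions[0], cohort)
        assert result.elimination_order[-1] == 32  # MAO
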