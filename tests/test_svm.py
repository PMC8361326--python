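"""Kernels, SVM dual solutions, and multiple-kernel learning."""

import numpy as np
import pytest
from scipy.optimize import minimize

import connmkl as ck
from connmkl.svm import dual_objective


def qp_dual_oracle(K, y, C):
    """Independent QP solution of the SVM dual via SLSQP."""
    n = len(y)
    y = np.asarray(y, dtype=float)

    def neg_obj(a):
        ay = a * y
        return -(a.sum() - 0.5 * ay @ K @ ay)

    def neg_grad(a):
        return -(np.ones(n) - y * (K @ (a * y)))

    cons = [{"type": "eq", "fun": lambda a: a @ y, "jac": lambda a: y}]
    res = minimize(neg_obj, np.full(n, min(C, 1.0) / 2), jac=neg_grad,
                   bounds=[(0, C)] * n, constraints=cons, method="SLSQP",
                   options={"maxiter": 500, "ftol": 1e-14})
    return res.x, -res.fun


def random_problem(rng, n, d=4, C=None):
    X = rng.standard_normal((n, d))
    y = np.where(rng.random(n) < 0.5, 1, -1)
    while len(set(y.tolist())) < 2:
        y = np.where(rng.random(n) < 0.5, 1, -1)
    C = C if C is not None else float(rng.uniform(0.5, 5))
    return X @ X.T, y, C


class TestComputeKernel:
    def test_linear_orthonormal_rows_give_identity(self):
        rows = np.array([[1.0, 0.0], [0.0, 1.0]])
        K = ck.compute_kernel(rows, rows, ck.KernelSpec("linear"))
        np.testing.assert_allclose(K, np.eye(2))

    def test_rbf_unit_diagonal(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((5, 3))
        K = ck.compute_kernel(X, X, ck.KernelSpec("rbf", gamma=0.7))
        np.testing.assert_allclose(np.diag(K), np.ones(5))

    def test_polynomial_cube(self):
        a = np.array([[1.0, 0.0]])
        K = ck.compute_kernel(a, a, ck.KernelSpec("polynomial", degree=3,
                                                  coef0=1.0))
        assert K[0, 0] == pytest.approx(8.0)  # (1 + 1)^3

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError):
            ck.compute_kernel(np.zeros((2, 3)), np.zeros((2, 4)),
                              ck.KernelSpec("linear"))

    def test_self_kernel_psd(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((8, 3))
        for spec in (ck.KernelSpec("linear"),
                     ck.KernelSpec("polynomial"),
                     ck.KernelSpec("rbf", gamma=0.5)):
            K = ck.compute_kernel(X, X, spec)
            assert np.allclose(K, K.T)
            assert np.linalg.eigvalsh(K).min() > -1e-8


class TestTrainSvm:
    def test_analytic_two_point_max_margin(self):
        K = np.array([[1.0, -1.0], [-1.0, 1.0]])
        alpha, bias = ck.train_svm(K, [1, -1], C=10.0)
        np.testing.assert_allclose(alpha, [0.5, 0.5], atol=1e-6)
        assert bias == pytest.approx(0.0, abs=1e-6)

    def test_feasibility_on_random_problems(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            K, y, C = random_problem(rng, int(rng.integers(6, 25)))
            alpha, _ = ck.train_svm(K, y, C)
            assert np.all(alpha >= -1e-8) and np.all(alpha <= C + 1e-8)
            assert abs(alpha @ y) < 1e-8

    def test_dual_objective_matches_qp_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            K, y, C = random_problem(rng, int(rng.integers(10, 21)))
            alpha, _ = ck.train_svm(K, y, C)
            _, J_oracle = qp_dual_oracle(K, y, C)
            J = dual_objective(K, y, alpha)
            assert J == pytest.approx(J_oracle, rel=1e-6)

    def test_non_psd_kernel_rejected(self):
        K = np.array([[1.0, 2.0], [2.0, 1.0]])  # eigenvalues 3, -1
        with pytest.raises(ValueError, match="PSD"):
            ck.train_svm(K, [1, -1], C=1.0)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            ck.train_svm(np.eye(3), [1, 1, 1], C=1.0)


class TestTrainMkl:
    def test_single_kernel_reduces_to_svm(self):
        rng = np.random.default_rng(4)
        K, y, C = random_problem(rng, 15)
        res = ck.train_mkl([K], y, C)
        alpha, bias = ck.train_svm(K, y, C)
        np.testing.assert_allclose(res.beta, [1.0])
        np.testing.assert_allclose(res.alpha, alpha, atol=1e-8)
        assert res.bias == pytest.approx(bias, abs=1e-8)

    def test_identical_kernels_keep_single_kernel_objective(self):
        rng = np.random.default_rng(5)
        K, y, C = random_problem(rng, 18)
        res = ck.train_mkl([K, K.copy()], y, C)
        alpha, _ = ck.train_svm(K, y, C)
        assert res.objective == pytest.approx(dual_objective(K, y, alpha),
                                              rel=1e-6)

    def test_informative_kernel_dominates_noise(self):
        rng = np.random.default_rng(6)
        n = 24
        y = np.array([1] * 12 + [-1] * 12)
        X_good = y[:, None] * 1.0 + 0.3 * rng.standard_normal((n, 3))
        X_noise = rng.standard_normal((n, 3))
        K_good = X_good @ X_good.T
        K_noise = X_noise @ X_noise.T
        K_good /= np.mean(np.diag(K_good))
        K_noise /= np.mean(np.diag(K_noise))
        res = ck.train_mkl([K_good, K_noise], y, C=1.0)
        assert res.beta[0] >= 0.9

    def test_objective_matches_simplex_grid_oracle(self):
        rng = np.random.default_rng(7)
        for trial in range(3):
            n = int(rng.integers(12, 30))
            K1, y, C = random_problem(rng, n)
            K2 = random_problem(rng, n)[0]
            K1 /= np.mean(np.diag(K1))
            K2 /= np.mean(np.diag(K2))
            res = ck.train_mkl([K1, K2], y, C)
            grid_best = np.inf
            for b in np.arange(0.0, 1.0001, 0.01):
                K = b * K1 + (1 - b) * K2
                alpha, _ = ck.train_svm(K, y, C, check_psd=False)
                grid_best = min(grid_best, dual_objective(K, y, alpha))
            # reduced-gradient optimum matches the exhaustive grid minimum
            assert res.objective == pytest.approx(grid_best, rel=1e-3,
                                                  abs=1e-3)

    def test_simplex_constraints_hold(self):
        rng = np.random.default_rng(8)
        n = 20
        kernels = [random_problem(rng, n)[0] for _ in range(3)]
        y = np.array([1] * 10 + [-1] * 10)
        res = ck.train_mkl(kernels, y, C=2.0)
        assert np.all(res.beta >= -1e-12)
        assert res.beta.sum() == pytest.approx(1.0, abs=1e-8)
        assert np.all(res.alpha >= -1e-8) and np.all(res.alpha <= 2.0 + 1e-8)
        assert abs(res.alpha @ y) < 1e-8

    def test_empty_kernel_list_rejected(self):
        with pytest.raises(ValueError):
            ck.train_mkl([], [1, -1], C=1.0)


class TestDecisionAndPrimal:
    def _toy_model(self, seed=9):
        rng = np.random.default_rng(seed)
        n = 16
        y = np.array([1] * 8 + [-1] * 8)
        blocks = [y[:, None] * 0.8 + 0.4 * rng.standard_normal((n, 3)),
                  rng.standard_normal((n, 2)),
                  y[:, None] * 0.5 + 0.6 * rng.standard_normal((n, 4))]
        model = ck.fit_mkl_classifier(blocks, y, C=1.0,
                                      spec=ck.KernelSpec("linear"),
                                      network_kinds=["FN", "FA", "MD"])
        return model, blocks, y

    def test_separable_training_data_classified_perfectly(self):
        rng = np.random.default_rng(10)
        n = 12
        y = np.array([1] * 6 + [-1] * 6)
        blocks = [y[:, None] * 2.0 + 0.1 * rng.standard_normal((n, 2))]
        model = ck.fit_mkl_classifier(blocks, y, C=10.0,
                                      spec=ck.KernelSpec("linear"),
                                      network_kinds=["FN"])
        pred = ck.predict(model, blocks)
        np.testing.assert_array_equal(pred, y)

    def test_hand_expanded_decision_function(self):
        model, blocks, y = self._toy_model()
        test_rows = [b[:3] for b in blocks]
        f = ck.decision_values(model, test_rows)
        # manual expansion: f(x) = sum_i alpha_i y_i sum_m beta_m k_m + b
        for t in range(3):
            val = model.bias
            for i in range(len(y)):
                k_sum = 0.0
                for m, b in enumerate(blocks):
                    k_m = float(b[i] @ test_rows[m][t]) / model.kernel_norms[m]
                    k_sum += model.beta[m] * k_m
                val += model.alpha[i] * y[i] * k_sum
            assert f[t] == pytest.approx(val, abs=1e-10)

    def test_duplicated_network_leaves_decision_unchanged(self):
        rng = np.random.default_rng(11)
        n = 14
        y = np.array([1] * 7 + [-1] * 7)
        X = y[:, None] * 1.0 + 0.5 * rng.standard_normal((n, 3))
        K = X @ X.T
        alpha, bias = ck.train_svm(K, y, C=1.0)
        f_single = (alpha * y) @ K + bias
        # same kernel twice with the beta split in half
        f_split = (alpha * y) @ (0.5 * K + 0.5 * K) + bias
        np.testing.assert_allclose(f_single, f_split, atol=1e-12)

    def test_primal_weights_reproduce_decision_values(self):
        model, blocks, y = self._toy_model()
        ws = ck.primal_weights_linear(model)
        test_rows = [b[:5] for b in blocks]
        f_kernel = ck.decision_values(model, test_rows)
        f_primal = model.bias + sum(
            model.beta[m] * (test_rows[m] @ ws[m])
            for m in range(len(blocks)))
        np.testing.assert_allclose(f_primal, f_kernel, atol=1e-10)

    def test_orthogonal_toy_puts_weight_on_separating_axis(self):
        y = np.array([1, 1, -1, -1])
        X = np.array([[1.0, 3.0], [1.0, -3.0], [-1.0, 3.0], [-1.0, -3.0]])
        model = ck.fit_mkl_classifier([X], y, C=10.0,
                                      spec=ck.KernelSpec("linear"),
                                      network_kinds=["FN"])
        w = ck.primal_weights_linear(model)[0]
        assert abs(w[0]) > 1e-3
        assert abs(w[1]) < 1e-8

    def test_primal_weights_refused_for_rbf(self):
        rng = np.random.default_rng(12)
        y = np.array([1] * 5 + [-1] * 5)
        X = y[:, None] + 0.3 * rng.standard_normal((10, 2))
        model = ck.fit_mkl_classifier([X], y, C=1.0,
                                      spec=ck.KernelSpec("rbf", gamma=0.5),
                                      network_kinds=["FN"])
        with pytest.raises(ValueError):
            ck.primal_weights_linear(model)

    def test_feature_permutation_invariance(self):
        model, blocks, y = self._toy_model()
        rng = np.random.default_rng(13)
        perms = [rng.permutation(b.shape[1]) for b in blocks]
        blocks_p = [b[:, p] for b, p in zip(blocks, perms)]
        model_p = ck.fit_mkl_classifier(blocks_p, y, C=1.0,
                                        spec=ck.KernelSpec("linear"),
                                        network_kinds=["FN", "FA", "MD"])
        f = ck.decision_values(model, [b[:4] for b in blocks])
        f_p = ck.decision_values(model_p, [b[:4] for b in blocks_p])
        np.testing.assert_allclose(f, f_p, atol=1e-6)

    def test_model_json_round_trip(self):
        model, blocks, _ = self._toy_model()
        text = model.to_json()
        back = ck.TrainedMKLModel.from_json(text)
        np.testing.assert_array_equal(back.alpha, model.alpha)
        np.testing.assert_array_equal(back.beta, model.beta)
        assert back.bias == model.bias
        f_a = ck.decision_values(model, [b[:2] for b in blocks])
        f_b = ck.decision_values(back, [b[:2] for b in blocks])
        np.testing.assert_array_equal(f_a, f_b)

    def test_empty_block_dropped_with_zero_beta(self):
        rng = np.random.default_rng(14)
        n = 12
        y = np.array([1] * 6 + [-1] * 6)
        blocks = [y[:, None] + 0.3 * rng.standard_normal((n, 2)),
                  np.zeros((n, 0))]
        model = ck.fit_mkl_classifier(blocks, y, C=1.0,
                                      spec=ck.KernelSpec("linear"),
                                      network_kinds=["FN", "FA"])
        assert model.beta[1] == 0.0
        assert model.beta.sum() == pytest.approx(1.0)
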