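import numpy as np
import pytest

from mdnmf.exceptions import DivergenceError, ParameterError
from mdnmf.graphs import normalized_laplacian
from mdnmf.initialization import FactorPair, nndsvd_init
from mdnmf.solver import (
    SolverParams,
    grad_smooth_X,
    grad_smooth_Y,
    ipalm_solve,
    objective,
    predict_scores,
    prox_nonneg,
    smoothed_objective,
    step_constant,
)


def random_laplacian(n, rng):
    W = rng.random((n, n))
    W = 0.5 * (W + W.T)
    np.fill_diagonal(W, 0.0)
    return normalized_laplacian(W)


def zeros_problem(m, d):
    return np.zeros((m, m)), np.zeros((d, d))


class TestObjective:
    def test_zero_factors(self, rng):
        A = rng.random((4, 3))
        Lm, Ld = zeros_problem(4, 3)
        p = SolverParams(lambda_m=0, lambda_d=0, lambda_l=0)
        val = objective(A, np.zeros((4, 2)), np.zeros((3, 2)), Lm, Ld, p)
        assert val == pytest.approx(0.5 * np.sum(A**2))

    def test_exact_factorization_is_zero(self, rng):
        X, Y = rng.random((5, 2)), rng.random((3, 2))
        Lm, Ld = zeros_problem(5, 3)
        p = SolverParams(lambda_m=0, lambda_d=0, lambda_l=0)
        assert objective(X @ Y.T, X, Y, Lm, Ld, p) == pytest.approx(0.0, abs=1e-15)

    def test_l21_term_is_sum_of_row_norms(self):
        X = np.array([[3.0, 4.0]])
        Y = np.zeros((1, 2))
        Lm, Ld = zeros_problem(1, 1)
        p = SolverParams(lambda_m=0, lambda_d=0, lambda_l=1.0)
        # data term: A = 0 (1x1), X Y^T = 0 -> only ||X||_2,1 = 5 remains
        assert objective(np.zeros((1, 1)), X, Y, Lm, Ld, p) == pytest.approx(5.0)

    def test_non_finite_input_raises(self):
        p = SolverParams()
        with pytest.raises(DivergenceError):
            objective(np.array([[np.inf]]), np.ones((1, 1)), np.ones((1, 1)),
                      np.zeros((1, 1)), np.zeros((1, 1)), p)


class TestGradients:
    def test_finite_difference_match(self, rng):
        """Central differences of the smoothed objective vs analytic gradients."""
        m, d, k = 6, 4, 2
        A = rng.random((m, d))
        X = rng.random((m, k)) + 0.1
        Y = rng.random((d, k)) + 0.1
        Lm, Ld = random_laplacian(m, rng), random_laplacian(d, rng)
        p = SolverParams(lambda_m=0.3, lambda_d=0.2, lambda_l=0.15)
        gx = grad_smooth_X(A, X, Y, Lm, p)
        gy = grad_smooth_Y(A, X, Y, Ld, p)
        h = 1e-6
        for G, M, which in ((gx, X, "X"), (gy, Y, "Y")):
            num = np.zeros_like(M)
            for idx in np.ndindex(M.shape):
                Mp, Mm = M.copy(), M.copy()
                Mp[idx] += h
                Mm[idx] -= h
                if which == "X":
                    fp = smoothed_objective(A, Mp, Y, Lm, Ld, p)
                    fm = smoothed_objective(A, Mm, Y, Lm, Ld, p)
                else:
                    fp = smoothed_objective(A, X, Mp, Lm, Ld, p)
                    fm = smoothed_objective(A, X, Mm, Lm, Ld, p)
                num[idx] = (fp - fm) / (2 * h)
            assert np.linalg.norm(num - G) / max(np.linalg.norm(G), 1e-12) < 1e-5

    def test_stationary_at_exact_plain_nmf(self, rng):
        X, Y = rng.random((5, 2)), rng.random((4, 2))
        p = SolverParams(lambda_m=0, lambda_d=0, lambda_l=0)
        Lm, Ld = zeros_problem(5, 4)
        assert np.allclose(grad_smooth_X(X @ Y.T, X, Y, Lm, p), 0.0, atol=1e-12)
        assert np.allclose(grad_smooth_Y(X @ Y.T, X, Y, Ld, p), 0.0, atol=1e-12)

    def test_l21_gradient_is_unit_row(self):
        X = np.array([[3.0, 4.0]])
        Y = np.zeros((1, 2))
        p = SolverParams(lambda_m=0, lambda_d=0, lambda_l=1.0)
        g = grad_smooth_X(np.zeros((1, 1)), X, Y, np.zeros((1, 1)), p)
        assert np.allclose(g, [[0.6, 0.8]])

    def test_orthonormal_x_identity(self, rng):
        # lambdas = 0, X orthonormal columns: grad_Y = -A^T X + Y (X^T X) = -A^T X + Y
        A = rng.random((4, 3))
        X, _ = np.linalg.qr(rng.standard_normal((4, 2)))
        Y = rng.random((3, 2))
        p = SolverParams(lambda_m=0, lambda_d=0, lambda_l=0)
        g = grad_smooth_Y(A, X, Y, np.zeros((3, 3)), p)
        assert np.allclose(g, -A.T @ X + Y, atol=1e-12)


class TestProx:
    def test_projection_examples(self):
        V = np.array([[-1.0, 2.0], [0.0, -0.5]])
        assert np.array_equal(prox_nonneg(V, 1.0), [[0.0, 2.0], [0.0, 0.0]])
        W = np.array([[0.3, 1.0]])
        assert np.array_equal(prox_nonneg(W, 5.0), W)

    def test_matches_scalar_grid_oracle(self):
        # argmin_u delta(u) + (c/2)(u - v)^2 over a fine grid
        grid = np.linspace(-3, 3, 6001)
        for v in (-1.0, -0.2, 0.0, 0.5, 2.0):
            for c in (0.5, 1.0, 4.0):
                vals = np.where(grid >= 0, 0.5 * c * (grid - v) ** 2, np.inf)
                best = grid[np.argmin(vals)]
                assert prox_nonneg(np.array([[v]]), c)[0, 0] == pytest.approx(best, abs=1e-3)

    def test_invalid_step_constant(self):
        with pytest.raises(ParameterError):
            prox_nonneg(np.zeros((1, 1)), 0.0)


class TestStepConstant:
    def test_orthonormal_columns(self):
        Y, _ = np.linalg.qr(np.random.default_rng(0).standard_normal((6, 3)))
        p = SolverParams(lambda_m=0, lambda_d=0, lambda_l=0)
        assert step_constant(Y, np.zeros((6, 6)), 0.0, p) == pytest.approx(np.sqrt(3))

    def test_zero_factor_floors(self):
        p = SolverParams(lambda_m=0, lambda_d=0, lambda_l=0)
        assert step_constant(np.zeros((4, 2)), np.zeros((4, 4)), 0.0, p) > 0.0

    def test_quadratic_scaling(self, rng):
        Y = rng.random((5, 2))
        p = SolverParams(lambda_m=0, lambda_d=0, lambda_l=0)
        c1 = step_constant(Y, np.zeros((5, 5)), 0.0, p)
        c2 = step_constant(2 * Y, np.zeros((5, 5)), 0.0, p)
        assert c2 == pytest.approx(4 * c1)


class TestIpalmSolve:
    def test_descent_without_inertia(self):
        for seed in range(5):
            rng = np.random.default_rng(seed)
            A = rng.random((10, 6))
            Lm, Ld = random_laplacian(10, rng), random_laplacian(6, rng)
            lm, ld, ll = rng.random(3) * 0.5
            p = SolverParams(lambda_m=lm, lambda_d=ld, lambda_l=ll,
                             max_iter=150, tol=0, inertia="none")
            _, tr = ipalm_solve(A, Lm, Ld, nndsvd_init(A, 2), p)
            v = np.array(tr.objective_values)
            assert (np.diff(v) <= 1e-12 * v[0]).all()

    def test_exact_rank_recovery(self, rng):
        X0, Y0 = rng.random((20, 2)), rng.random((10, 2))
        A = X0 @ Y0.T
        Lm, Ld = zeros_problem(20, 10)
        p = SolverParams(lambda_m=0, lambda_d=0, lambda_l=0, max_iter=500, tol=0)
        f, _ = ipalm_solve(A, Lm, Ld, nndsvd_init(A, 2), p)
        assert 0.5 * np.linalg.norm(A - f.X @ f.Y.T) ** 2 <= 1e-6 * np.linalg.norm(A) ** 2

    def test_factors_stay_non_negative(self, rng):
        A = rng.random((8, 5))
        Lm, Ld = random_laplacian(8, rng), random_laplacian(5, rng)
        p = SolverParams(max_iter=100, tol=0)
        f, _ = ipalm_solve(A, Lm, Ld, nndsvd_init(A, 3), p)
        assert f.X.min() >= 0.0 and f.Y.min() >= 0.0

    def test_plain_nmf_kkt_complementarity(self, rng):
        A = rng.random((10, 6))
        Lm, Ld = zeros_problem(10, 6)
        p = SolverParams(lambda_m=0, lambda_d=0, lambda_l=0,
                         max_iter=5000, tol=1e-14, inertia="none")
        f, tr = ipalm_solve(A, Lm, Ld, nndsvd_init(A, 2), p)
        gx = grad_smooth_X(A, f.X, f.Y, Lm, p)
        gy = grad_smooth_Y(A, f.X, f.Y, Ld, p)
        assert np.abs(np.minimum(f.X, gx)).max() < 1e-4
        assert np.abs(np.minimum(f.Y, gy)).max() < 1e-4

    def test_bit_reproducible(self, rng):
        A = rng.random((9, 7))
        Lm, Ld = random_laplacian(9, rng), random_laplacian(7, rng)
        p = SolverParams(max_iter=80, tol=0)
        f1, t1 = ipalm_solve(A, Lm, Ld, nndsvd_init(A, 2), p)
        f2, t2 = ipalm_solve(A, Lm, Ld, nndsvd_init(A, 2), p)
        assert np.array_equal(f1.X, f2.X) and np.array_equal(f1.Y, f2.Y)
        assert t1.objective_values == t2.objective_values

    def test_inertia_accelerates_convergence(self):
        """Median iterations-to-tolerance with inertia <= without (10 seeds)."""
        from mdnmf.similarity import gip_kernels
        from mdnmf.graphs import build_graph_regularizers
        from mdnmf.simulate import PlantedConfig, planted_blocks

        iters = {"nesterov": [], "none": []}
        for seed in range(10):
            data = planted_blocks(PlantedConfig(m=20, d=10, n_blocks=2,
                                                within_block_prob=0.9,
                                                background_prob=0.02, seed=seed))
            ker = gip_kernels(data)
            regs = build_graph_regularizers(ker.GM, ker.GD, 5)
            init = nndsvd_init(data.A, 2)
            for mode in iters:
                p = SolverParams(max_iter=2000, tol=1e-8, inertia=mode)
                _, tr = ipalm_solve(data.A, regs.Lm_tilde, regs.Ld_tilde, init, p)
                iters[mode].append(tr.iterations_run)
        assert np.median(iters["nesterov"]) <= np.median(iters["none"])

    def test_negative_init_rejected(self):
        with pytest.raises(ParameterError):
            ipalm_solve(np.ones((2, 2)), np.zeros((2, 2)), np.zeros((2, 2)),
                        FactorPair(-np.ones((2, 1)), np.ones((2, 1))), SolverParams())

    def test_non_finite_input_raises(self):
        with pytest.raises(DivergenceError):
            ipalm_solve(np.array([[np.nan, 1.0]]), np.zeros((1, 1)), np.zeros((2, 2)),
                        FactorPair(np.ones((1, 1)), np.ones((2, 1))), SolverParams())


class TestPredictScores:
    def test_outer_product(self):
        f = FactorPair(np.array([[1.0], [2.0]]), np.array([[3.0]]))
        assert np.array_equal(predict_scores(f), [[3.0], [6.0]])

    def test_non_negative(self, rng):
        f = FactorPair(rng.random((6, 3)), rng.random((4, 3)))
        assert predict_scores(f).min() >= 0.0
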