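"""Unit tests for the objective, gradients, prox and spectral estimates."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import sparse

import cvxspca as cx
from cvxspca import (
    DataMatrix,
    InputError,
    ProblemSpec,
    estimate_lambda1,
    full_gradient,
    gamma_max,
    lipschitz_constant,
    objective_value,
    prox_l1,
    second_moment_matvec,
    vr_stochastic_gradient,
)


def _materialized_S(data: DataMatrix) -> np.ndarray:
    X = data.values.toarray() if data.is_sparse else data.values
    return (X.T @ X) / data.n


class TestSecondMomentMatvec:
    def test_diagonal_example(self):
        dm = DataMatrix([[2.0, 0.0], [0.0, 1.0]])
        np.testing.assert_allclose(second_moment_matvec(dm, [1.0, 1.0]), [2.0, 0.5])

    def test_zero_vector_maps_to_zero(self):
        dm = DataMatrix(np.random.default_rng(0).standard_normal((5, 3)))
        np.testing.assert_array_equal(second_moment_matvec(dm, np.zeros(3)), np.zeros(3))

    def test_matches_materialized_oracle(self):
        rng = np.random.default_rng(1)
        dm = DataMatrix(rng.standard_normal((20, 10)))
        z = rng.standard_normal(10)
        np.testing.assert_allclose(
            second_moment_matvec(dm, z), _materialized_S(dm) @ z, atol=1e-12
        )

    def test_sparse_dense_agree(self):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((15, 6))
        X[X < 0.5] = 0.0
        z = rng.standard_normal(6)
        dense = second_moment_matvec(DataMatrix(X), z)
        sp = second_moment_matvec(DataMatrix(sparse.csr_array(X)), z)
        np.testing.assert_allclose(sp, dense, atol=1e-12)

    def test_dimension_mismatch_rejected(self):
        dm = DataMatrix([[1.0, 2.0]])
        with pytest.raises(InputError):
            second_moment_matvec(dm, [1.0, 2.0, 3.0])


class TestEstimateLambda1:
    def test_diagonal_example(self):
        dm = DataMatrix([[2.0, 0.0], [0.0, 1.0]])
        est = estimate_lambda1(dm)
        assert est.converged
        assert est.lambda1 == pytest.approx(2.0, abs=1e-8)

    def test_rank_one_rows(self):
        a = np.array([1.0, 2.0, -2.0])
        dm = DataMatrix(np.tile(a, (4, 1)))
        est = estimate_lambda1(dm)
        assert est.lambda1 == pytest.approx(float(a @ a), rel=1e-8)

    def test_matches_dense_eigensolver(self, tiny_gaussian):
        est = estimate_lambda1(tiny_gaussian, tol=1e-13, max_iter=5000)
        expected = np.linalg.eigvalsh(_materialized_S(tiny_gaussian))[-1]
        assert est.lambda1 == pytest.approx(expected, abs=1e-8)
        assert abs(np.linalg.norm(est.vector) - 1.0) < 1e-10

    def test_all_zero_data(self):
        est = estimate_lambda1(DataMatrix(np.zeros((3, 4))))
        assert est.lambda1 == 0.0
        assert est.converged
        assert abs(np.linalg.norm(est.vector) - 1.0) < 1e-10


class TestObjectiveAndGradient:
    def test_zero_point_gives_zero_objective(self, tiny_gaussian):
        prob = ProblemSpec(lam=10.0, w=np.ones(8), gamma=0.5)
        assert objective_value(prob, tiny_gaussian, np.zeros(8)) == 0.0

    def test_scalar_arithmetic(self):
        dm = DataMatrix([[1.0]])
        prob = ProblemSpec(lam=2.0, w=[1.0], gamma=0.0)
        assert objective_value(prob, dm, [1.0]) == pytest.approx(-0.5)

    def test_matches_finite_sum_oracle(self, tiny_gaussian):
        # term-by-term mean of the per-sample losses plus the l1 penalty
        rng = np.random.default_rng(3)
        z = rng.standard_normal(8)
        w = rng.standard_normal(8)
        prob = ProblemSpec(lam=9.0, w=w, gamma=0.7)
        per_sample = []
        for i in range(tiny_gaussian.n):
            xi = tiny_gaussian.row(i)
            per_sample.append(0.5 * (prob.lam * z @ z - (xi @ z) ** 2) - w @ z)
        expected = np.mean(per_sample) + prob.gamma * np.abs(z).sum()
        assert objective_value(prob, tiny_gaussian, z) == pytest.approx(expected, abs=1e-10)

    def test_nonfinite_z_rejected(self, tiny_gaussian):
        prob = ProblemSpec(lam=9.0, w=np.ones(8), gamma=0.0)
        with pytest.raises(InputError):
            objective_value(prob, tiny_gaussian, np.full(8, np.nan))

    def test_gradient_at_zero_is_minus_w(self, tiny_gaussian):
        w = np.arange(8.0)
        prob = ProblemSpec(lam=9.0, w=w, gamma=0.0)
        np.testing.assert_array_equal(full_gradient(prob, tiny_gaussian, np.zeros(8)), -w)

    def test_gradient_scalar_example(self):
        dm = DataMatrix([[1.0]])
        prob = ProblemSpec(lam=2.0, w=[1.0], gamma=0.0)
        np.testing.assert_allclose(full_gradient(prob, dm, [3.0]), [2.0])

    def test_gradient_matches_finite_differences(self, tiny_gaussian):
        rng = np.random.default_rng(4)
        z = rng.standard_normal(8)
        w = rng.standard_normal(8)
        prob = ProblemSpec(lam=9.0, w=w, gamma=0.0)  # F only: smooth part
        g = full_gradient(prob, tiny_gaussian, z)
        h = 1e-6
        num = np.empty(8)
        for j in range(8):
            e = np.zeros(8)
            e[j] = h
            num[j] = (
                objective_value(prob, tiny_gaussian, z + e)
                - objective_value(prob, tiny_gaussian, z - e)
            ) / (2 * h)
        np.testing.assert_allclose(g, num, atol=1e-6)


class TestVrStochasticGradient:
    def test_reduces_to_full_gradient_at_reference(self):
        rng = np.random.default_rng(5)
        d = 6
        prob = ProblemSpec(lam=3.0, w=rng.standard_normal(d), gamma=0.0)
        z = rng.standard_normal(d)
        g = rng.standard_normal(d)
        out = vr_stochastic_gradient(prob, rng.standard_normal(d), z, z, g)
        np.testing.assert_array_equal(out, g)

    def test_scalar_example(self):
        prob = ProblemSpec(lam=2.0, w=[0.0], gamma=0.0)
        out = vr_stochastic_gradient(prob, [1.0], [1.0], [0.0], [0.0])
        np.testing.assert_allclose(out, [1.0])

    def test_unbiasedness_identity(self, tiny_gaussian):
        # averaging v_k over every sample recovers the full gradient exactly
        rng = np.random.default_rng(6)
        d = tiny_gaussian.d
        w = rng.standard_normal(d)
        prob = ProblemSpec(lam=9.0, w=w, gamma=0.0)
        z_tilde = rng.standard_normal(d)
        z_prev = rng.standard_normal(d)
        g_full = full_gradient(prob, tiny_gaussian, z_tilde)
        acc = np.zeros(d)
        for i in range(tiny_gaussian.n):
            acc += vr_stochastic_gradient(prob, tiny_gaussian.row(i), z_prev, z_tilde, g_full)
        mean_vk = acc / tiny_gaussian.n
        expected = full_gradient(prob, tiny_gaussian, z_prev)
        np.testing.assert_allclose(mean_vk, expected, atol=1e-12)


class TestProxL1:
    def test_zero_threshold_is_identity(self):
        v = np.array([1.5, -0.2, 0.0])
        np.testing.assert_array_equal(prox_l1(v, 0.0), v)

    def test_small_magnitudes_vanish(self):
        np.testing.assert_array_equal(prox_l1(np.array([0.5, -0.5]), 1.0), np.zeros(2))

    def test_matches_bruteforce_scalar_minimization(self):
        # each output component minimizes 1/2 (y - v_j)^2 + thr |y|
        rng = np.random.default_rng(7)
        v = rng.uniform(-3, 3, size=12)
        thr = 0.8
        out = prox_l1(v, thr)
        grid = np.linspace(-4, 4, 80001)
        for j in range(v.size):
            costs = 0.5 * (grid - v[j]) ** 2 + thr * np.abs(grid)
            assert out[j] == pytest.approx(grid[np.argmin(costs)], abs=1e-4)

    def test_negative_threshold_rejected(self):
        with pytest.raises(InputError):
            prox_l1(np.ones(3), -0.1)

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(
        a=st.lists(st.floats(-50, 50), min_size=1, max_size=8),
        b=st.lists(st.floats(-50, 50), min_size=1, max_size=8),
        thr=st.floats(0, 10),
    )
    def test_non_expansive(self, a, b, thr):
        n = min(len(a), len(b))
        x, y = np.array(a[:n]), np.array(b[:n])
        lhs = np.linalg.norm(prox_l1(x, thr) - prox_l1(y, thr))
        assert lhs <= np.linalg.norm(x - y) + 1e-12


class TestLipschitzConstant:
    def test_single_sample_exact(self):
        dm = DataMatrix([[2.0, 0.0]])  # ||x||^2 = 4
        info = lipschitz_constant(dm, 1.0, mode="exact")
        assert info.L_Q == pytest.approx(3.0)

    def test_paper_mode_is_lambda1(self):
        dm = DataMatrix([[2.0, 0.0], [0.0, 1.0]])
        info = lipschitz_constant(dm, 2.1, mode="paper")
        assert info.L_Q == pytest.approx(2.0, abs=1e-8)

    def test_exact_mode_bounds_gradient_differences(self, tiny_gaussian):
        rng = np.random.default_rng(8)
        lam = 9.0
        info = lipschitz_constant(tiny_gaussian, lam, mode="exact")
        assert info.L <= info.L_Q + 1e-12
        d = tiny_gaussian.d
        worst = 0.0
        for _ in range(1000):
            i = rng.integers(tiny_gaussian.n)
            xi = tiny_gaussian.row(i)
            z, y = rng.standard_normal(d), rng.standard_normal(d)
            gz = lam * z - xi * (xi @ z)
            gy = lam * y - xi * (xi @ y)
            worst = max(worst, np.linalg.norm(gz - gy) / np.linalg.norm(z - y))
        assert worst <= info.L_Q + 1e-9


class TestGammaMax:
    def test_examples(self):
        assert gamma_max([1.0, -2.0, 0.5]) == 2.0
        assert gamma_max(np.zeros(4)) == 0.0

    def test_above_gamma_max_ista_returns_zero(self, tiny_gaussian):
        rng = np.random.default_rng(9)
        w = rng.standard_normal(tiny_gaussian.d)
        prob = ProblemSpec(lam=9.0, w=w, gamma=1.01 * gamma_max(w))
        res = cx.fit_ista_reference(prob, tiny_gaussian, tol=1e-12)
        np.testing.assert_array_equal(res.z, np.zeros(tiny_gaussian.d))


class TestStrongConvexity:
    def test_modulus_lower_bound_on_random_pairs(self, tiny_gaussian):
        # F(z) - F(y) - grad F(y)^T (z - y) >= (lam - lambda1)/2 ||z - y||^2
        rng = np.random.default_rng(10)
        lam1 = estimate_lambda1(tiny_gaussian, tol=1e-13).lambda1
        lam = 1.3 * lam1
        w = rng.standard_normal(tiny_gaussian.d)
        prob = ProblemSpec(lam=lam, w=w, gamma=0.0)
        mu = lam - lam1
        for _ in range(50):
            z = rng.standard_normal(tiny_gaussian.d)
            y = rng.standard_normal(tiny_gaussian.d)
            lhs = (
                objective_value(prob, tiny_gaussian, z)
                - objective_value(prob, tiny_gaussian, y)
                - full_gradient(prob, tiny_gaussian, y) @ (z - y)
            )
            assert lhs >= 0.5 * mu * np.linalg.norm(z - y) ** 2 - 1e-8


class TestCentering:
    def test_centering_removes_column_means(self):
        rng = np.random.default_rng(11)
        X = rng.standard_normal((40, 5)) + 3.0
        centered = cx.center_data(DataMatrix(X))
        np.testing.assert_allclose(centered.values.mean(axis=0), np.zeros(5), atol=1e-12)
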