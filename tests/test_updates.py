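import numpy as np
import pytest

from rnmf import (
    RegularizerSpec,
    objective_value,
    project_simplex,
    refresh_residual,
    simplex_optimality_gap,
    update_component_l1,
    update_component_related,
    update_component_tikhonov,
    update_mixing_column,
)
from rnmf.model import FactorModel, objective_from_arrays

from oracles import grid2_min_oracle, nnls_oracle, scalar_min_oracle, simplex_oracle


def random_block_fixture(rng, n=6, m=5, k=3, alpha=1.0):
    W = rng.uniform(size=(n, k))
    A = rng.uniform(size=(m, k))
    A = A / A.sum(axis=0) * alpha
    X = rng.uniform(size=(n, m))
    return X, W, A


class TestMixingColumn:
    def test_exact_rank_one_data_recovered(self, rng):
        w = rng.uniform(0.5, 1.5, size=4)
        a_star = project_simplex(rng.standard_normal(5), 1.0)
        R = np.outer(w, a_star)
        a = update_mixing_column(R, w, np.full(5, 0.2), alpha=1.0, tau_a=1e-12)
        np.testing.assert_allclose(a, a_star, atol=1e-9)

    def test_zero_base_vector_returns_previous(self):
        a_prev = np.array([0.2, 0.3, 0.5])
        R = np.ones((2, 3))
        a = update_mixing_column(R, np.zeros(2), a_prev, alpha=1.0, tau_a=0.5)
        np.testing.assert_allclose(a, a_prev, atol=1e-15)

    def test_fixture_matches_simplex_oracle(self):
        R = np.array([[1.0, 0.0, 2.0], [0.0, 1.0, 0.0]])
        w = np.array([1.0, 1.0])
        a_prev = np.full(3, 1 / 3)
        tau_a = 0.1
        c = (R.T @ w + tau_a * a_prev) / (w @ w + tau_a)
        a = update_mixing_column(R, w, a_prev, alpha=1.0, tau_a=tau_a)
        np.testing.assert_allclose(a, simplex_oracle(c, 1.0), atol=1e-12)

    def test_output_feasible_with_zero_gap(self, rng):
        for _ in range(30):
            n, m = 5, 6
            R = rng.standard_normal((n, m))
            w = rng.uniform(size=n)
            a_prev = project_simplex(rng.standard_normal(m), 1.0)
            tau_a = 0.05
            a = update_mixing_column(R, w, a_prev, 1.0, tau_a)
            assert np.all(a >= 0)
            assert abs(a.sum() - 1.0) <= 1e-12 * m
            # gradient of the subproblem at the returned point
            grad = 2 * ((w @ w + tau_a) * a - (R.T @ w + tau_a * a_prev))
            assert simplex_optimality_gap(grad, a) <= 1e-8

    def test_requires_positive_tau(self):
        with pytest.raises(ValueError):
            update_mixing_column(np.ones((2, 2)), np.ones(2), np.full(2, 0.5), 1.0, 0.0)


class TestComponentL1:
    def test_unregularized_exact_data(self, rng):
        w_star = rng.uniform(size=5)
        a = rng.uniform(0.1, 1.0, size=4)
        R = np.outer(w_star, a)
        w = update_component_l1(R, a, np.zeros(5), lam=0.0, tau_w=0.0)
        np.testing.assert_allclose(w, w_star, atol=1e-12)

    def test_full_shrinkage_threshold(self, rng):
        R = rng.uniform(size=(4, 3))
        a = rng.uniform(0.1, 1.0, size=3)
        lam = 2.0 * np.max(R @ a) + 1e-9
        w = update_component_l1(R, a, np.zeros(4), lam=lam, tau_w=0.0)
        assert np.all(w == 0.0)

    def test_each_coordinate_matches_scalar_oracle(self, rng):
        n, m = 3, 4
        R = rng.standard_normal((n, m))
        a = rng.uniform(0.1, 1.0, size=m)
        a *= np.sqrt(2.0 / (a @ a))  # ||a||^2 = 2
        lam = 1.0
        w = update_component_l1(R, a, np.zeros(n), lam=lam, tau_w=0.0)
        f = R @ a
        np.testing.assert_allclose(w, np.maximum(0.0, f - 0.5) / 2.0, atol=1e-12)
        for i in range(n):
            # independent 1-D minimization of the separable subproblem
            def sub(t, i=i):
                return (a @ a) * t**2 - 2 * f[i] * t + lam * t

            t_star = scalar_min_oracle(sub, 0.0, max(1.0, 2 * abs(f[i])))
            assert w[i] == pytest.approx(t_star, abs=1e-6)

    def test_sparsity_monotone_in_lam(self, rng):
        R = rng.standard_normal((8, 6))
        a = rng.uniform(0.1, 1.0, size=6)
        prev_w, prev_zeros = None, -1
        for lam in [0.0, 0.1, 0.3, 0.8, 2.0, 6.0]:
            w = update_component_l1(R, a, np.zeros(8), lam=lam, tau_w=0.0)
            zeros = int(np.sum(w == 0))
            if prev_w is not None:
                assert np.all(w <= prev_w + 1e-12)
                assert zeros >= prev_zeros
            prev_w, prev_zeros = w, zeros

    def test_zero_mixing_column_requires_tau(self):
        with pytest.raises(ValueError):
            update_component_l1(np.ones((2, 2)), np.zeros(2), np.ones(2), 0.1, 0.0)


class TestComponentTikhonov:
    def test_lam_zero_equals_l1_lam_zero(self, rng):
        R = rng.standard_normal((5, 4))
        a = rng.uniform(0.1, 1.0, size=4)
        w_prev = rng.uniform(size=5)
        w_tik = update_component_tikhonov(R, a, w_prev, 0.0, np.eye(5), tau_w=1e-3)
        w_l1 = update_component_l1(R, a, w_prev, 0.0, tau_w=1e-3)
        np.testing.assert_allclose(w_tik, w_l1, atol=1e-10)

    def test_identity_filter_matches_closed_form(self, rng):
        for _ in range(20):
            n, m = 6, 5
            R = rng.standard_normal((n, m))
            a = rng.uniform(0.1, 1.0, size=m)
            w_prev = rng.uniform(size=n)
            lam, tau_w = 0.7, 0.01
            w = update_component_tikhonov(R, a, w_prev, lam, np.eye(n), tau_w)
            closed = np.maximum(0.0, R @ a + tau_w * w_prev) / (a @ a + lam + tau_w)
            np.testing.assert_allclose(w, closed, atol=1e-10)

    def test_difference_filter_matches_nnls_oracle(self, rng):
        n, m = 5, 4
        L = np.zeros((n, n))
        for i in range(n - 1):
            L[i, i], L[i, i + 1] = -1.0, 1.0
        R = rng.standard_normal((n, m)) * 0.5
        a = rng.uniform(0.1, 1.0, size=m)
        w_prev = rng.uniform(size=n)
        lam, tau_w = 1.0, 1e-6
        w = update_component_tikhonov(R, a, w_prev, lam, L, tau_w)
        G = (a @ a + tau_w) * np.eye(n) + lam * L.T @ L
        f = R @ a + tau_w * w_prev
        np.testing.assert_allclose(w, nnls_oracle(G, f), atol=1e-8)


class TestComponentRelated:
    def test_lam_zero_rows_solve_plain_nnls(self, rng):
        n, m, k = 5, 6, 3
        X = rng.uniform(size=(n, m))
        A = rng.uniform(size=(m, k))
        A /= A.sum(axis=0)
        W = update_component_related(X, A, np.zeros((n, k)), 0.0, [(0, 1)], 0.0)
        G = A.T @ A
        for i in range(n):
            np.testing.assert_allclose(W[i], nnls_oracle(G, A.T @ X[i]), atol=1e-8)

    def test_large_lam_forces_paired_columns_together(self, rng):
        n, m, k = 8, 6, 3
        X = rng.uniform(size=(n, m))
        A = rng.uniform(size=(m, k))
        A /= A.sum(axis=0)
        W = update_component_related(X, A, rng.uniform(size=(n, k)), 1e6, [(0, 1)], 1e-6)
        d = np.linalg.norm(W[:, 0] - W[:, 1])
        assert d <= 1e-3 * max(np.linalg.norm(W[:, 0]), 1e-30)

    def test_micro_fixture_matches_grid_oracle(self):
        # one feature row, two components: 2-variable problem on a grid
        X = np.array([[1.0, 0.4]])
        A = np.array([[0.7, 0.2], [0.3, 0.8]])
        lam, tau_w = 0.5, 0.01
        W_prev = np.array([[0.3, 0.6]])
        W = update_component_related(X, A, W_prev, lam, [(0, 1)], tau_w)

        def objective(v):
            recon = A @ v
            return (
                np.sum((X[0] - recon) ** 2)
                + lam * (v[0] - v[1]) ** 2
                + tau_w * np.sum((v - W_prev[0]) ** 2)
            )

        v_star = grid2_min_oracle(objective, [0.0, 0.0], [3.0, 3.0])
        np.testing.assert_allclose(W[0], v_star, atol=1e-4)

    def test_invalid_pair_indices(self, rng):
        X, W, A = random_block_fixture(rng)
        with pytest.raises(ValueError):
            update_component_related(X, A, W, 1.0, [(0, 5)], 1e-6)


class TestResidualBookkeeping:
    def test_trivial_residuals(self, rng):
        X = rng.uniform(size=(4, 3))
        A = rng.uniform(size=(3, 2))
        A /= A.sum(axis=0)
        np.testing.assert_array_equal(refresh_residual(X, np.zeros((4, 2)), A), X)
        W = rng.uniform(size=(4, 2))
        np.testing.assert_allclose(
            refresh_residual(W @ A.T, W, A), np.zeros((4, 3)), atol=1e-15
        )

    def test_cumulative_drift_bounded_over_50_sweeps(self, rng):
        n, m, k = 10, 8, 3
        X, W, A = random_block_fixture(rng, n, m, k)
        tau = 1e-6
        R = refresh_residual(X, W, A)
        for _ in range(50):
            for l in range(k):
                R += np.outer(W[:, l], A[:, l])
                W[:, l] = update_component_l1(R, A[:, l], W[:, l], 0.01, tau)
                A[:, l] = update_mixing_column(R, W[:, l], A[:, l], 1.0, tau)
                R -= np.outer(W[:, l], A[:, l])
        drift = np.linalg.norm(R - refresh_residual(X, W, A)) / np.linalg.norm(X)
        assert drift <= 1e-6


class TestDescent:
    """Each exact block update can never increase the global objective."""

    def test_single_block_updates_decrease_objective(self, rng):
        n, m, k = 7, 6, 3
        X, W, A = random_block_fixture(rng, n, m, k)
        tau = 1e-8
        regs = [
            RegularizerSpec("none"),
            RegularizerSpec("l1", 0.2),
            RegularizerSpec("tikhonov", 0.3, filter=np.eye(n)),
            RegularizerSpec("related", 0.4, pairs=((0, 1), (1, 2))),
        ]
        for reg in regs:
            Wc, Ac = W.copy(), A.copy()
            F0 = objective_from_arrays(X, Wc, Ac, reg)
            R = X - Wc @ Ac.T
            if reg.kind == "related":
                Wc = update_component_related(X, Ac, Wc, reg.lam, reg.pairs, tau)
            else:
                l = 0
                R += np.outer(Wc[:, l], Ac[:, l])
                if reg.kind == "tikhonov":
                    Wc[:, l] = update_component_tikhonov(
                        R, Ac[:, l], Wc[:, l], reg.lam, reg.filter, tau
                    )
                else:
                    Wc[:, l] = update_component_l1(R, Ac[:, l], Wc[:, l], reg.lam, tau)
                R -= np.outer(Wc[:, l], Ac[:, l])
            F1 = objective_from_arrays(X, Wc, Ac, reg)
            assert F1 <= F0 + 1e-10 * (1 + F0)
            # now one mixing-column update
            R = X - Wc @ Ac.T
            R += np.outer(Wc[:, 0], Ac[:, 0])
            Ac[:, 0] = update_mixing_column(R, Wc[:, 0], Ac[:, 0], 1.0, tau)
            F2 = objective_from_arrays(X, Wc, Ac, reg)
            assert F2 <= F1 + 1e-10 * (1 + F1)
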