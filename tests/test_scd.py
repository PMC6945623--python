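"""Coordinate-descent NNLS: system assembly, exactness against a
brute-force QP oracle, and bookkeeping invariants."""

import numpy as np
import pytest

from conftest import nnls_oracle, random_spd_system
from nmfkit import TargetMatrix
from nmfkit.scd import QuadraticSystem, build_system, quad_objective, scd_solve


class TestBuildSystem:
    def test_identity_basis_fully_observed(self):
        A = TargetMatrix([[3.0], [5.0]])
        system = build_system(A, np.eye(2), (0.0, 0.0, 0.0))
        assert not system.per_column
        np.testing.assert_allclose(system.V, np.eye(2))
        np.testing.assert_allclose(system.U, [[-3.0], [-5.0]])

    def test_l1_weight_shifts_U(self):
        A = TargetMatrix([[3.0], [5.0]])
        system = build_system(A, np.eye(2), (0.0, 0.0, 1.0))
        np.testing.assert_allclose(system.U, [[-2.0], [-4.0]])

    @pytest.mark.parametrize("b1, b3", [(0.0, 0.0), (0.7, 0.0), (0.3, 1.5)])
    def test_missing_row_restricts_to_observed_subset(self, b1, b3):
        # second row of the single column is missing: I_j = {0}
        A = TargetMatrix([[4.0, 1.0], [np.nan, 1.0]])
        W = np.array([[1.0], [2.0]])
        system = build_system(A, W, (b1, 0.0, b3))
        assert system.per_column
        assert system.V[0, 0, 0] == pytest.approx(1.0 + b1)
        assert system.U[0, 0] == pytest.approx(-4.0 + b3)

    def test_per_column_gram_matches_explicit_row_slicing(self, rng):
        values = rng.uniform(0, 3, size=(10, 6))
        observed = rng.uniform(size=(10, 6)) > 0.3
        observed[0, :] = observed[:, 0] = True
        A = TargetMatrix(values, observed)
        W = rng.uniform(size=(10, 3))
        system = build_system(A, W, (0.4, 0.2, 0.1))
        for j in range(6):
            rows = observed[:, j]
            Wj = W[rows]
            V_expected = Wj.T @ Wj + 0.4 * np.eye(3) \
                + 0.2 * (np.ones((3, 3)) - np.eye(3))
            np.testing.assert_allclose(system.V[j], V_expected, atol=1e-12)
            np.testing.assert_allclose(
                system.U[:, j], -Wj.T @ values[rows, j] + 0.1, atol=1e-12)

    def test_rejects_violated_positivity_condition(self, small_target, rng):
        W = rng.uniform(size=(12, 2))
        with pytest.raises(ValueError):
            build_system(small_target, W, (0.1, 0.2, 0.0))


class TestScdSolve:
    def test_identity_system_solves_in_one_sweep(self):
        system = QuadraticSystem(V=np.eye(2), U=np.array([[-3.0], [-5.0]]),
                                 per_column=False)
        H, sweeps = scd_solve(system, np.zeros((2, 1)), n_inner=1)
        np.testing.assert_allclose(H, [[3.0], [5.0]])

    def test_outward_gradient_clamps_to_zero(self):
        system = QuadraticSystem(V=np.eye(1), U=np.array([[2.0]]),
                                 per_column=False)
        H, _ = scd_solve(system, np.zeros((1, 1)), n_inner=3)
        assert H[0, 0] == 0.0

    def test_matches_active_set_oracle(self, rng):
        for _ in range(20):
            k = int(rng.integers(1, 5))
            V, u = random_spd_system(rng, k)
            system = QuadraticSystem(V=V, U=u[:, None], per_column=False)
            H, _ = scd_solve(system, np.zeros((k, 1)), n_inner=2000,
                             inner_rel_tol=1e-15)
            np.testing.assert_allclose(H[:, 0], nnls_oracle(V, u), atol=1e-8)

    def test_sweeps_never_increase_quadratic_objective(self, rng):
        k = 4
        V, _ = random_spd_system(rng, k)
        U = rng.uniform(-2, 2, size=(k, 7))
        system = QuadraticSystem(V=V, U=U, per_column=False)
        H = rng.uniform(0, 2, size=(k, 7))
        prev = quad_objective(system, H)
        for _ in range(10):
            H, _ = scd_solve(system, H, n_inner=1, early_stop=False)
            cur = quad_objective(system, H)
            assert cur <= prev + 1e-12 * max(1.0, abs(prev))
            prev = cur

    def test_incremental_gradient_matches_recomputation(self, rng):
        """Solving with n sweeps at once equals n restarted single sweeps,
        so the running rank-1 gradient patches agree with rebuilding
        V @ H + U from scratch."""
        k = 4
        V, _ = random_spd_system(rng, k)
        U = rng.uniform(-2, 2, size=(k, 6))
        system = QuadraticSystem(V=V, U=U, per_column=False)
        H_multi, _ = scd_solve(system, np.zeros((k, 6)), n_inner=5,
                               early_stop=False)
        H_restart = np.zeros((k, 6))
        for _ in range(5):
            H_restart, _ = scd_solve(system, H_restart, n_inner=1,
                                     early_stop=False)
        # each restart rebuilds V @ H + U from scratch, so agreement with
        # the single incremental run validates the rank-1 patches
        np.testing.assert_allclose(H_multi, H_restart, rtol=1e-10,
                                   atol=1e-12)

    def test_output_exactly_nonnegative(self, rng):
        V, u = random_spd_system(rng, 3)
        system = QuadraticSystem(V=V, U=np.tile(u[:, None], (1, 9)),
                                 per_column=False)
        H, _ = scd_solve(system, rng.uniform(0, 1, size=(3, 9)), n_inner=50)
        assert H.min() >= 0.0
        assert not np.signbit(H).any()

    def test_negative_diagonal_rejected(self):
        V = np.array([[-0.5]])
        system = QuadraticSystem(V=V, U=np.array([[1.0]]), per_column=False)
        with pytest.raises(ValueError, match="diagonal"):
            scd_solve(system, np.zeros((1, 1)), n_inner=1)

    def test_fixed_coordinates_hold_and_free_ones_adapt(self, rng):
        k = 3
        V, u = random_spd_system(rng, k)
        system = QuadraticSystem(V=V, U=u[:, None], per_column=False)
        H0 = np.array([[1.5], [0.0], [0.0]])
        fixed = np.array([[True], [False], [False]])
        H, _ = scd_solve(system, H0, n_inner=2000, fixed=fixed,
                         inner_rel_tol=1e-15)
        assert H[0, 0] == 1.5
        # the free block solves the reduced QP with the fixed contribution
        # folded into the linear term
        free = [1, 2]
        u_red = u[free] + V[np.ix_(free, [0])] @ np.array([1.5])
        expected = nnls_oracle(V[np.ix_(free, free)], u_red)
        np.testing.assert_allclose(H[free, 0], expected, atol=1e-8)

    def test_per_column_system_solution_matches_column_by_column(self, rng):
        values = rng.uniform(0, 3, size=(12, 5))
        observed = rng.uniform(size=(12, 5)) > 0.3
        observed[0, :] = observed[:, 0] = True
        A = TargetMatrix(values, observed)
        W = rng.uniform(size=(12, 3))
        system = build_system(A, W, (0.2, 0.0, 0.0))
        H, _ = scd_solve(system, np.zeros((3, 5)), n_inner=2000,
                         inner_rel_tol=1e-15)
        for j in range(5):
            expected = nnls_oracle(system.V[j], system.U[:, j])
            np.testing.assert_allclose(H[:, j], expected, atol=1e-8)
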