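import numpy as np
import pytest
from scipy.linalg import subspace_angles

from omrfe.solvers import (
    Block,
    BlockSpec,
    SolverConfig,
    compute_lambda,
    omrfe_objective,
    solve_fe,
    solve_om_pca,
    solve_ombrfe,
    solve_omrfe,
    solve_rfe,
)

from oracles import best_projected_objective


class TestComputeLambda:
    @pytest.mark.parametrize(
        "l, m, n, expected",
        [
            (0.0001, 5000, 200, np.sqrt(0.5)),
            (1.0, 1, 1, 1.0),
            (0.001, 100, 400, np.sqrt(0.4)),
        ],
    )
    def test_rule(self, l, m, n, expected):
        assert compute_lambda(l, m, n) == pytest.approx(expected, rel=1e-12)

    @pytest.mark.parametrize("args", [(0.0, 5, 5), (-1.0, 5, 5), (0.1, 0, 5)])
    def test_nonpositive_rejected(self, args):
        with pytest.raises(ValueError):
            compute_lambda(*args)


class TestSolveFe:
    def test_exact_rank_k_reconstruction(self, rng):
        W0 = rng.standard_normal((20, 3))
        V0 = rng.standard_normal((10, 3))
        V0 -= V0.mean(axis=0)  # zero column mean
        X = W0 @ V0.T
        res = solve_fe(X, 3)
        assert np.linalg.norm(X - res.W @ res.V.T) < 1e-8

    def test_shift_invariance_of_subspace(self, rng):
        X = rng.standard_normal((15, 8))
        u = rng.standard_normal(15)
        r0, r1 = solve_fe(X, 2), solve_fe(X + u[:, None], 2)
        # identical up to column sign
        for j in range(2):
            assert (
                np.allclose(r0.W[:, j], r1.W[:, j], atol=1e-8)
                or np.allclose(r0.W[:, j], -r1.W[:, j], atol=1e-8)
            )

    def test_mean_of_constant_rows(self):
        X = np.tile(np.array([2.0, -1.0, 0.5])[:, None], (1, 6))
        res = solve_fe(X, 1)
        np.testing.assert_allclose(res.b, [2.0, -1.0, 0.5], atol=1e-12)

    def test_k_too_large(self, rng):
        with pytest.raises(ValueError):
            solve_fe(rng.standard_normal((5, 4)), 5)


class TestSolveOmPca:
    def test_identical_columns_fit_perfectly(self, rng):
        col = rng.standard_normal(12)
        X = np.tile(col[:, None], (1, 7))
        res = solve_om_pca(X, 2)
        assert res.objective_trace[-1] == pytest.approx(0.0, abs=1e-10)
        np.testing.assert_allclose(res.b, col, atol=1e-10)

    def test_equal_weight_limit_reduces_to_fe(self, rng):
        X = rng.standard_normal((30, 12))
        fe = solve_fe(X, 3)
        one_step = solve_om_pca(X, 3, max_iter=1)  # weights still all-ones
        assert subspace_angles(one_step.W, fe.W).max() < 1e-8

    def test_outlier_free_data_close_to_fe_subspace(self, rng):
        # without outliers the IRLS weights stay near-uniform, so the
        # fitted subspace agrees with plain PCA; the dominant subspace
        # must be well separated for the comparison to be identifiable
        U = rng.standard_normal((40, 2)) * [5.0, 3.0]
        X = U @ rng.standard_normal((2, 25)) + 0.01 * rng.standard_normal((40, 25))
        fe = solve_fe(X, 2)
        om = solve_om_pca(X, 2)
        assert subspace_angles(om.W, fe.W).max() < 1e-3

    def test_objective_nonincreasing(self, rng):
        X = rng.standard_normal((50, 20))
        res = solve_om_pca(X, 3, max_iter=60)
        diffs = np.diff(res.objective_trace)
        assert np.all(diffs <= 1e-10)

    def test_nonconvergence_is_flagged_not_raised(self, rng):
        res = solve_om_pca(rng.standard_normal((30, 10)), 2, max_iter=2)
        assert res.converged is False


class TestSolveOmrfe:
    def test_noiseless_rank_k_factorization(self, rng):
        W0 = rng.standard_normal((40, 3))
        V0 = rng.standard_normal((12, 3))
        V0 -= V0.mean(axis=0)
        X = W0 @ V0.T
        res = solve_omrfe(X, SolverConfig(k=3, l=1e-8))
        assert res.converged
        assert res.primal_residual_trace[-1] < 1e-7
        assert np.linalg.norm(X - res.W @ res.V.T) / np.linalg.norm(X) < 1e-4

    def test_optimal_mean_absorbs_feature_shift(self, rng):
        X = rng.standard_normal((60, 15))
        u = rng.standard_normal(60)
        cfg = SolverConfig(k=3)
        r0 = solve_omrfe(X, cfg)
        r1 = solve_omrfe(X + u[:, None], cfg)
        np.testing.assert_allclose(r1.W, r0.W, atol=1e-6)
        np.testing.assert_allclose(r1.b - r0.b, u, atol=1e-6)

    def test_converges_on_random_input(self, rng):
        X = rng.standard_normal((200, 40))
        res = solve_omrfe(X, SolverConfig(k=4, tol=1e-7, max_iter=500))
        assert res.converged
        assert res.primal_residual_trace[-1] < 1e-7
        assert len(res.objective_trace) == res.n_iter
        assert np.linalg.norm(res.V.T @ res.V - np.eye(4)) < 1e-8

    def test_objective_not_above_initialization(self, rng):
        for _ in range(5):
            X = rng.standard_normal((30, 10)) * rng.uniform(0.5, 2)
            cfg = SolverConfig(k=2, l=0.05)
            res = solve_omrfe(X, cfg)
            lam = compute_lambda(cfg.l, *X.shape)
            b0 = X.mean(axis=1)
            W0 = (X - b0[:, None]) @ res.V
            obj0 = omrfe_objective(X, W0, b0, res.V, lam)
            obj1 = omrfe_objective(X, res.W, res.b, res.V, lam)
            assert obj1 <= obj0 + 1e-9 * max(1.0, obj0)

    def test_nan_input_rejected(self):
        X = np.ones((5, 4))
        X[2, 1] = np.nan
        with pytest.raises(ValueError):
            solve_omrfe(X, SolverConfig(k=2))

    def test_determinism_bit_identical(self, rng):
        X = rng.standard_normal((30, 12))
        cfg = SolverConfig(k=3)
        r0, r1 = solve_omrfe(X, cfg), solve_omrfe(X, cfg)
        np.testing.assert_array_equal(r0.W, r1.W)
        np.testing.assert_array_equal(r0.b, r1.b)
        np.testing.assert_array_equal(r0.E, r1.E)

    @pytest.mark.parametrize("l", [1e-4, 0.5])
    def test_matches_generic_minimizer_at_small_scale(self, rng, l):
        X = rng.standard_normal((8, 5))
        cfg = SolverConfig(k=2, l=l)
        res = solve_omrfe(X, cfg)
        lam = compute_lambda(l, 8, 5)
        obj_alm = omrfe_objective(X, res.W, res.b, res.V, lam)
        b0 = X.mean(axis=1)
        obj_best = best_projected_objective(
            X - b0[:, None], res.V, lam, n_restarts=200, seed=0
        )
        assert obj_alm <= obj_best + 1e-3

    def test_procrustes_mode_converges(self, rng):
        X = rng.standard_normal((60, 20))
        res = solve_omrfe(X, SolverConfig(k=3, v_mode="procrustes"))
        assert res.converged
        assert np.linalg.norm(res.V.T @ res.V - np.eye(3)) < 1e-8


class TestSolveRfe:
    def test_determinism_bit_identical(self, rng):
        X = rng.standard_normal((25, 10))
        cfg = SolverConfig(k=2)
        r0, r1 = solve_rfe(X, cfg), solve_rfe(X, cfg)
        np.testing.assert_array_equal(r0.W, r1.W)

    def test_mean_frozen_at_euclidean_mean(self, rng):
        X = rng.standard_normal((20, 8)) + 3.0
        res = solve_rfe(X, SolverConfig(k=2))
        np.testing.assert_allclose(res.b, X.mean(axis=1), atol=1e-12)

    def test_objective_never_beats_optimal_mean(self, rng):
        # constant offset on 10% of samples corrupts the Euclidean mean
        diffs = []
        for seed in range(30):
            r = np.random.default_rng(seed)
            X = r.standard_normal((40, 20))
            X[:, r.choice(20, 2, replace=False)] += 3.0
            cfg = SolverConfig(k=2, l=0.05)
            lam = compute_lambda(cfg.l, *X.shape)
            rfe = solve_rfe(X, cfg)
            om = solve_omrfe(X, cfg)
            obj_rfe = omrfe_objective(X, rfe.W, rfe.b, rfe.V, lam)
            obj_om = omrfe_objective(X, om.W, om.b, om.V, lam)
            diffs.append(obj_rfe - obj_om)
        assert np.median(diffs) >= -1e-9


class TestBlockSpec:
    def test_gap_rejected(self):
        with pytest.raises(ValueError):
            BlockSpec([Block("a", 0, 10, 1e-4), Block("b", 12, 20, 1e-4)])

    def test_overlap_rejected(self):
        with pytest.raises(ValueError):
            BlockSpec([Block("a", 0, 10, 1e-4), Block("b", 8, 20, 1e-4)])

    def test_tiling_validated_at_fit_time(self, rng):
        X = rng.standard_normal((30, 10))
        spec = BlockSpec([Block("a", 0, 20, 1e-4)])
        with pytest.raises(ValueError):
            solve_ombrfe(X, spec, SolverConfig(k=2))


class TestSolveOmbrfe:
    def test_single_block_identical_to_omrfe(self, rng):
        X = rng.standard_normal((40, 15))
        cfg = SolverConfig(k=3, l=2e-4)
        spec = BlockSpec([Block("all", 0, 40, 2e-4)])
        rb = solve_ombrfe(X, spec, cfg)
        ro = solve_omrfe(X, cfg)
        np.testing.assert_array_equal(rb.W, ro.W)
        np.testing.assert_array_equal(rb.V, ro.V)
        np.testing.assert_array_equal(rb.b, ro.b)
        np.testing.assert_array_equal(rb.E, ro.E)

    def test_duplicated_blocks_give_identical_factors(self, rng):
        half = rng.standard_normal((25, 12))
        X = np.vstack([half, half])
        spec = BlockSpec([Block("x1", 0, 25, 1e-4), Block("x2", 25, 50, 1e-4)])
        res = solve_ombrfe(X, spec, SolverConfig(k=2))
        # identical inputs solved deterministically: equal up to column sign
        for j in range(2):
            assert (
                np.allclose(res.W[:25, j], res.W[25:, j], atol=1e-10)
                or np.allclose(res.W[:25, j], -res.W[25:, j], atol=1e-10)
            )

    def test_shapes_and_block_orthonormality(self, rng):
        X = rng.standard_normal((40, 10))
        spec = BlockSpec(
            [Block("a", 0, 15, 1e-4), Block("b", 15, 28, 1e-3), Block("c", 28, 40, 1e-4)]
        )
        res = solve_ombrfe(X, spec, SolverConfig(k=2))
        assert res.W.shape == (40, 2)
        assert res.b.shape == (40,)
        assert res.V is None
        assert len(res.block_results) == 3
        for sub in res.block_results:
            assert np.linalg.norm(sub.V.T @ sub.V - np.eye(2)) < 1e-8
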