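"""Fused group Lasso solver: algebra, ADMM, tuning and selection."""

import numpy as np
import pytest
import statsmodels.api as sm

from dfgl import (
    CVSpec,
    PenaltySpec,
    SolverConfig,
    adaptive_weights,
    cross_validate,
    default_lambda_grid,
    fit_dfgl_two_stage,
    fit_fgl,
    fusion_matrix,
    group_soft_threshold,
    penalized_objective,
    soft_threshold,
    standardize,
)
from dfgl.losses import grad_neg_loglik, lipschitz_constant, neg_loglik
from dfgl.simulate import ScenarioSpec, simulate_dataset
from dfgl.data import CoefficientMatrix
from dfgl.solver import admm_B_update, admm_inner_solve, fusion_pairs

from .conftest import make_grouped
from ._oracles import smoothed_fgl_objective_min


class TestFusionMatrix:
    def test_two_groups_single_column(self):
        np.testing.assert_array_equal(fusion_matrix(2), [[1.0], [-1.0]])

    def test_three_groups_columns_and_identity(self):
        H = fusion_matrix(3)
        np.testing.assert_array_equal(
            H, [[1, 1, 0], [-1, 0, 1], [0, -1, -1]]
        )
        rng = np.random.default_rng(0)
        D = rng.standard_normal((4, 3))
        manual = sum(
            np.abs(D[:, g] - D[:, h]).sum() for g, h in fusion_pairs(3)
        )
        assert np.abs(D @ H).sum() == pytest.approx(manual, rel=1e-12)

    @pytest.mark.parametrize("G", range(2, 8))
    def test_gram_identity(self, G):
        H = fusion_matrix(G)
        np.testing.assert_allclose(
            H @ H.T, G * np.eye(G) - np.ones((G, G)), atol=1e-12
        )

    def test_single_group_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            fusion_matrix(1)


class TestThresholds:
    def test_soft_threshold_three_cases(self):
        assert soft_threshold(1.0, 0.4) == pytest.approx(0.6)
        assert soft_threshold(-0.3, 0.4) == 0.0
        assert soft_threshold(-1.0, 0.4) == pytest.approx(-0.6)

    def test_group_soft_threshold(self):
        np.testing.assert_allclose(group_soft_threshold([3.0, 4.0], 5.0), [0, 0])
        np.testing.assert_allclose(group_soft_threshold([3.0, 4.0], 0.0), [3, 4])
        np.testing.assert_allclose(
            group_soft_threshold([3.0, 4.0], 2.5), [1.5, 2.0]
        )


class TestAdmmBUpdate:
    def test_two_group_closed_form(self):
        H = fusion_matrix(2)
        V = np.ones((3, 2))
        out = admm_B_update(V, H, eta=1.0, rho=1.0)
        # system matrix [[3,-1],[-1,3]]; rows of ones map to (1/2, 1/2)
        np.testing.assert_allclose(out, 0.5 * np.ones((3, 2)), atol=1e-12)

    def test_rho_zero_reduces_to_gradient_scaling(self):
        H = fusion_matrix(3)
        V = np.random.default_rng(1).standard_normal((4, 3))
        np.testing.assert_allclose(
            admm_B_update(V, H, eta=2.0, rho=0.0), V / 2.0, atol=1e-12
        )

    def test_linear_equation_residual(self):
        rng = np.random.default_rng(2)
        H = fusion_matrix(4)
        V = rng.standard_normal((5, 4))
        eta, rho = 1.7, 0.9
        B = admm_B_update(V, H, eta, rho)
        lhs = B @ (rho * H @ H.T + (eta + rho) * np.eye(4))
        np.testing.assert_allclose(lhs, V, atol=1e-10)


def _inner_setup(data, config):
    G = data.n_groups
    H = fusion_matrix(G)
    eta = lipschitz_constant(data)
    Q = config.rho * (H @ H.T) + (eta + config.rho) * np.eye(G)
    return H, eta, np.linalg.inv(Q)


class TestAdmmInnerSolve:
    def test_zero_penalty_returns_gradient_step(self, toy_null):
        config = SolverConfig(inner_iters=400)
        H, eta, Qinv = _inner_setup(toy_null, config)
        rng = np.random.default_rng(3)
        B_t = rng.standard_normal((toy_null.n_features, toy_null.n_groups)) * 0.3
        grad = grad_neg_loglik(toy_null, B_t)
        pen = PenaltySpec.unit(0.0, 0.0, toy_null.n_features, toy_null.n_groups)
        A = admm_inner_solve(B_t, grad, eta, H, Qinv, pen, config)
        np.testing.assert_allclose(A, B_t - grad / eta, atol=1e-6)

    def test_huge_penalty_annihilates(self, toy_null):
        config = SolverConfig()
        H, eta, Qinv = _inner_setup(toy_null, config)
        B_t = np.full((toy_null.n_features, toy_null.n_groups), 0.2)
        grad = grad_neg_loglik(toy_null, B_t)
        pen = PenaltySpec.unit(1e3, 0.0, toy_null.n_features, toy_null.n_groups)
        A = admm_inner_solve(B_t, grad, eta, H, Qinv, pen, config)
        np.testing.assert_array_equal(A, 0.0)

    def test_subproblem_objective_matches_smooth_oracle(self):
        """ADMM output minimizes the linearized-plus-penalty subproblem."""
        from scipy.optimize import minimize

        data, _, _ = make_grouped(4, group_sizes=(30, 30, 30), p=5)
        config = SolverConfig(inner_iters=2000)
        H, eta, Qinv = _inner_setup(data, config)
        rng = np.random.default_rng(5)
        B_t = rng.standard_normal((5, 3)) * 0.2
        grad = grad_neg_loglik(data, B_t)
        lam1, lam2 = 0.05, 0.02
        pen = PenaltySpec.unit(lam1, lam2, 5, 3)
        A = admm_inner_solve(B_t, grad, eta, H, Qinv, pen, config)

        def sub_obj(B):
            B = B.reshape(5, 3)
            val = float(np.sum(grad * (B - B_t))) + eta / 2 * np.sum((B - B_t) ** 2)
            val += lam1 * np.linalg.norm(B, axis=1).sum()
            val += lam2 * np.abs(B @ H).sum()
            return val

        eps = 1e-8

        def sub_obj_smooth(x):
            B = x.reshape(5, 3)
            val = float(np.sum(grad * (B - B_t))) + eta / 2 * np.sum((B - B_t) ** 2)
            val += lam1 * np.sqrt((B * B).sum(axis=1) + eps**2).sum()
            d = B @ H
            val += lam2 * np.sqrt(d * d + eps**2).sum()
            return val

        res = minimize(sub_obj_smooth, A.ravel(), method="L-BFGS-B",
                       options={"maxiter": 20000, "ftol": 1e-16})
        assert sub_obj(A.ravel()) <= sub_obj(res.x) + 1e-4


class TestFitFGL:
    def test_requires_standardized_data(self, toy_null):
        toy_null.standardized = False
        pen = PenaltySpec.unit(0.1, 0.1, toy_null.n_features, toy_null.n_groups)
        with pytest.raises(ValueError, match="standardized"):
            fit_fgl(toy_null, pen)
        toy_null.standardized = True

    def test_single_group_zero_penalty_matches_mle(self):
        rng = np.random.default_rng(6)
        X = rng.standard_normal((200, 3))
        beta = np.array([0.8, -0.5, 0.0])
        y = (rng.random(200) < 1 / (1 + np.exp(-X @ beta))).astype(float)
        data, _ = standardize([X], [y])
        fit = fit_fgl(
            data,
            PenaltySpec.unit(0.0, 0.0, 3, 1),
            SolverConfig(outer_iters=2000, outer_tol=1e-10),
        )
        mle = sm.Logit(data.responses[0], data.designs[0]).fit(disp=0)
        np.testing.assert_allclose(fit.B_hat.values[:, 0], mle.params, atol=1e-3)

    def test_objective_dominated_by_zero_and_fixed_point(self):
        data, _, _ = make_grouped(7, group_sizes=(60, 60, 60), p=6)
        pen = PenaltySpec.unit(0.1, 0.05, 6, 3)
        config = SolverConfig(outer_iters=3000, outer_tol=1e-11)
        fit = fit_fgl(data, pen, config)
        obj0 = penalized_objective(data, np.zeros((6, 3)), pen)
        assert fit.objective_value <= obj0 + 1e-12
        # stationarity: one exact proximal step moves the iterate by < 1e-3
        H = fusion_matrix(3)
        eta = lipschitz_constant(data)
        Qinv = np.linalg.inv(config.rho * (H @ H.T) + (eta + config.rho) * np.eye(3))
        B = fit.B_hat.values
        step = admm_inner_solve(
            B, grad_neg_loglik(data, B), eta, H, Qinv, pen,
            SolverConfig(inner_iters=2000),
        )
        assert np.linalg.norm(step - B) <= 1e-3

    def test_objective_value_consistent_with_returned_B(self, toy_signal):
        pen = PenaltySpec.unit(0.05, 0.02, 6, 3)
        fit = fit_fgl(toy_signal, pen)
        assert fit.objective_value == pytest.approx(
            penalized_objective(toy_signal, fit.B_hat, pen), abs=1e-10
        )

    def test_zero_rows_outside_support(self, toy_signal):
        pen = PenaltySpec.unit(0.08, 0.03, 6, 3)
        fit = fit_fgl(toy_signal, pen)
        for j in range(6):
            if j not in fit.S_hat:
                np.testing.assert_array_equal(fit.B_hat.values[j], 0.0)

    def test_shrinkage_monotone_along_path(self):
        data, _, _ = make_grouped(8, group_sizes=(50, 50), p=4)
        norms = []
        init = None
        for lam1 in [0.3, 0.2, 0.12, 0.07, 0.03, 0.01]:
            fit = fit_fgl(
                data,
                PenaltySpec.unit(lam1, lam1 / 2**1.5, 4, 2),
                SolverConfig(outer_iters=1000, outer_tol=1e-9),
                init=init,
            )
            init = fit.B_hat.values
            norms.append(np.linalg.norm(fit.B_hat.values))
        # lam1 decreasing -> fitted norm non-decreasing
        assert all(b >= a - 1e-6 for a, b in zip(norms, norms[1:]))

    def test_total_fusion_limit_matches_pooled_mle(self):
        beta = np.array([[0.9, 0.9], [-0.6, -0.6], [0.0, 0.0]])
        data, _, _ = make_grouped(9, group_sizes=(120, 120), p=3, beta=beta)
        fit = fit_fgl(
            data,
            PenaltySpec.unit(0.0, 50.0, 3, 2),
            SolverConfig(outer_iters=3000, outer_tol=1e-11),
        )
        B = fit.B_hat.values
        np.testing.assert_allclose(B[:, 0], B[:, 1], atol=1e-8)
        stacked = np.vstack(data.designs)
        yy = np.concatenate(data.responses)
        mle = sm.Logit(yy, stacked).fit(disp=0)
        np.testing.assert_allclose(B[:, 0], mle.params, atol=1e-3)

    def test_oracle_equivalence_small_instances(self):
        """Penalized objective within 1e-4 relative of the smoothed oracle."""
        for seed in range(3):
            rng = np.random.default_rng(seed)
            G = int(rng.integers(2, 4))
            p = int(rng.integers(3, 7))
            sizes = tuple(int(rng.integers(30, 67)) for _ in range(G))
            beta = rng.standard_normal((p, G)) * 0.5
            data, _, _ = make_grouped(100 + seed, group_sizes=sizes, p=p, beta=beta)
            pen = PenaltySpec.unit(0.08, 0.03, p, G)
            fit = fit_fgl(data, pen, SolverConfig(outer_iters=4000, outer_tol=1e-11))
            obj_oracle, _ = smoothed_fgl_objective_min(data, pen, x0=fit.B_hat.values)
            assert fit.objective_value <= obj_oracle + 1e-4 * abs(obj_oracle)
            assert fit.objective_value >= obj_oracle - 1e-4 * abs(obj_oracle)


class TestAdaptiveWeights:
    def test_inverse_norm_and_caps(self):
        B = np.array([[2.0, 0.0, 0.0], [0.0, 0.0, 0.0], [1.0, 1.0, 2.0]])
        pen = PenaltySpec.unit(0.1, 0.1, 3, 3)
        fit_like = type("F", (), {"B_hat": CoefficientMatrix(B)})
        w, v = adaptive_weights(fit_like, cap=1e8)
        assert w[0] == pytest.approx(0.5)
        assert w[1] == 1e8  # zero row -> cap
        # row 2 pair (g1,g2) equal -> cap; pair (g1,g3) diff 1 -> weight 1
        assert v[2, 0] == 1e8
        assert v[2, 1] == pytest.approx(1.0)


class TestLambdaGrid:
    def test_anchor_arithmetic(self):
        grid = default_lambda_grid(1400, 80, 7, n_points=3, span=(1.0, 1.0),
                                   mode="paired")
        lam_star = np.sqrt(16 * 7 * (np.log(80) + np.log(7)) / 1400)
        assert grid[0][0] == pytest.approx(lam_star, rel=1e-12)
        assert grid[0][1] == pytest.approx(7 ** (-1.5) * lam_star, rel=1e-12)

    def test_single_group_no_fusion(self):
        grid = default_lambda_grid(100, 10, 1, n_points=4)
        assert all(l2 == 0.0 for _, l2 in grid)

    def test_grid_sizes(self):
        assert len(default_lambda_grid(100, 10, 3, n_points=5, mode="paired")) == 5
        assert len(default_lambda_grid(100, 10, 3, n_points=5, mode="product")) == 25

    def test_warm_start_ordering(self):
        grid = default_lambda_grid(100, 10, 3, n_points=5, mode="paired")
        lam1s = [l1 for l1, _ in grid]
        assert lam1s == sorted(lam1s, reverse=True)


class TestCrossValidate:
    def test_single_point_grid_is_chosen(self, toy_signal):
        res = cross_validate(toy_signal, [(0.05, 0.01)], folds=3, seed=0)
        assert res.chosen == (0.05, 0.01)

    def test_huge_penalty_gives_null_deviance(self, toy_null):
        res = cross_validate(toy_null, [(1e3, 1e3)], folds=3, seed=0)
        assert res.mean_loss[0] == pytest.approx(2 * np.log(2), rel=1e-6)

    def test_null_data_prefers_strong_penalty(self):
        """On pure-noise data CV should land in the upper half of the path."""
        upper = 0
        n_runs = 20
        # wide span so the low end of the path overfits grossly, not marginally
        grid = default_lambda_grid(
            700, 10, 7, n_points=6, span=(0.001, 1.0), mode="paired"
        )
        for seed in range(n_runs):
            data, _, _ = make_grouped(500 + seed, group_sizes=(100,) * 7, p=10)
            res = cross_validate(data, grid, folds=5, seed=seed)
            rank = [l1 for l1, _ in grid].index(res.chosen[0])
            upper += rank < 3  # grid sorted descending
        assert upper / n_runs >= 0.8


class TestTwoStage:
    def test_pure_noise_pilot_zero_forces_final_zero(self):
        data, _, _ = make_grouped(30, group_sizes=(40, 40, 40), p=6)
        res = fit_dfgl_two_stage(
            data,
            SolverConfig(),
            CVSpec(grid=[(5.0, 1.0)], folds=3),
        )
        pilot, final = res
        np.testing.assert_array_equal(pilot.B_hat.values, 0.0)
        np.testing.assert_array_equal(final.B_hat.values, 0.0)

    def test_support_and_fusion_recovery(self):
        """Constant-truth instance: S_hat = truth, Omega_hat empty, most runs.

        Tuned with the one-standard-error CV rule — the deviance
        minimizer sits in a flat overfitting region, so selection
        accuracy needs the sparser within-1-SE choice.
        """
        truth = np.zeros((20, 3))
        truth[[0, 1, 2]] = 1.5
        spec = ScenarioSpec(
            G=3, p=20, group_sizes=(150,) * 3, covariance_kind="ar1",
            true_B=CoefficientMatrix(truth), reps=1, base_seed=0,
        )
        cv = CVSpec(n_points=6, mode="paired", rule="1se")
        support_hits = fusion_hits = 0
        n_runs = 20
        for run in range(n_runs):
            spec.base_seed = 1000 + run
            data = simulate_dataset(spec, 0)
            _, final = fit_dfgl_two_stage(data, None, cv)
            support_hits += final.S_hat == {0, 1, 2}
            fusion_hits += len(final.Omega_hat) == 0
        assert support_hits / n_runs >= 0.8
        assert fusion_hits / n_runs >= 0.8
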