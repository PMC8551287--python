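import numpy as np
import pytest
from scipy.optimize import minimize

from ssikit.predictors import (
    blup_hat,
    cross_validate_lambda,
    default_lambda_grid,
    kkt_violation,
    predict,
    ssi_hat,
    ssi_objective,
    ssi_solve_path,
)

from conftest import random_psd_system


def qp_oracle(C, g, lam):
    """Independent solver: split b = b+ - b- and run a bound-constrained QP."""
    n = g.size

    def f(x):
        b = x[:n] - x[n:]
        return 0.5 * b @ C @ b - g @ b + lam * x.sum()

    def grad(x):
        b = x[:n] - x[n:]
        gb = C @ b - g
        return np.concatenate([gb + lam, -gb + lam])

    x0 = np.zeros(2 * n)
    res = minimize(f, x0, jac=grad, method="L-BFGS-B",
                   bounds=[(0, None)] * 2 * n,
                   options={"maxiter": 2000, "ftol": 1e-14, "gtol": 1e-10})
    return res.x[:n] - res.x[n:], res.fun


class TestBlupHat:
    def test_unrelated_prediction_set(self):
        hat = blup_hat(np.eye(4), np.zeros((2, 4)), 1.0)
        np.testing.assert_array_equal(hat.B, 0.0)
        np.testing.assert_array_equal(predict(hat, np.ones(4)).u_hat, 0.0)

    def test_duplicate_line_concentrates_weight(self):
        # training set: line j and its duplicate plus two unrelated lines
        K = np.eye(4)
        K[0, 1] = K[1, 0] = 1.0
        k_new = np.array([[1.0, 1.0, 0.0, 0.0]])  # identical to lines 0 and 1
        hat = blup_hat(K, k_new, 0.5)
        b = hat.B[0]
        assert b[0] == pytest.approx(b[1]) and b[0] > 0
        assert abs(b[2]) < 1e-12 and abs(b[3]) < 1e-12

    def test_direct_inverse_oracle(self, rng):
        C0, g, _ = random_psd_system(rng, 5, lambda0=0.0)
        K_ps_ts = rng.normal(size=(3, 5))
        lam0 = 0.5
        hat = blup_hat(C0, K_ps_ts, lam0)
        expected = K_ps_ts @ np.linalg.inv(C0 + lam0 * np.eye(5))
        assert np.abs(hat.B - expected).max() < 1e-10

    def test_singular_system_message(self):
        K = np.ones((3, 3))  # rank 1, singular at lambda0 = 0
        with pytest.raises(np.linalg.LinAlgError, match="lambda0"):
            blup_hat(K, np.ones((1, 3)), 0.0)


class TestSolvePath:
    def test_zero_at_lambda_max(self, rng):
        C, g, _ = random_psd_system(rng, 8)
        lam_max = np.abs(g).max()
        path = ssi_solve_path(g, C, np.array([lam_max]))
        np.testing.assert_array_equal(path.coefficients[0], 0.0)
        assert path.support[0] == 0

    def test_lambda_zero_equals_blup_row(self, rng):
        C, g, _ = random_psd_system(rng, 10)
        grid = default_lambda_grid(np.abs(g).max(), n_lambda=30)
        path = ssi_solve_path(g, C, grid, tol=1e-12)
        np.testing.assert_allclose(path.coefficients[-1], np.linalg.solve(C, g), atol=1e-8)

    def test_grid_validation(self, rng):
        C, g, _ = random_psd_system(rng, 5)
        with pytest.raises(ValueError, match="non-increasing"):
            ssi_solve_path(g, C, np.array([0.1, 0.2]))
        with pytest.raises(ValueError, match="lam_max"):
            ssi_solve_path(g, C, np.array([np.abs(g).max() / 2]))

    def test_objective_nonincreasing_along_sweeps(self, rng):
        # objective at each grid point must not exceed the warm-start value
        C, g, _ = random_psd_system(rng, 12)
        grid = default_lambda_grid(np.abs(g).max(), n_lambda=20)
        path = ssi_solve_path(g, C, grid, tol=1e-10)
        for k in range(len(grid) - 1):
            prev_at_next = ssi_objective(C, g, path.coefficients[k], grid[k + 1])
            assert path.objective[k + 1] <= prev_at_next + 1e-12

    def test_kkt_certificate(self, rng):
        for _ in range(10):
            C, g, _ = random_psd_system(rng, 15)
            lam = 0.3 * np.abs(g).max()
            grid = np.array([np.abs(g).max(), lam])
            path = ssi_solve_path(g, C, grid, tol=1e-10)
            assert kkt_violation(C, g, path.coefficients[-1], lam) < 1e-6

    def test_qp_oracle_on_toy(self, rng):
        C, g, _ = random_psd_system(rng, 6)
        lam = 0.3 * np.abs(g).max()
        path = ssi_solve_path(g, C, np.array([np.abs(g).max(), lam]), tol=1e-12)
        b_cd = path.coefficients[-1]
        b_qp, f_qp = qp_oracle(C, g, lam)
        assert abs(ssi_objective(C, g, b_cd, lam) - f_qp) < 1e-6
        assert np.abs(b_cd - b_qp).max() < 1e-5

    def test_support_shrinkage_at_ends(self, rng):
        C, g, _ = random_psd_system(rng, 10)
        grid = default_lambda_grid(np.abs(g).max(), n_lambda=25)
        path = ssi_solve_path(g, C, grid, tol=1e-10)
        assert path.support[0] == 0
        b_blup = np.linalg.solve(C, g)
        assert path.support[-1] == (np.abs(b_blup) > 1e-12).sum()


class TestSSIHat:
    def test_lambda_zero_matches_blup(self, rng):
        C, _, _ = random_psd_system(rng, 20, lambda0=0.0)
        K_ps_ts = rng.normal(size=(5, 20))
        lam0 = 0.8
        dense = blup_hat(C, K_ps_ts, lam0)
        sparse = ssi_hat(C, K_ps_ts, lam0, 0.0, tol=1e-12)
        assert np.abs(dense.B - sparse.B).max() < 1e-8

    def test_lambda_above_max_all_zero(self, rng):
        C, _, _ = random_psd_system(rng, 8)
        K_ps_ts = rng.normal(size=(3, 8))
        lam = np.abs(K_ps_ts).max() * 1.1
        hat = ssi_hat(C, K_ps_ts, 0.5, lam)
        np.testing.assert_array_equal(hat.B, 0.0)
        pred = predict(hat, rng.normal(size=8))
        np.testing.assert_array_equal(pred.u_hat, 0.0)
        assert pred.mean_n_sup == 0

    def test_order_invariance(self, rng):
        K_full, _, _ = random_psd_system(rng, 40, lambda0=0.0)
        K_ts = K_full[:20, :20]
        K_ps_ts = K_full[20:, :20]
        lam = 0.2 * np.abs(K_ps_ts).max()
        serial = ssi_hat(K_ts, K_ps_ts, 0.5, lam)
        chunks = [ssi_hat(K_ts, K_ps_ts[i: i + 5], 0.5, lam) for i in range(0, 20, 5)]
        stacked = np.vstack([c.B for c in chunks])
        np.testing.assert_array_equal(serial.B, stacked)


class TestCrossValidation:
    def test_determinism(self, small_grm, small_population):
        import pandas as pd

        y = pd.Series(small_population.phenotype, index=small_population.ids)
        ids = list(small_grm.ids[:80])
        K = small_grm.values[:80, :80]
        yts = y.loc[ids].to_numpy()
        a = cross_validate_lambda(yts, K, 1.0, n_folds=5, seed=3)
        b = cross_validate_lambda(yts, K, 1.0, n_folds=5, seed=3)
        assert a.selected_fraction == b.selected_fraction
        np.testing.assert_array_equal(a.fold_accuracy, b.fold_accuracy)
        for fa, fb in zip(a.folds, b.folds):
            np.testing.assert_array_equal(fa, fb)

    def test_pure_noise_returns_grid_member(self, rng):
        C, _, _ = random_psd_system(rng, 60, lambda0=0.0)
        y = rng.normal(size=60)
        cv = cross_validate_lambda(y, C, 1.0, n_folds=5, seed=4)
        assert cv.selected_fraction in cv.fractions

    def test_fold_sizes_balanced(self, rng):
        C, _, _ = random_psd_system(rng, 53, lambda0=0.0)
        y = rng.normal(size=53)
        cv = cross_validate_lambda(y, C, 1.0, n_folds=10, seed=5)
        sizes = [len(f) for f in cv.folds]
        assert max(sizes) - min(sizes) <= 1
        assert sum(sizes) == 53

    def test_small_folds_rejected(self, rng):
        C, _, _ = random_psd_system(rng, 20, lambda0=0.0)
        with pytest.raises(ValueError, match="fewer folds"):
            cross_validate_lambda(rng.normal(size=20), C, 1.0, n_folds=10)


class TestPredict:
    def test_hand_product(self):
        B = np.array([[1.0, 0.0, 2.0, 0.0], [0.0, 1.0, 0.0, 1.0], [0.0, 0.0, 0.0, 0.0]])
        hat = ssi_hat(np.eye(4), np.zeros((3, 4)), 1.0, 1.0)
        hat.B = B  # inject known coefficients
        y = np.array([1.0, 2.0, 3.0, 4.0])
        pred = predict(hat, y)
        np.testing.assert_allclose(pred.u_hat, [7.0, 6.0, 0.0])
        np.testing.assert_array_equal(pred.n_sup, [2, 2, 0])
        assert pred.pct_sparsity == pytest.approx(100 * (4 / 3) / 4)

    def test_blup_support_is_full_ts(self, rng):
        C, _, _ = random_psd_system(rng, 10, lambda0=0.0)
        K_ps_ts = rng.normal(size=(4, 10))
        pred = predict(blup_hat(C, K_ps_ts, 0.5), rng.normal(size=10))
        assert np.all(pred.n_sup == 10)
        assert pred.pct_sparsity == pytest.approx(100.0)

    def test_length_mismatch(self, rng):
        hat = blup_hat(np.eye(3), np.zeros((1, 3)), 1.0)
        with pytest.raises(ValueError, match="length"):
            predict(hat, np.zeros(4))
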