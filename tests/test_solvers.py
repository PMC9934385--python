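import numpy as np
import pytest

from lqsso import (InitialEstimates, fit_adaptive_lasso, fit_lqsso, kkt_check,
                   lasso_cd, ols_init, ridge_init, standardize,
                   weighted_lasso, weighted_lasso_path)
from conftest import random_instance
from solver_oracles import weighted_l1_qp


class TestStandardize:
    def test_three_point_column_closed_form(self):
        X = np.array([[1.0, 5.0], [2.0, 1.0], [3.0, -2.0]])
        y = np.array([1.0, 2.0, 3.0])
        data = standardize(X, y)
        a = np.sqrt(3.0 / 2.0)
        assert np.allclose(data.X[:, 0], [-a, 0.0, a])
        assert np.allclose(data.y, [-1.0, 0.0, 1.0])

    def test_moments_and_idempotence(self, rng):
        X = rng.standard_normal((20, 5)) * 3 + 1
        y = rng.standard_normal(20) + 2
        data = standardize(X, y)
        assert np.allclose(data.X.mean(axis=0), 0, atol=1e-12)
        assert np.allclose((data.X**2).sum(axis=0), data.n, atol=1e-10)
        assert abs(data.y.mean()) < 1e-12
        again = standardize(data.X, data.y)
        assert np.allclose(again.X, data.X, atol=1e-10)
        assert np.allclose(again.y, data.y, atol=1e-10)

    def test_constant_column_rejected_by_index(self, rng):
        X = rng.standard_normal((10, 3))
        X[:, 1] = 7.0
        with pytest.raises(ValueError, match=r"\[1\]"):
            standardize(X, rng.standard_normal(10))

    def test_roundtrip_via_scaling_info(self, rng):
        X = rng.standard_normal((15, 4)) * 2 + 5
        y = rng.standard_normal(15)
        data = standardize(X, y)
        sc = data.scaling
        assert np.allclose(data.X * sc.x_scale + sc.x_mean, X)


class TestLassoCD:
    def test_lambda_zero_recovers_ols(self, small_data):
        fit = lasso_cd(small_data, 0.0)
        ols = np.linalg.lstsq(small_data.X, small_data.y, rcond=None)[0]
        assert np.allclose(fit.beta, ols, atol=1e-7)

    def test_null_threshold_gives_zero(self, small_data):
        lam = 2.0 * np.max(np.abs(small_data.X.T @ small_data.y)) * 1.0001
        fit = lasso_cd(small_data, lam)
        assert np.all(fit.beta == 0.0)
        assert kkt_check(small_data, fit).passed

    def test_matches_convex_oracle(self, rng):
        data, _ = random_instance(rng, 10, 4)
        lam = 1.0
        fit = lasso_cd(data, lam, tol=1e-12)
        _, obj = weighted_l1_qp(data.X, data.y, lam)
        assert fit.objective == pytest.approx(obj, rel=1e-6)

    def test_objective_monotone_across_sweeps(self, rng):
        data, _ = random_instance(rng, 25, 8)
        fit = lasso_cd(data, 3.0, track_objective=True)
        trace = fit.objective_trace
        assert trace is not None and len(trace) >= 2
        assert np.all(np.diff(trace) <= 1e-10)

    def test_nonconvergence_flagged(self, rng):
        data, _ = random_instance(rng, 20, 6)
        fit = lasso_cd(data, 0.5, tol=1e-15, max_iter=2)
        assert not fit.converged

    def test_objective_matches_recomputation(self, small_data):
        fit = lasso_cd(small_data, 2.0)
        r = small_data.y - small_data.X @ fit.beta
        expected = r @ r + 2.0 * np.abs(fit.beta).sum()
        assert fit.objective == pytest.approx(expected, rel=1e-8)

    def test_negative_lambda_rejected(self, small_data):
        with pytest.raises(ValueError):
            lasso_cd(small_data, -1.0)


class TestWeightedLasso:
    def test_unit_weights_equal_lasso(self, small_data):
        lam = 1.5
        a = weighted_lasso(small_data, lam, np.ones(small_data.p))
        b = lasso_cd(small_data, lam)
        assert np.allclose(a.beta, b.beta, atol=1e-10)

    def test_constant_weight_factors_out(self, small_data):
        a = weighted_lasso(small_data, 2.0, np.full(small_data.p, 0.5))
        b = lasso_cd(small_data, 1.0)
        assert np.allclose(a.beta, b.beta, atol=1e-8)

    def test_matches_convex_oracle(self, rng):
        data, _ = random_instance(rng, 12, 6)
        w = np.array([0.8, 0.2, 0.8, 0.2, 0.5, 0.9])
        lam = 2.0
        fit = weighted_lasso(data, lam, w, tol=1e-12)
        _, obj = weighted_l1_qp(data.X, data.y, lam, w)
        assert fit.objective == pytest.approx(obj, rel=1e-6)

    def test_nonpositive_weights_rejected(self, small_data):
        with pytest.raises(ValueError):
            weighted_lasso(small_data, 1.0, np.zeros(small_data.p))

    def test_normalization_scales_to_mean_one(self, small_data):
        w = np.full(small_data.p, 0.25)
        a = weighted_lasso(small_data, 1.0, w, normalize=True)
        b = lasso_cd(small_data, 1.0)
        assert np.allclose(a.beta, b.beta, atol=1e-10)

    def test_path_matches_single_fits(self, rng):
        data, _ = random_instance(rng, 20, 5)
        lams = np.array([0.5, 2.0, 8.0])
        betas, conv = weighted_lasso_path(data, lams, tol=1e-10)
        assert conv.all()
        for lam, beta in zip(lams, betas):
            single = lasso_cd(data, lam, tol=1e-10)
            assert np.allclose(beta, single.beta, atol=1e-7)


class TestLqsso:
    def test_tau_half_is_lasso_at_half_lambda(self, small_data):
        fit = fit_lqsso(small_data, 3.0, tau=0.5)
        ref = lasso_cd(small_data, 1.5)
        assert np.allclose(fit.beta, ref.beta, atol=1e-8)

    def test_lambda_zero_is_ols(self, small_data):
        fit = fit_lqsso(small_data, 0.0, tau=0.8)
        ols = np.linalg.lstsq(small_data.X, small_data.y, rcond=None)[0]
        assert np.allclose(fit.beta, ols, atol=1e-7)

    def test_sign_flip_symmetry(self, rng):
        data, _ = random_instance(rng, 25, 5)
        init = ols_init(data)
        fit = fit_lqsso(data, 4.0, tau=0.7, init=init, tol=1e-12)
        X2 = data.X.copy()
        X2[:, 2] *= -1.0
        data2 = standardize(X2, data.y)
        init2 = InitialEstimates(beta=init.beta * np.where(
            np.arange(5) == 2, -1.0, 1.0), source="user")
        fit2 = fit_lqsso(data2, 4.0, tau=0.7, init=init2, tol=1e-12)
        expected = fit.beta * np.where(np.arange(5) == 2, -1.0, 1.0)
        assert np.allclose(fit2.beta, expected, atol=1e-7)

    def test_matches_convex_oracle(self, rng):
        data, _ = random_instance(rng, 15, 6)
        init = ols_init(data)
        tau, lam = 0.8, 2.5
        fit = fit_lqsso(data, lam, tau, init=init, tol=1e-12)
        w = np.where(init.beta > 0, tau, 1 - tau)
        _, obj = weighted_l1_qp(data.X, data.y, lam, w)
        assert fit.objective == pytest.approx(obj, rel=1e-6)

    def test_records_metadata(self, small_data):
        fit = fit_lqsso(small_data, 1.0, tau=0.3)
        assert fit.tau == 0.3 and fit.init_source == "ols"
        assert fit.method == "lqsso"


class TestAdaptiveLasso:
    def test_unit_inits_reduce_to_lasso(self, small_data):
        init = InitialEstimates(beta=np.ones(small_data.p), source="user")
        fit = fit_adaptive_lasso(small_data, 2.0, gamma=1.3, init=init)
        ref = lasso_cd(small_data, 2.0)
        assert np.allclose(fit.beta, ref.beta, atol=1e-8)

    def test_gamma_to_zero_approaches_lasso(self, small_data):
        init = ols_init(small_data)
        fit = fit_adaptive_lasso(small_data, 2.0, gamma=1e-8, init=init)
        ref = lasso_cd(small_data, 2.0)
        assert np.allclose(fit.beta, ref.beta, atol=1e-5)

    def test_matches_convex_oracle(self, rng):
        data, _ = random_instance(rng, 10, 4)
        init = ols_init(data)
        fit = fit_adaptive_lasso(data, 1.0, gamma=1.0, init=init, tol=1e-12)
        w = 1.0 / np.abs(init.beta)
        _, obj = weighted_l1_qp(data.X, data.y, 1.0, w)
        assert fit.objective == pytest.approx(obj, rel=1e-6)

    def test_all_zero_init_rejected(self, small_data):
        init = InitialEstimates(beta=np.zeros(small_data.p), source="user")
        with pytest.raises(ValueError):
            fit_adaptive_lasso(small_data, 1.0, gamma=1.0, init=init)


class TestInitializers:
    def test_ols_closed_form_orthonormal(self, rng):
        # build a design whose columns are exactly orthogonal with sum x^2 = n
        n = 32
        from scipy.linalg import qr
        Q, _ = qr(rng.standard_normal((n, 4)), mode="economic")
        X = Q * np.sqrt(n)
        y = rng.standard_normal(n)
        y -= y.mean()
        X -= X.mean(axis=0)  # re-center; columns stay near-orthogonal
        data = standardize(X, y)
        init = ols_init(data)
        direct = np.linalg.lstsq(data.X, data.y, rcond=None)[0]
        assert np.allclose(init.beta, direct, atol=1e-8)

    def test_ols_requires_low_dimension(self, rng):
        X = rng.standard_normal((10, 15))
        data = standardize(X, rng.standard_normal(10))
        with pytest.raises(ValueError, match="ridge"):
            ols_init(data)

    def test_ridge_matches_direct_solve(self, rng):
        X = rng.standard_normal((15, 30))
        data = standardize(X, rng.standard_normal(15))
        lam = 3.7
        init = ridge_init(data, ridge_lambda=lam)
        direct = np.linalg.solve(data.X.T @ data.X + lam * np.eye(30),
                                 data.X.T @ data.y)
        assert np.allclose(init.beta, direct, atol=1e-10)
        assert init.source == "ridge"

    def test_ridge_shrinks_monotonically(self, rng):
        X = rng.standard_normal((20, 10))
        data = standardize(X, rng.standard_normal(20))
        norms = [np.linalg.norm(ridge_init(data, ridge_lambda=lam).beta)
                 for lam in [0.1, 1.0, 10.0, 100.0, 1000.0]]
        assert all(a > b for a, b in zip(norms, norms[1:]))

    def test_ridge_auto_lambda(self, rng):
        X = rng.standard_normal((15, 30))
        data = standardize(X, rng.standard_normal(15))
        init = ridge_init(data)
        assert np.all(np.isfinite(init.beta)) and init.beta.size == 30


class TestKKT:
    def test_converged_fit_passes(self, rng):
        data, _ = random_instance(rng, 20, 8)
        fit = lasso_cd(data, 2.0, tol=1e-12)
        report = kkt_check(data, fit, tol=1e-6)
        assert report.passed

    def test_perturbation_fails_locally(self, rng):
        data, _ = random_instance(rng, 20, 8)
        fit = lasso_cd(data, 2.0, tol=1e-12)
        j = fit.active_set[0]
        beta_bad = fit.beta.copy()
        beta_bad[j] += 0.1
        from dataclasses import replace
        bad = replace(fit, beta=beta_bad)
        report = kkt_check(data, bad, tol=1e-6)
        assert not report.passed
        assert j in report.active_violations

    def test_shrinks_to_zero_large_lambda(self, small_data):
        fit = lasso_cd(small_data, 1e6)
        assert np.all(fit.beta == 0.0)
        assert kkt_check(small_data, fit).passed
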