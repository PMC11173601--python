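"""ZIGP regression: likelihood, EM fits, stacked fits with shared (tau, alpha)."""

import numpy as np
import pytest

from gzigpfa import (
    ZigpParams,
    ZigpRegressionProblem,
    em_fit,
    posterior_zero_weights,
    stacked_fit,
    zigp_logpmf,
    zigp_loglik,
)
from gzigpfa.glm import _pointwise_loglik

from conftest import make_regression, make_stacked


def _brute_force_loglik(problem, beta, params):
    """Naive per-row sum of the ZIGP log-pmf (the oracle)."""
    eta = problem.X @ beta
    lam = np.exp(eta)
    mu = lam * np.exp(problem.offset_log)
    phi = 1.0 / (1.0 + lam**params.tau)
    total = 0.0
    for i in range(len(problem.y)):
        if problem.mask is not None and not problem.mask[i]:
            continue
        total += zigp_logpmf(problem.y[i], phi[i], mu[i], params.alpha)
    return total


def test_loglik_matches_brute_force_sum():
    problem, beta, tau, alpha = make_regression(n=20, K=2, seed=5)
    params = ZigpParams(tau, alpha)
    assert zigp_loglik(problem, beta, params) == pytest.approx(
        _brute_force_loglik(problem, beta, params), rel=1e-10
    )


def test_loglik_respects_mask():
    problem, beta, tau, alpha = make_regression(n=30, K=2, seed=6)
    mask = np.zeros(30, dtype=bool)
    mask[:17] = True
    masked = ZigpRegressionProblem(
        y=problem.y, X=problem.X, offset_log=problem.offset_log, mask=mask
    )
    params = ZigpParams(tau, alpha)
    assert zigp_loglik(masked, beta, params) == pytest.approx(
        _brute_force_loglik(masked, beta, params), rel=1e-10
    )


def test_homogeneous_all_zero_closed_form():
    # all y = 0 and lam = 1 (beta = 0): phi = 0.5 for any tau; with scalar T
    # the log-likelihood is n*log(0.5 + 0.5*exp(-T/(1+alpha*T)))
    n, T, alpha = 25, 2.0, 0.3
    problem = ZigpRegressionProblem(
        y=np.zeros(n, dtype=int), X=np.ones((n, 1)), offset_log=np.log(T) * np.ones(n)
    )
    got = zigp_loglik(problem, np.zeros(1), ZigpParams(0.0, alpha))
    want = n * np.log(0.5 + 0.5 * np.exp(-T / (1 + alpha * T)))
    assert got == pytest.approx(want, rel=1e-12)


def test_single_observation_closed_form():
    problem = ZigpRegressionProblem(y=np.array([2]), X=np.ones((1, 1)))
    got = zigp_loglik(problem, np.zeros(1), ZigpParams(0.0, 0.0))
    assert got == pytest.approx(np.log(0.5 * np.exp(-1) / 2), rel=1e-12)


def test_posterior_weights_vanish_on_positive_counts():
    problem, beta, tau, alpha = make_regression(n=200, seed=7)
    z = posterior_zero_weights(problem, beta, ZigpParams(tau, alpha))
    assert np.all(z[problem.y > 0] == 0)
    assert np.all((z >= 0) & (z <= 1))
    assert np.any(z[problem.y == 0] > 0.1)


class TestEmFit:
    def test_loglik_trace_is_monotone(self):
        problem, *_ = make_regression(n=300, seed=8)
        fit = em_fit(problem)
        tr = np.asarray(fit.loglik_trace)
        assert np.all(np.diff(tr) >= -1e-8 * np.maximum(1.0, np.abs(tr[:-1])))
        assert fit.converged

    def test_parameter_recovery_within_three_standard_errors(self):
        problem, beta, tau, alpha = make_regression(
            n=2000, K=2, beta=(0.9, 0.7), tau=1.0, alpha=0.2, seed=9
        )
        fit = em_fit(problem, init_params=ZigpParams(1.0, 0.05))
        theta_hat = np.concatenate([fit.beta, [fit.params.tau, fit.params.alpha]])
        theta_true = np.concatenate([beta, [tau, alpha]])
        se = _asymptotic_se(problem, theta_hat)
        assert np.all(np.abs(theta_hat - theta_true) < 3 * se), (theta_hat, theta_true, se)

    def test_matches_poisson_glm_without_zero_inflation(self):
        # all-positive counts, alpha fixed at 0, tau fixed large: the EM
        # reduces to a plain Poisson log-linear regression
        statsmodels = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(10)
        n = 500
        X = np.column_stack([np.ones(n), rng.normal(0, 0.3, n)])
        offset = rng.uniform(-0.2, 0.2, n)
        beta_true = np.array([2.5, 0.5])
        y = rng.poisson(np.exp(X @ beta_true + offset))
        assert np.all(y > 0)
        problem = ZigpRegressionProblem(y=y, X=X, offset_log=offset)
        fit = em_fit(problem, init_params=ZigpParams(30.0, 0.0), fix_params=True)
        glm = statsmodels.GLM(
            y, X, family=statsmodels.families.Poisson(), offset=offset
        ).fit()
        np.testing.assert_allclose(fit.beta, glm.params, atol=1e-4)

    def test_all_zero_response_stays_finite(self):
        problem = ZigpRegressionProblem(y=np.zeros(40, dtype=int), X=np.ones((40, 1)))
        fit = em_fit(problem, max_iter=50)
        assert np.isfinite(fit.loglik)

    def test_rank_deficient_design_rejected(self):
        X = np.ones((10, 2))  # duplicated column
        with pytest.raises(ValueError):
            ZigpRegressionProblem(y=np.ones(10, dtype=int), X=X)


def _asymptotic_se(problem, theta_hat):
    """Standard errors from a finite-difference Hessian of the observed
    log-likelihood in (beta, tau, alpha)."""
    K = problem.X.shape[1]

    def ll(theta):
        return zigp_loglik(problem, theta[:K], ZigpParams(theta[K], max(theta[K + 1], 1e-9)))

    p = len(theta_hat)
    H = np.zeros((p, p))
    h = 1e-4
    for i in range(p):
        for j in range(i, p):
            ei = np.eye(p)[i] * h
            ej = np.eye(p)[j] * h
            H[i, j] = H[j, i] = (
                ll(theta_hat + ei + ej) - ll(theta_hat + ei - ej)
                - ll(theta_hat - ei + ej) + ll(theta_hat - ei - ej)
            ) / (4 * h * h)
    cov = np.linalg.inv(-H)
    return np.sqrt(np.diag(cov))


class TestStackedFit:
    def test_single_block_agrees_with_em_fit(self):
        problem, *_ = make_regression(n=250, seed=11)
        single = em_fit(problem, tol=1e-8)
        stacked = stacked_fit([problem], tol=1e-8, inner_iters=5)
        assert stacked.loglik == pytest.approx(single.loglik, abs=0.2)
        np.testing.assert_allclose(stacked.betas[0], single.beta, atol=0.05)

    def test_identical_blocks_get_identical_coefficients(self):
        problem, *_ = make_regression(n=150, seed=12)
        res = stacked_fit([problem, problem])
        np.testing.assert_allclose(res.betas[0], res.betas[1], atol=1e-9)
        single = em_fit(problem, tol=1e-8)
        assert res.params.tau == pytest.approx(single.params.tau, abs=0.05)
        assert res.params.alpha == pytest.approx(single.params.alpha, abs=0.02)

    def test_shared_params_beat_free_fits_with_averaged_params(self):
        problems = make_stacked(n=50, n_blocks=5, seed=20)
        res = stacked_fit(problems, tol=1e-7)
        free = [em_fit(p) for p in problems]
        avg = ZigpParams(
            float(np.mean([f.params.tau for f in free])),
            float(np.mean([f.params.alpha for f in free])),
        )
        naive = sum(zigp_loglik(p, f.beta, avg) for p, f in zip(problems, free))
        assert res.loglik >= naive - 1e-6

    def test_total_loglik_trace_is_monotone(self):
        problems = make_stacked(n=80, n_blocks=4, seed=30)
        res = stacked_fit(problems)
        tr = np.asarray(res.loglik_trace)
        assert np.all(np.diff(tr) >= -1e-8 * np.maximum(1.0, np.abs(tr[:-1])))

    def test_profile_gradient_vanishes_at_convergence(self):
        problems = make_stacked(n=120, n_blocks=3, seed=40)
        res = stacked_fit(problems, tol=1e-9, max_outer=60, inner_iters=6)
        tau, alpha = res.params.tau, res.params.alpha

        def total(t, a):
            return sum(zigp_loglik(p, b, ZigpParams(t, a)) for p, b in zip(problems, res.betas))

        h = 1e-5
        g_tau = (total(tau + h, alpha) - total(tau - h, alpha)) / (2 * h)
        g_alpha = (total(tau, alpha + h) - total(tau, alpha - h)) / (2 * h)
        assert abs(g_tau) < 1e-3
        # alpha can sit on the boundary of [0, ALPHA_MAX]; only an interior
        # optimum must be stationary
        if 1e-6 < alpha < 4.999:
            assert abs(g_alpha) < 1e-3

    def test_requires_shared_design(self):
        p1, *_ = make_regression(n=50, seed=50)
        p2, *_ = make_regression(n=60, seed=51)
        with pytest.raises(ValueError):
            stacked_fit([p1, p2])


def test_pointwise_loglik_clamps_extreme_linear_predictors():
    y = np.array([0.0, 3.0])
    out = _pointwise_loglik(y, np.array([-500.0, 500.0]), 0.0, 1.0, 0.2)
    assert np.all(np.isfinite(out))
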