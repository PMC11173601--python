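"""ZIGP regression by EM: GP mean with log link and offset, zero probability
tied to the rate through ``logit(phi) = -tau*log(lam)``.

A single regression problem has responses ``y`` (length n), a design matrix
``X`` (n x K), an optional log-offset (the log relative library size) and an
optional inclusion mask.  The latent rate is ``lam = exp(X beta)``; the GP
mean is ``T * lam``; the structural-zero probability is
``phi = sigmoid(-tau * X beta)``.

The EM algorithm treats the indicator "this zero is structural" as the
latent variable.  Because ``phi`` depends on ``beta`` and ``tau`` through the
rate, the M-step does not separate into a logistic part and a GP part; the
expected complete-data log-likelihood is maximized jointly by quasi-Newton
ascent with analytic gradients (``alpha`` box-constrained to
``[0, ALPHA_MAX]``).

``stacked_fit`` solves many regressions that share the same design matrix
and a single global ``(tau, alpha)``: a block-coordinate scheme alternates
(a) EM updates of all coefficient blocks at fixed ``(tau, alpha)`` — the
blocks separate, so they are updated in one joint quasi-Newton call — with
(b) a bounded 2-D maximization of the total observed-data log-likelihood
over ``(tau, alpha)``.  This is the workhorse of the alternating factor
algorithm, where step 1 stacks the columns and step 2 stacks the rows of
the count matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit, gammaln, log_expit

from .distributions import ALPHA_MAX, ZigpParams

__all__ = [
    "ZigpRegressionProblem",
    "ZigpRegressionFit",
    "StackedFit",
    "zigp_loglik",
    "posterior_zero_weights",
    "em_fit",
    "stacked_fit",
]

#: Linear predictors are clamped to +-ETA_CLIP before exponentiation.  The
#: lower clamp keeps all-zero response blocks (whose rate is unidentifiable
#: downward) finite; the upper clamp is an overflow guard.
ETA_CLIP = 30.0

_TAU_BOUNDS = (-50.0, 50.0)


# ---------------------------------------------------------------------------
# problem containers
# ---------------------------------------------------------------------------


@dataclass
class ZigpRegressionProblem:
    """One ZIGP regression: responses, design, log-offset, inclusion mask."""

    y: np.ndarray
    X: np.ndarray
    offset_log: np.ndarray | None = None
    mask: np.ndarray | None = None

    def __post_init__(self):
        self.y = np.asarray(self.y, dtype=float)
        self.X = np.asarray(self.X, dtype=float)
        if self.y.ndim != 1 or self.X.ndim != 2 or self.X.shape[0] != self.y.size:
            raise ValueError("y must be 1-D and X must be (len(y), K)")
        if np.any(self.y < 0) or np.any(self.y != np.floor(self.y)):
            raise ValueError("responses must be non-negative integers")
        if self.offset_log is None:
            self.offset_log = np.zeros_like(self.y)
        else:
            self.offset_log = np.broadcast_to(
                np.asarray(self.offset_log, dtype=float), self.y.shape
            ).copy()
        if self.mask is not None:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.y.shape:
                raise ValueError("mask must match y")
        rows = self.X if self.mask is None else self.X[self.mask]
        if np.linalg.matrix_rank(rows) < self.X.shape[1]:
            raise ValueError("design matrix is rank deficient on included rows")

    @property
    def n_included(self) -> int:
        return int(self.y.size if self.mask is None else self.mask.sum())


@dataclass
class ZigpRegressionFit:
    """Result of an EM fit of one ZIGP regression."""

    beta: np.ndarray
    params: ZigpParams
    loglik: float
    n_em_iters: int
    converged: bool
    loglik_trace: list = field(default_factory=list)


@dataclass
class StackedFit:
    """Result of fitting many ZIGP regressions with shared (tau, alpha)."""

    betas: list
    params: ZigpParams
    loglik: float
    loglik_trace: list
    converged: bool


# ---------------------------------------------------------------------------
# pointwise kernels (shared with the factor module)
# ---------------------------------------------------------------------------


def _pointwise_loglik(y, eta, log_t, tau, alpha):
    """Observed-data ZIGP log-likelihood per entry; eta is clamped."""
    eta = np.clip(eta, -ETA_CLIP, ETA_CLIP)
    mu = np.exp(eta + log_t)
    c = 1.0 + alpha * mu
    r = mu / c
    gp = (
        y * np.log(r)
        + (y - 1.0) * np.log1p(alpha * y)
        - r * (1.0 + alpha * y)
        - gammaln(y + 1.0)
    )
    log_phi = log_expit(-tau * eta)
    log_1mphi = log_expit(tau * eta)
    return np.where(y > 0, log_1mphi + gp, np.logaddexp(log_phi, log_1mphi - r))


def _posterior_z(y, eta, log_t, tau, alpha):
    """P(zero is structural | data); exactly 0 wherever y > 0."""
    eta = np.clip(eta, -ETA_CLIP, ETA_CLIP)
    mu = np.exp(eta + log_t)
    r = mu / (1.0 + alpha * mu)
    # logit(z) = logit(phi) - log p0 = -tau*eta + r
    z = expit(-tau * eta + r)
    return np.where(y > 0, 0.0, z)


def _q_eta(y, z, eta_raw, log_t, tau, alpha, gam, mask=None):
    """Expected complete-data log-likelihood and its gradient w.r.t. eta.

    ``gam`` carries ``gammaln(y+1)`` (precomputed; y never changes inside an
    M-step).  Entries where eta is clamped get zero gradient.
    """
    clipped = np.abs(eta_raw) >= ETA_CLIP
    eta = np.clip(eta_raw, -ETA_CLIP, ETA_CLIP)
    mu = np.exp(eta + log_t)
    c = 1.0 + alpha * mu
    r = mu / c
    ay = alpha * y
    gp = y * np.log(r) + (y - 1.0) * np.log1p(ay) - r * (1.0 + ay) - gam
    log_phi = log_expit(-tau * eta)
    log_1mphi = log_expit(tau * eta)
    w = 1.0 - z
    q = z * log_phi + w * (log_1mphi + gp)
    phi = expit(-tau * eta)
    d_eta = tau * (w * phi - z * (1.0 - phi)) + w * (y - ay * r - (1.0 + ay) * r / c)
    d_eta = np.where(clipped, 0.0, d_eta)
    if mask is not None:
        q = q * mask
        d_eta = d_eta * mask
    return q.sum(), d_eta


def _q_tau_alpha_grad(y, z, eta, log_t, tau, alpha, mask=None):
    """Gradient of the expected complete-data log-likelihood in (tau, alpha)."""
    eta = np.clip(eta, -ETA_CLIP, ETA_CLIP)
    mu = np.exp(eta + log_t)
    c = 1.0 + alpha * mu
    r = mu / c
    phi = expit(-tau * eta)
    w = 1.0 - z
    d_tau = eta * (w * phi - z * (1.0 - phi))
    d_alpha = w * (y * (y - 1.0) / (1.0 + alpha * y) - y * r - r * (y - mu) / c)
    if mask is not None:
        d_tau = d_tau * mask
        d_alpha = d_alpha * mask
    return d_tau.sum(), d_alpha.sum()


# ---------------------------------------------------------------------------
# M-steps
# ---------------------------------------------------------------------------


def _mstep_betas(Y, X, Beta0, log_t, z, tau, alpha, mask=None, maxiter=40):
    """Maximize Q over all coefficient blocks jointly.

    ``Y`` is (n, B) with one response vector per column; every block shares
    the design ``X`` (n, K) so ``eta = X @ Beta``.  The objective separates
    over blocks; a single L-BFGS call updates them all.
    """
    K, B = Beta0.shape
    gam = gammaln(Y + 1.0)

    def negq(vec):
        Beta = vec.reshape(K, B)
        eta = X @ Beta
        q, d_eta = _q_eta(Y, z, eta, log_t, tau, alpha, gam, mask)
        return -q, -(X.T @ d_eta).ravel()

    f0, _ = negq(Beta0.ravel())
    res = minimize(
        negq, Beta0.ravel(), jac=True, method="L-BFGS-B", options={"maxiter": maxiter}
    )
    if res.fun <= f0:
        return res.x.reshape(K, B)
    return Beta0  # line-search failure: keep the monotone guarantee


def _optimize_params(Y, eta, log_t, tau0, alpha0, mask=None, maxiter=100):
    """Maximize the observed-data log-likelihood over (tau, alpha).

    The gradient uses Fisher's identity: the observed-data score equals the
    posterior-weighted complete-data score, with the structural-zero
    posterior evaluated at the same (tau, alpha).
    """

    def nll(p):
        tau, alpha = p
        ll = _pointwise_loglik(Y, eta, log_t, tau, alpha)
        if mask is not None:
            ll = ll * mask
        z = _posterior_z(Y, eta, log_t, tau, alpha)
        d_tau, d_alpha = _q_tau_alpha_grad(Y, z, eta, log_t, tau, alpha, mask)
        return -ll.sum(), -np.array([d_tau, d_alpha])

    f0, _ = nll((tau0, alpha0))
    res = minimize(
        nll,
        np.array([tau0, alpha0], dtype=float),
        jac=True,
        method="L-BFGS-B",
        bounds=[_TAU_BOUNDS, (0.0, ALPHA_MAX)],
        options={"maxiter": maxiter, "ftol": 1e-14, "gtol": 1e-9},
    )
    if res.fun < f0:
        return float(res.x[0]), float(res.x[1])
    return float(tau0), float(alpha0)


def _stacked_update(
    Y,
    X,
    Beta,
    log_t,
    tau,
    alpha,
    mask=None,
    fix_params=False,
    inner_iters=3,
    mstep_maxiter=40,
):
    """A few EM cycles on the coefficient blocks, then a (tau, alpha) step.

    Returns updated ``(Beta, tau, alpha, loglik)``.  Each piece only ever
    increases the observed-data log-likelihood (EM inequality for the
    coefficient cycles; guarded ascent for the parameter step).
    """
    for _ in range(inner_iters):
        eta = X @ Beta
        z = _posterior_z(Y, eta, log_t, tau, alpha)
        Beta = _mstep_betas(Y, X, Beta, log_t, z, tau, alpha, mask, mstep_maxiter)
    eta = X @ Beta
    if not fix_params:
        tau, alpha = _optimize_params(Y, eta, log_t, tau, alpha, mask)
    ll = _pointwise_loglik(Y, eta, log_t, tau, alpha)
    if mask is not None:
        ll = ll * mask
    return Beta, tau, alpha, float(ll.sum())


# ---------------------------------------------------------------------------
# public API
# ---------------------------------------------------------------------------


def zigp_loglik(problem: ZigpRegressionProblem, beta, params: ZigpParams) -> float:
    """Observed-data ZIGP log-likelihood of one regression at (beta, params)."""
    beta = np.asarray(beta, dtype=float)
    eta = problem.X @ beta
    ll = _pointwise_loglik(problem.y, eta, problem.offset_log, params.tau, params.alpha)
    if problem.mask is not None:
        ll = ll * problem.mask
    total = float(ll.sum())
    if not np.isfinite(total):
        bad = np.nonzero(~np.isfinite(ll))[0][:10]
        raise FloatingPointError(f"non-finite log-likelihood at rows {bad.tolist()}")
    return total


def posterior_zero_weights(problem: ZigpRegressionProblem, beta, params: ZigpParams):
    """Posterior probability that each observed zero is structural."""
    eta = problem.X @ np.asarray(beta, dtype=float)
    return _posterior_z(problem.y, eta, problem.offset_log, params.tau, params.alpha)


def _default_beta(problem: ZigpRegressionProblem) -> np.ndarray:
    """Warm start: least squares of log(y+1) - offset on X (included rows)."""
    target = np.log(problem.y + 1.0) - problem.offset_log
    X = problem.X
    if problem.mask is not None:
        X, target = X[problem.mask], target[problem.mask]
    beta, *_ = np.linalg.lstsq(X, target, rcond=None)
    return beta


def em_fit(
    problem: ZigpRegressionProblem,
    init_beta=None,
    init_params: ZigpParams | None = None,
    fix_params: bool = False,
    *,
    max_iter: int = 200,
    tol: float = 1e-6,
    mstep_maxiter: int = 80,
) -> ZigpRegressionFit:
    """Fit one ZIGP regression by EM.

    The E-step computes the structural-zero posterior; the M-step maximizes
    the expected complete-data log-likelihood jointly over ``beta`` (and
    ``tau, alpha`` unless ``fix_params``) by L-BFGS-B with analytic
    gradients.  The observed-data log-likelihood trace is non-decreasing.
    """
    beta = np.asarray(init_beta, dtype=float) if init_beta is not None else _default_beta(problem)
    params = init_params if init_params is not None else ZigpParams(1.0, 0.05)
    tau, alpha = float(params.tau), float(params.alpha)
    y, X, log_t, mask = problem.y, problem.X, problem.offset_log, problem.mask
    gam = gammaln(y + 1.0)
    K = X.shape[1]

    ll = zigp_loglik(problem, beta, ZigpParams(tau, alpha))
    trace = [ll]
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        eta = X @ beta
        z = _posterior_z(y, eta, log_t, tau, alpha)

        if fix_params:
            def negq(vec):
                q, d_eta = _q_eta(y, z, X @ vec, log_t, tau, alpha, gam, mask)
                return -q, -(X.T @ d_eta)

            x0 = beta
            bounds = None
        else:
            def negq(vec):
                b, t, a = vec[:K], vec[K], vec[K + 1]
                eta_v = X @ b
                q, d_eta = _q_eta(y, z, eta_v, log_t, t, a, gam, mask)
                d_t, d_a = _q_tau_alpha_grad(y, z, eta_v, log_t, t, a, mask)
                return -q, -np.concatenate([X.T @ d_eta, [d_t, d_a]])

            x0 = np.concatenate([beta, [tau, alpha]])
            bounds = [(None, None)] * K + [_TAU_BOUNDS, (0.0, ALPHA_MAX)]

        f0, _ = negq(x0)
        res = minimize(
            negq, x0, jac=True, method="L-BFGS-B", bounds=bounds,
            options={"maxiter": mstep_maxiter},
        )
        x = res.x if res.fun <= f0 else x0
        beta = x[:K]
        if not fix_params:
            tau, alpha = float(x[K]), float(np.clip(x[K + 1], 0.0, ALPHA_MAX))

        ll_new = zigp_loglik(problem, beta, ZigpParams(tau, alpha))
        trace.append(ll_new)
        if abs(ll_new - ll) <= tol * (1.0 + abs(ll)):
            ll = ll_new
            converged = True
            break
        ll = ll_new
    if not converged:
        warnings.warn("EM did not converge within max_iter", RuntimeWarning)
    return ZigpRegressionFit(
        beta=beta,
        params=ZigpParams(tau, alpha),
        loglik=ll,
        n_em_iters=n_iter,
        converged=converged,
        loglik_trace=trace,
    )


def stacked_fit(
    problems,
    inits=None,
    init_params: ZigpParams | None = None,
    *,
    fix_params: bool = False,
    tol: float = 1e-5,
    max_outer: int = 25,
    inner_iters: int = 3,
    mstep_maxiter: int = 40,
) -> StackedFit:
    """Fit many ZIGP regressions sharing one global (tau, alpha).

    All problems must share the same design matrix (the factor algorithm
    stacks the columns of the count matrix against the current scores, or
    its rows against the current loadings).  Alternates joint EM updates of
    the coefficient blocks with bounded 2-D maximization over (tau, alpha)
    until the total observed-data log-likelihood stabilizes.
    """
    problems = list(problems)
    if not problems:
        raise ValueError("need at least one problem")
    X = problems[0].X
    for p in problems[1:]:
        if p.X.shape != X.shape or not np.array_equal(p.X, X):
            raise ValueError("stacked_fit requires a shared design matrix")
    n, K = X.shape
    B = len(problems)
    Y = np.column_stack([p.y for p in problems])
    log_t = np.column_stack([p.offset_log for p in problems])
    if any(p.mask is not None for p in problems):
        mask = np.column_stack(
            [p.mask if p.mask is not None else np.ones(n, dtype=bool) for p in problems]
        ).astype(float)
    else:
        mask = None

    if inits is not None:
        Beta = np.column_stack([np.asarray(b, dtype=float) for b in inits])
    else:
        Beta = np.column_stack([_default_beta(p) for p in problems])
    params = init_params if init_params is not None else ZigpParams(1.0, 0.05)
    tau, alpha = float(params.tau), float(params.alpha)

    def total_ll(Beta, tau, alpha):
        ll = _pointwise_loglik(Y, X @ Beta, log_t, tau, alpha)
        if mask is not None:
            ll = ll * mask
        return float(ll.sum())

    ll = total_ll(Beta, tau, alpha)
    trace = [ll]
    converged = False
    for _ in range(max_outer):
        Beta, tau, alpha, ll_new = _stacked_update(
            Y, X, Beta, log_t, tau, alpha, mask,
            fix_params=fix_params, inner_iters=inner_iters, mstep_maxiter=mstep_maxiter,
        )
        trace.append(ll_new)
        if abs(ll_new - ll) <= tol * (1.0 + abs(ll)):
            ll = ll_new
            converged = True
            break
        ll = ll_new
    if not converged:
        warnings.warn("stacked_fit did not converge within max_outer", RuntimeWarning)
    betas = [Beta[:, j].copy() for j in range(B)]
    return StackedFit(
        betas=betas,
        params=ZigpParams(tau, alpha),
        loglik=ll,
        loglik_trace=trace,
        converged=converged,
    )
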