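"""Generalized Poisson (GP) and zero-inflated GP probability primitives.

The GP distribution is used in its mean parameterization,

    p(y; mu, alpha) = (1/y!) * (mu/(1+alpha*mu))**y * (1+alpha*y)**(y-1)
                      * exp(-mu*(1+alpha*y)/(1+alpha*mu)),

with mean ``mu > 0`` and dispersion ``alpha >= 0``; the variance is
``mu * (1+alpha*mu)**2`` so ``alpha = 0`` recovers the Poisson distribution.
Only over-dispersion is supported: negative ``alpha`` truncates the support
and is rejected.

The zero-inflated GP (ZIGP) mixes a point mass at zero (probability ``phi``,
the *structural* or excess-zero probability) with a GP draw.  In the factor
model ``phi`` is tied to the latent rate ``lam`` through a shape parameter
``tau``; the model link is ``logit(phi) = -tau * log(lam)`` and two
alternative links (used only when generating data under misspecification)
are provided as well.

All pmf evaluations are carried out in log space.
"""

from __future__ import annotations

import enum
import math

import numpy as np
from scipy.special import expit, gammaln, log_expit

__all__ = [
    "ALPHA_MAX",
    "GpParams",
    "ZigpParams",
    "ZeroLink",
    "gp_logpmf",
    "zigp_logpmf",
    "phi_from_lambda",
    "gp_sample",
    "zigp_sample",
    "zigp_total_zero_prob",
]

#: Upper bound for the GP dispersion parameter.  Microbiome counts are
#: over-dispersed but finite; the box keeps the M-steps well conditioned.
ALPHA_MAX = 5.0


class ZeroLink(str, enum.Enum):
    """Functional form tying the structural-zero probability to the rate."""

    #: logit(phi) = -tau*log(lam)  (the model link; negative association)
    LOGIT_NEG = "logit_neg"
    #: log(-log(phi)) = tau*log(lam)
    LOGLOG = "loglog"
    #: log(-log(1-phi)) = tau*log(lam)
    CLOGLOG = "cloglog"
    #: a fixed per-taxon phi_j, independent of lam (simulation only)
    FIXED_PER_TAXON = "fixed_per_taxon"


class GpParams:
    """Mean/dispersion pair of a generalized Poisson distribution.

    Parameters
    ----------
    mu : float
        Mean of the GP component (the model uses ``T_i * lam_ij``).
    alpha : float
        Dispersion; ``0 <= alpha <= ALPHA_MAX``.
    """

    __slots__ = ("mu", "alpha")

    def __init__(self, mu: float, alpha: float):
        mu = float(mu)
        alpha = float(alpha)
        if not mu > 0:
            raise ValueError(f"GP mean must be positive, got mu={mu}")
        _check_alpha(alpha)
        self.mu = mu
        self.alpha = alpha

    def __repr__(self) -> str:  # pragma: no cover
        return f"GpParams(mu={self.mu!r}, alpha={self.alpha!r})"


class ZigpParams:
    """Global (tau, alpha) pair shared by every entry of the factor model."""

    __slots__ = ("tau", "alpha")

    def __init__(self, tau: float, alpha: float):
        tau = float(tau)
        alpha = float(alpha)
        if not math.isfinite(tau):
            raise ValueError(f"tau must be finite, got {tau}")
        _check_alpha(alpha)
        self.tau = tau
        self.alpha = alpha

    def __iter__(self):
        return iter((self.tau, self.alpha))

    def __repr__(self) -> str:  # pragma: no cover
        return f"ZigpParams(tau={self.tau!r}, alpha={self.alpha!r})"


def _check_alpha(alpha) -> None:
    if np.any(np.asarray(alpha) < 0):
        raise ValueError("dispersion alpha must be >= 0 (under-dispersion is not supported)")
    if np.any(np.asarray(alpha) > ALPHA_MAX):
        raise ValueError(f"dispersion alpha must be <= {ALPHA_MAX}")


def _check_counts(y) -> np.ndarray:
    y = np.asarray(y, dtype=float)
    if np.any(y < 0):
        raise ValueError("counts must be non-negative")
    if np.any(y != np.floor(y)):
        raise ValueError("counts must be integers")
    return y


def gp_logpmf(y, mu, alpha):
    """Log pmf of the generalized Poisson distribution.

    Vectorizes over any broadcastable combination of ``y``, ``mu`` and
    ``alpha``.  The ``(1+alpha*y)**(y-1)`` factor is evaluated as
    ``(y-1)*log1p(alpha*y)`` which is exactly 0 at ``y = 0``.
    """
    y = _check_counts(y)
    mu = np.asarray(mu, dtype=float)
    if np.any(mu <= 0):
        raise ValueError("GP mean mu must be positive")
    _check_alpha(alpha)
    alpha = np.asarray(alpha, dtype=float)
    c = 1.0 + alpha * mu
    r = mu / c
    out = (
        y * np.log(r)
        + (y - 1.0) * np.log1p(alpha * y)
        - r * (1.0 + alpha * y)
        - gammaln(y + 1.0)
    )
    return out if out.shape else float(out)


def zigp_logpmf(y, phi, mu, alpha):
    """Log pmf of the zero-inflated GP mixture.

    ``log[phi * 1{y=0} + (1-phi) * p(y; mu, alpha)]`` with a log-sum-exp at
    ``y = 0``.  ``phi`` must lie in ``[0, 1)``.
    """
    y = _check_counts(y)
    phi = np.asarray(phi, dtype=float)
    if np.any(phi < 0) or np.any(phi >= 1):
        raise ValueError("phi must lie in [0, 1)")
    gp = gp_logpmf(y, mu, alpha)
    with np.errstate(divide="ignore"):
        log_phi = np.log(phi)
    log_1mphi = np.log1p(-phi)
    nonzero = log_1mphi + gp
    out = np.where(y > 0, nonzero, np.logaddexp(log_phi, nonzero))
    return out if out.shape else float(out)


def phi_from_lambda(lam, tau, link: ZeroLink | str = ZeroLink.LOGIT_NEG):
    """Structural-zero probability implied by the rate ``lam``.

    ``logit_neg`` (the model link): ``phi = 1/(1+lam**tau)``; strictly
    decreasing in ``lam`` for ``tau > 0``.  ``loglog``: ``phi =
    exp(-lam**tau)``.  ``cloglog``: ``phi = 1 - exp(-lam**tau)``.
    """
    lam = np.asarray(lam, dtype=float)
    if np.any(lam <= 0):
        raise ValueError("lam must be positive")
    link = ZeroLink(link)
    t_log_lam = tau * np.log(lam)
    if link is ZeroLink.LOGIT_NEG:
        out = expit(-t_log_lam)
    elif link is ZeroLink.LOGLOG:
        out = np.exp(-np.exp(t_log_lam))
    elif link is ZeroLink.CLOGLOG:
        out = -np.expm1(-np.exp(t_log_lam))
    else:
        raise ValueError("fixed_per_taxon has no lambda dependence; draw phi_j directly")
    return out if out.shape else float(out)


def _as_rng(rng) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


def gp_sample(mu, alpha, size=None, rng=None, max_generations: int = 100_000):
    """Draw generalized Poisson variates.

    Uses the exact Lagrangian-Poisson (branching process) representation:
    with ``theta = mu/(1+alpha*mu)`` and ``delta = alpha*mu/(1+alpha*mu)``,
    a GP(mu, alpha) variate is the total progeny of a Galton-Watson process
    with Poisson(theta) ancestors and Poisson(delta) offspring.  The process
    is subcritical (``delta < 1``), so it terminates almost surely, the draw
    is exact to the pmf, fully vectorized, and seed-reproducible.
    """
    rng = _as_rng(rng)
    mu = np.asarray(mu, dtype=float)
    if np.any(mu <= 0):
        raise ValueError("GP mean mu must be positive")
    _check_alpha(alpha)
    alpha = np.asarray(alpha, dtype=float)
    if size is not None:
        mu, alpha = np.broadcast_arrays(*np.broadcast_arrays(mu, alpha), np.empty(size))[:2]
    theta = mu / (1.0 + alpha * mu)
    delta = alpha * mu / (1.0 + alpha * mu)
    total = rng.poisson(theta)
    active = total.copy() if isinstance(total, np.ndarray) else np.asarray(total)
    total = np.asarray(total)
    delta = np.broadcast_to(delta, total.shape)
    for _ in range(max_generations):
        alive = active > 0
        if not alive.any():
            break
        births = rng.poisson(delta[alive] * active[alive])
        nxt = np.zeros_like(active)
        nxt[alive] = births
        total = total + nxt
        active = nxt
    else:  # pragma: no cover - subcritical process; defensive only
        raise RuntimeError("GP branching sampler failed to terminate")
    if size is None and total.shape == ():
        return int(total)
    return total


def zigp_sample(phi, mu, alpha, size=None, rng=None):
    """Draw zero-inflated GP variates (structural zeros with probability phi)."""
    rng = _as_rng(rng)
    phi = np.asarray(phi, dtype=float)
    if np.any(phi < 0) or np.any(phi >= 1):
        raise ValueError("phi must lie in [0, 1)")
    y = gp_sample(mu, alpha, size=size, rng=rng)
    y = np.asarray(y)
    structural = rng.random(y.shape) < np.broadcast_to(phi, y.shape)
    y = np.where(structural, 0, y)
    return y


def zigp_total_zero_prob(phi, mu, alpha, mixture: bool = True):
    """Total probability that a ZIGP count equals zero.

    The mixture-correct form is ``phi + (1-phi) * exp(-mu/(1+alpha*mu))``
    (default).  ``mixture=False`` returns ``phi + exp(-mu/(1+alpha*mu))``,
    the unweighted sum of the structural mass and the GP zero mass, which
    some diagnostics print; it can exceed 1 and is not a probability in
    general.
    """
    phi = np.asarray(phi, dtype=float)
    mu = np.asarray(mu, dtype=float)
    _check_alpha(alpha)
    p0 = np.exp(-mu / (1.0 + np.asarray(alpha, dtype=float) * mu))
    out = phi + p0 if not mixture else phi + (1.0 - phi) * p0
    return out if out.shape else float(out)
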