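"""Synthetic zero-inflated count matrices with a known rank-3 log-rate.

The generator emulates a canonical benchmark design for count-matrix factor
models: a 200 x 3 score matrix F and a 100 x 3 loading matrix L with
piecewise-constant blocks plus small Gaussian jitter, a rate matrix
``Lam = exp(F L^T)``, and counts drawn from a zero-inflated distribution
under six scenarios:

1. ZIGP counts, model link            logit(phi)    = -tau*log(lam)
2. ZIGP counts, misspecified link     log(-log(phi))   = tau*log(lam)
3. ZIGP counts, misspecified link     log(-log(1-phi)) = tau*log(lam)
4. ZIGP counts, fixed per-taxon phi_j ~ Uniform(c-0.1, c+0.1)
5. ZIP counts (Poisson component), model link
6. ZINB counts (negative binomial component), model link

The block design (1-based inclusive ranges at the canonical 200 x 100 size;
other sizes scale the break points proportionally):

    F column 1:  F(36:80)  = 2.0,  F(81:140) = 1.7
    F column 2:  F(1:35)   = 1.8,  F(36:80)  = 0.9
    F column 3:  F(1:35)   = 1.7,  F(36:200) = 0.9
    L column 1:  L(61:100) = 1.7
    L column 2:  L(36:60)  = 1.7,  L(61:100) = 1.0
    L column 3:  L(1:25)   = 1.7,  L(26:100) = 0.9

all remaining entries 0, then N(0, 0.06^2) jitter on every entry of F and
N(0, 0.05^2) on every entry of L.  The published description of this design
contains two internally inconsistent column-3 assignments; the default
above resolves both so that column 3 mirrors the loading pattern (a large
first block, 0.9 elsewhere), which keeps every rate bounded away from 1 —
a requirement for the zero-probability calibration below to reach light
(20%) inflation.  ``blocks="literal"`` applies the inconsistent printed
assignments verbatim instead.

The zero level of a scenario is a *target total zero fraction*: the link
shape ``tau`` (or the Uniform center for scenario 4) is calibrated by root
finding so that the expected fraction of zeros — structural plus sampling —
equals the target.  ``zero_mode="phi"`` instead calibrates the mean
structural-zero probability to the target.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import brentq

from .distributions import ZeroLink, gp_sample, phi_from_lambda
from .factor import CountMatrix

__all__ = [
    "ScenarioSpec",
    "SimulatedDataset",
    "CalibrationError",
    "build_true_factors",
    "calibrate_tau",
    "generate",
]

_SCENARIO_LINKS = {
    1: ZeroLink.LOGIT_NEG,
    2: ZeroLink.LOGLOG,
    3: ZeroLink.CLOGLOG,
    4: ZeroLink.FIXED_PER_TAXON,
    5: ZeroLink.LOGIT_NEG,
    6: ZeroLink.LOGIT_NEG,
}


class CalibrationError(ValueError):
    """The requested zero fraction is outside the attainable range."""


@dataclass
class ScenarioSpec:
    """Settings of one simulation scenario."""

    scenario: int = 1
    zero_target: float = 0.20
    n: int = 200
    m: int = 100
    alpha: float = 0.2
    T: np.ndarray | None = None  # defaults to all ones
    jitter_sd_F: float = 0.06
    jitter_sd_L: float = 0.05
    nb_size: float | None = None  # scenario 6 only; None = variance-matched
    zero_mode: str = "total"  # "total" or "phi"
    blocks: str = "consistent"  # or "literal"
    seed: int = 0

    def __post_init__(self):
        if self.scenario not in _SCENARIO_LINKS:
            raise ValueError(f"scenario must be 1..6, got {self.scenario}")
        if not 0.0 < self.zero_target < 1.0:
            raise ValueError("zero_target must lie in (0, 1)")
        if self.zero_mode not in ("total", "phi"):
            raise ValueError("zero_mode must be 'total' or 'phi'")


@dataclass
class SimulatedDataset:
    """A simulated count matrix together with its generating truth."""

    Y: CountMatrix
    F_true: np.ndarray
    L_true: np.ndarray
    logLambda_true: np.ndarray
    Phi_true: np.ndarray
    tau_used: float
    spec: ScenarioSpec = field(repr=False)


def _scaled(idx: int, size: int, canonical: int) -> int:
    """Scale a canonical 1-based break point to another dimension."""
    return int(round(idx * size / canonical))


def build_true_factors(
    n: int = 200,
    m: int = 100,
    rng=None,
    *,
    jitter_sd_F: float = 0.06,
    jitter_sd_L: float = 0.05,
    blocks: str = "consistent",
):
    """Block-structured true factors with Gaussian jitter.

    Returns ``(F, L)`` of shapes (n, 3) and (m, 3).  ``blocks="literal"``
    applies the internally inconsistent printed column-3 assignments
    (zeroing F(36:200, 2) and overwriting L(26:100, 2) with 0.9) instead of
    the consistent resolution documented in the module docstring.
    """
    if blocks not in ("consistent", "literal"):
        raise ValueError("blocks must be 'consistent' or 'literal'")
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    F = np.zeros((n, 3))
    L = np.zeros((m, 3))
    a35, a80, a140 = (_scaled(i, n, 200) for i in (35, 80, 140))
    b25, b35, b60 = (_scaled(i, m, 100) for i in (25, 35, 60))

    F[a35:a80, 0] = 2.0
    F[a80:a140, 0] = 1.7
    F[:a35, 1] = 1.8
    F[a35:a80, 1] = 0.9
    F[:a35, 2] = 1.7
    L[b60:, 0] = 1.7
    L[b35:b60, 1] = 1.7
    L[b60:, 1] = 1.0
    L[:b25, 2] = 1.7
    if blocks == "consistent":
        F[a35:, 2] = 0.9
        L[b25:, 2] = 0.9
    else:
        F[a35:, 1] = 0.0
        L[b25:, 1] = 0.9

    F = F + rng.normal(0.0, jitter_sd_F, F.shape)
    L = L + rng.normal(0.0, jitter_sd_L, L.shape)
    return F, L


def _sampling_zero_prob(mu, scenario: int, alpha: float, nb_size: float | None):
    """P(count = 0) of the non-structural component, per entry."""
    if scenario in (1, 2, 3, 4):
        return np.exp(-mu / (1.0 + alpha * mu))
    if scenario == 5:
        return np.exp(-mu)
    theta = nb_size
    return np.exp(theta * (np.log(theta) - np.log(theta + mu)))


def _uniform_clipped_mean(c: float, half_width: float = 0.10) -> float:
    """E[clip(U(c-w, c+w), 0, 1)] in closed form."""
    a, b = c - half_width, c + half_width
    lo, hi = max(a, 0.0), min(b, 1.0)
    if hi <= lo:
        return 0.0 if b <= 0 else 1.0
    interior = 0.5 * (lo + hi) * (hi - lo) / (b - a)
    upper_tail = (b - hi) / (b - a)  # mass clipped at 1
    return interior + upper_tail


def default_nb_size(mu_bar: float, alpha: float) -> float:
    """NB size matching the GP variance at a central mean value:
    solve mu + mu^2/theta = mu*(1+alpha*mu)^2 at mu = mu_bar.

    Callers pass the geometric grand mean of ``T*Lam``: rates of a
    log-linear factor model are log-symmetric, so the geometric mean is the
    representative rate (the arithmetic mean is dominated by the largest
    block and yields an NB so over-dispersed that light zero-inflation
    targets become unreachable)."""
    denom = (1.0 + alpha * mu_bar) ** 2 - 1.0
    if denom <= 0:
        return np.inf
    return mu_bar / denom


def calibrate_tau(
    logLambda,
    scenario: int,
    zero_target: float,
    *,
    alpha: float = 0.2,
    T=None,
    nb_size: float | None = None,
    zero_mode: str = "total",
    bracket: tuple = (-30.0, 30.0),
) -> float:
    """Solve for the link shape that attains the requested zero level.

    For lambda-linked scenarios (1-3, 5, 6) the returned value is ``tau``;
    for scenario 4 it is the center of the per-taxon Uniform.  In
    ``zero_mode="total"`` the expected total zero fraction (structural +
    sampling) equals ``zero_target``; in ``zero_mode="phi"`` the expected
    structural-zero probability does.  Raises ``CalibrationError`` when the
    target is outside the attainable range.
    """
    eta = np.asarray(logLambda, dtype=float)
    lam = np.exp(eta)
    n = eta.shape[0]
    T = np.ones(n) if T is None else np.asarray(T, dtype=float)
    mu = T[:, None] * lam
    if scenario == 6 and nb_size is None:
        nb_size = default_nb_size(float(np.exp(np.mean(np.log(mu)))), alpha)
    p0 = _sampling_zero_prob(mu, scenario, alpha, nb_size)
    link = _SCENARIO_LINKS[scenario]

    if scenario == 4:
        def g(c):
            phi_bar = _uniform_clipped_mean(c)
            if zero_mode == "phi":
                return phi_bar - zero_target
            return float(np.mean(phi_bar + (1.0 - phi_bar) * p0)) - zero_target

        lo, hi = 0.0, 1.0 - 1e-9
        if g(lo) > 0 or g(hi) < 0:
            raise CalibrationError(
                f"zero target {zero_target} unattainable for scenario 4 "
                f"(range [{g(lo)+zero_target:.3f}, {g(hi)+zero_target:.3f}])"
            )
        return float(brentq(g, lo, hi, xtol=1e-10))

    def g(tau):
        phi = phi_from_lambda(lam, tau, link)
        if zero_mode == "phi":
            return float(np.mean(phi)) - zero_target
        return float(np.mean(phi + (1.0 - phi) * p0)) - zero_target

    # the zero fraction need not be monotone in tau over the whole line;
    # scan for a sign change, then refine by Brent's method
    grid = np.linspace(bracket[0], bracket[1], 241)
    vals = np.array([g(t) for t in grid])
    sign_change = np.nonzero(np.diff(np.sign(vals)) != 0)[0]
    if sign_change.size == 0:
        raise CalibrationError(
            f"zero target {zero_target} unattainable for scenario {scenario} in "
            f"tau bracket {bracket} (attainable range "
            f"[{vals.min()+zero_target:.3f}, {vals.max()+zero_target:.3f}])"
        )
    i = sign_change[0]
    return float(brentq(g, grid[i], grid[i + 1], xtol=1e-10))


def generate(spec: ScenarioSpec) -> SimulatedDataset:
    """Generate one dataset under a scenario; bit-reproducible for a seed."""
    rng = np.random.default_rng(spec.seed)
    F, L = build_true_factors(
        spec.n, spec.m, rng,
        jitter_sd_F=spec.jitter_sd_F, jitter_sd_L=spec.jitter_sd_L,
        blocks=spec.blocks,
    )
    eta = F @ L.T
    lam = np.exp(eta)
    T = np.ones(spec.n) if spec.T is None else np.asarray(spec.T, dtype=float)
    mu = T[:, None] * lam
    nb_size = spec.nb_size
    if spec.scenario == 6 and nb_size is None:
        nb_size = default_nb_size(float(np.exp(np.mean(np.log(mu)))), spec.alpha)

    tau = calibrate_tau(
        eta, spec.scenario, spec.zero_target,
        alpha=spec.alpha, T=T, nb_size=nb_size, zero_mode=spec.zero_mode,
    )
    if spec.scenario == 4:
        phi_j = np.clip(rng.uniform(tau - 0.10, tau + 0.10, spec.m), 0.0, 1.0 - 1e-9)
        Phi = np.broadcast_to(phi_j, (spec.n, spec.m)).copy()
    else:
        Phi = phi_from_lambda(lam, tau, _SCENARIO_LINKS[spec.scenario])

    structural = rng.random((spec.n, spec.m)) < Phi
    if spec.scenario in (1, 2, 3, 4):
        counts = gp_sample(mu, spec.alpha, rng=rng)
    elif spec.scenario == 5:
        counts = rng.poisson(mu)
    else:
        shape = rng.gamma(nb_size, 1.0, size=mu.shape)
        counts = rng.poisson(shape * mu / nb_size)
    Y = np.where(structural, 0, counts).astype(np.int64)

    return SimulatedDataset(
        Y=CountMatrix(Y),
        F_true=F,
        L_true=L,
        logLambda_true=eta,
        Phi_true=np.asarray(Phi, dtype=float),
        tau_used=float(tau),
        spec=spec,
    )


def generate_replicates(spec: ScenarioSpec, n_replicates: int, base_seed: int | None = None):
    """Yield datasets with seeds base_seed, base_seed+1, ..."""
    base = spec.seed if base_seed is None else base_seed
    for r in range(n_replicates):
        yield generate(replace(spec, seed=base + r))
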