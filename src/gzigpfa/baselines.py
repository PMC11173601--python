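"""Log-PCA baseline, Frobenius loss, and the simulation benchmark harness.

The log-PCA baseline replaces zeros by a small pseudo value, takes
logarithms, and reconstructs the log-rate matrix by a rank-K principal
component approximation (column-centered truncated SVD with the means
added back).  Accuracy of a method on simulated data is measured by the
Frobenius norm of the error between the estimated and the true log-rate
matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from joblib import Parallel, delayed
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .factor import GZIGPFA, _as_count_array
from .simulate import ScenarioSpec, generate

__all__ = [
    "LogPCA",
    "MethodResult",
    "LossSummary",
    "log_pca",
    "frobenius_loss",
    "run_benchmark_cell",
]


@dataclass
class MethodResult:
    """A method's rank-K estimate of the log-rate matrix."""

    method: str
    logLambda_hat: np.ndarray
    rank: int


@dataclass
class LossSummary:
    """Per-replicate Frobenius losses of a method under one scenario."""

    per_replicate_losses: np.ndarray
    mean: float
    sd: float
    n_replicates: int
    scenario: ScenarioSpec
    method: str
    n_failed: int = 0


class LogPCA(TransformerMixin, BaseEstimator):
    """Pseudo-count log transform followed by rank-K PCA reconstruction.

    Zeros are replaced by ``pseudo`` (default 0.5, the half-minimum-count
    convention), the matrix is log-transformed and column-centered, and the
    log-rate estimate is the column means plus the best rank-K
    approximation of the centered matrix.  ``center=False`` uses a raw
    truncated SVD instead.
    """

    def __init__(self, n_components: int = 3, *, pseudo: float = 0.5, center: bool = True):
        self.n_components = n_components
        self.pseudo = pseudo
        self.center = center

    def fit(self, Y, y=None):
        arr, sample_ids, taxon_ids, _ = _as_count_array(Y)
        if self.pseudo <= 0:
            raise ValueError("pseudo must be positive")
        K = self.n_components
        if not 0 <= K <= min(arr.shape):
            raise ValueError(f"n_components={K} out of range")
        Z = np.log(np.where(arr > 0, arr, self.pseudo))
        mean_ = Z.mean(axis=0) if self.center else np.zeros(Z.shape[1])
        Zc = Z - mean_
        if K == 0:
            self.log_rate_ = np.broadcast_to(mean_, Z.shape).copy()
            self.components_ = np.zeros((0, Z.shape[1]))
            self.scores_ = np.zeros((Z.shape[0], 0))
            self.singular_values_ = np.zeros(0)
        else:
            U, s, Vt = np.linalg.svd(Zc, full_matrices=False)
            self.scores_ = U[:, :K] * s[:K]
            self.components_ = Vt[:K]
            self.singular_values_ = s[:K]
            self.log_rate_ = mean_ + self.scores_ @ self.components_
        self.mean_ = mean_
        self.n_features_in_ = arr.shape[1]
        return self

    def fit_transform(self, Y, y=None):
        return self.fit(Y).scores_

    def transform(self, Y):
        check_is_fitted(self, "components_")
        arr, _, _, _ = _as_count_array(Y)
        Z = np.log(np.where(arr > 0, arr, self.pseudo)) - self.mean_
        return Z @ self.components_.T


def log_pca(Y, K: int, pseudo: float = 0.5, center: bool = True) -> MethodResult:
    """Functional wrapper around :class:`LogPCA`."""
    est = LogPCA(n_components=K, pseudo=pseudo, center=center).fit(Y)
    return MethodResult(method="log_pca", logLambda_hat=est.log_rate_, rank=K)


def frobenius_loss(logLambda_hat, logLambda_true) -> float:
    """``||logLambda_hat - logLambda_true||_F``."""
    A = np.asarray(logLambda_hat, dtype=float)
    B = np.asarray(logLambda_true, dtype=float)
    if A.shape != B.shape:
        raise ValueError(f"shape mismatch: {A.shape} vs {B.shape}")
    return float(np.linalg.norm(A - B))


def _fit_method(method: str, Y, rank: int, method_options: dict, T=None):
    if method == "gzigpfa":
        opts = dict(method_options)
        if T is not None:
            # benchmark fits use the generating library sizes so that the
            # estimated and true log-rate matrices share one normalization
            opts.setdefault("library_size", T)
        est = GZIGPFA(n_components=rank, **opts).fit(Y)
        return est.log_rate_
    if method == "log_pca":
        return log_pca(Y, rank, **method_options).logLambda_hat
    raise ValueError(f"unknown method {method!r} (expected 'gzigpfa' or 'log_pca')")


def _one_replicate(spec: ScenarioSpec, method: str, rank: int, seed: int, method_options):
    data = generate(replace(spec, seed=seed))
    T = np.ones(data.Y.shape[0]) if spec.T is None else np.asarray(spec.T, float)
    try:
        hat = _fit_method(method, data.Y.Y, rank, method_options, T=T)
        return frobenius_loss(hat, data.logLambda_true)
    except Exception:  # noqa: BLE001 - per-replicate failures are summarized
        return np.nan


def run_benchmark_cell(
    spec: ScenarioSpec,
    method: str = "gzigpfa",
    n_replicates: int = 10,
    base_seed: int = 0,
    *,
    rank: int = 3,
    n_jobs: int = 1,
    method_options: dict | None = None,
) -> LossSummary:
    """Mean and SD of the Frobenius loss over replicate simulations.

    Replicate ``r`` uses seed ``base_seed + r``; results are keyed by the
    replicate seed and therefore independent of ``n_jobs``.
    """
    if method not in ("gzigpfa", "log_pca"):
        raise ValueError(f"unknown method {method!r} (expected 'gzigpfa' or 'log_pca')")
    method_options = dict(method_options or {})
    losses = Parallel(n_jobs=n_jobs)(
        delayed(_one_replicate)(spec, method, rank, base_seed + r, method_options)
        for r in range(n_replicates)
    )
    losses = np.asarray(losses, dtype=float)
    ok = losses[np.isfinite(losses)]
    n_failed = int(losses.size - ok.size)
    if n_failed:
        import warnings

        warnings.warn(f"{n_failed}/{losses.size} replicates failed and were excluded")
    sd = float(np.std(ok, ddof=1)) if ok.size > 1 else 0.0
    return LossSummary(
        per_replicate_losses=losses,
        mean=float(ok.mean()) if ok.size else float("nan"),
        sd=sd,
        n_replicates=int(ok.size),
        scenario=spec,
        method=method,
        n_failed=n_failed,
    )
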