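"""Entry-wise N-fold cross-validation for selecting the factor rank.

The nm matrix entries are randomly partitioned into N folds.  For each
fold, the factor model is fitted on the complement (excluded entries drop
out of every column/row regression and of the likelihood) and the ZIGP
log-likelihood of the held-out entries is evaluated at the fitted
``(F, L, tau, alpha)``.  The candidate rank with the largest summed
held-out log-likelihood wins; ties go to the smaller rank.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .factor import GZIGPFA, _as_count_array
from .glm import _pointwise_loglik

__all__ = ["CvResult", "make_folds", "cv_select_rank"]

DEFAULT_RANKS = (1, 2, 3, 4, 5, 6)


@dataclass
class CvResult:
    """Cross-validated rank selection outcome."""

    ranks: list
    cv_loglik: np.ndarray
    selected_rank: int
    fold_assignment: np.ndarray
    seed: int | None = None


def make_folds(shape, n_folds: int, seed=None, max_retries: int = 50) -> np.ndarray:
    """Randomly partition the entries of an (n, m) matrix into N folds.

    Returns an integer matrix with values in ``{0, ..., N-1}``; fold sizes
    differ by at most one.  A fold is re-drawn (bounded retries) if removing
    it would leave some row or column with no training entries.
    """
    n, m = shape
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    if n_folds > n * m:
        raise ValueError(f"cannot split {n*m} entries into {n_folds} folds")
    rng = np.random.default_rng(seed)
    for _ in range(max_retries):
        perm = rng.permutation(n * m)
        fold = np.empty(n * m, dtype=np.int64)
        for k, part in enumerate(np.array_split(perm, n_folds)):
            fold[part] = k
        fold = fold.reshape(n, m)
        ok = True
        for k in range(n_folds):
            train = fold != k
            if np.any(~train.any(axis=1)) or np.any(~train.any(axis=0)):
                ok = False
                break
        if ok:
            return fold
    raise ValueError(
        f"could not build {n_folds} folds keeping every row/column observed; "
        f"matrix {shape} is too small"
    )


def cv_select_rank(
    Y,
    ranks=DEFAULT_RANKS,
    n_folds: int = 10,
    seed=None,
    *,
    warm_start: bool = True,
    fit_options: dict | None = None,
    fold_fit_options: dict | None = None,
) -> CvResult:
    """Select the factor rank by entry-wise N-fold cross-validation.

    ``fit_options`` configure the full-data fit per rank (used as the warm
    start); ``fold_fit_options`` configure the per-fold fits, which by
    default run fewer outer iterations since they start near the full-data
    solution.
    """
    arr, _, _, _ = _as_count_array(Y)
    n, m = arr.shape
    ranks = sorted(set(int(k) for k in ranks))
    if ranks[-1] > min(n, m):
        raise ValueError(f"candidate rank {ranks[-1]} exceeds min(n, m)")
    fold = make_folds((n, m), n_folds, seed)
    fit_options = dict(fit_options or {})
    fold_fit_options = dict(fold_fit_options or {})
    fold_fit_options.setdefault("max_iter", 8)

    cv_ll = np.zeros(len(ranks))
    for ki, K in enumerate(ranks):
        full = GZIGPFA(n_components=K, **fit_options).fit(arr)
        total = 0.0
        for f in range(n_folds):
            train = fold != f
            if warm_start:
                model = GZIGPFA(n_components=K, **{**fit_options, **fold_fit_options})
                model.fit(
                    arr, mask=train,
                    F_init=full.F_, L_init=full.L_,
                    params_init=full.to_factor_fit().params,
                )
            else:
                model = GZIGPFA(n_components=K, **{**fit_options, **fold_fit_options})
                model.fit(arr, mask=train)
            log_t = np.log(model.T_)[:, None]
            ll = _pointwise_loglik(arr, model.log_rate_, log_t, model.tau_, model.alpha_)
            total += float(ll[~train].sum())
        cv_ll[ki] = total

    best = int(np.argmax(cv_ll))  # argmax returns the first (smallest) rank on ties
    return CvResult(
        ranks=list(ranks),
        cv_loglik=cv_ll,
        selected_rank=ranks[best],
        fold_assignment=fold,
        seed=seed,
    )
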