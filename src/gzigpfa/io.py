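"""Tabular input/output: count tables, fitted factors, CV summaries."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .factor import CountMatrix, FactorFit, GZIGPFA
from .rank_cv import CvResult

__all__ = ["read_count_table", "write_count_table", "write_fit"]


def _sep_for(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_count_table(path, orientation: str = "samples_rows") -> CountMatrix:
    """Read a TSV/CSV count table into a CountMatrix.

    The first column holds row IDs and the header row holds column IDs.
    ``orientation="taxa_rows"`` transposes the table into the internal
    samples x taxa layout.
    """
    path = Path(path)
    if orientation not in ("samples_rows", "taxa_rows"):
        raise ValueError("orientation must be 'samples_rows' or 'taxa_rows'")
    df = pd.read_csv(path, sep=_sep_for(path), index_col=0)
    if df.index.has_duplicates or df.columns.has_duplicates:
        raise ValueError(f"{path}: duplicate row or column IDs")
    arr = df.to_numpy()
    if not np.issubdtype(arr.dtype, np.number):
        bad = np.argwhere(~df.map(lambda v: isinstance(v, (int, float, np.number))).to_numpy())
        r, c = bad[0]
        raise ValueError(f"{path}: non-numeric cell at row {df.index[r]!r}, column {df.columns[c]!r}")
    flt = arr.astype(float)
    bad = np.argwhere((flt < 0) | (flt != np.floor(flt)))
    if bad.size:
        r, c = bad[0]
        raise ValueError(
            f"{path}: cell (row {df.index[r]!r}, column {df.columns[c]!r}) "
            f"= {df.iat[r, c]!r} is not a non-negative integer"
        )
    if orientation == "taxa_rows":
        df = df.T
    return CountMatrix(
        Y=df.to_numpy().astype(np.int64),
        sample_ids=[str(i) for i in df.index],
        taxon_ids=[str(c) for c in df.columns],
    )


def write_count_table(cm: CountMatrix, path) -> None:
    path = Path(path)
    df = pd.DataFrame(cm.Y, index=cm.sample_ids, columns=cm.taxon_ids)
    df.to_csv(path, sep=_sep_for(path))


def _factor_frame(M: np.ndarray, row_ids, prefix: str) -> pd.DataFrame:
    cols = [f"factor_{k+1}" for k in range(M.shape[1])]
    return pd.DataFrame(M, index=row_ids, columns=cols)


def write_fit(fit, out_dir, cv: CvResult | None = None, seed=None) -> dict:
    """Write F.tsv, L.tsv, params.json (and cv.tsv) to a directory.

    ``fit`` may be a fitted :class:`GZIGPFA` estimator or a ``FactorFit``.
    Floats are written at full precision, so reading the tables back
    reproduces ``F L^T`` exactly.  Returns the paths written.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if isinstance(fit, GZIGPFA):
        sample_ids, taxon_ids = fit.sample_ids_, fit.taxon_ids_
        fit = fit.to_factor_fit()
    else:
        sample_ids = taxon_ids = None
    n, K = fit.F.shape
    m = fit.L.shape[0]
    sample_ids = sample_ids or [f"sample_{i+1}" for i in range(n)]
    taxon_ids = taxon_ids or [f"taxon_{j+1}" for j in range(m)]

    paths = {}
    paths["F"] = out / "F.tsv"
    _factor_frame(fit.F, sample_ids, "sample").to_csv(
        paths["F"], sep="\t", float_format=None
    )
    paths["L"] = out / "L.tsv"
    _factor_frame(fit.L, taxon_ids, "taxon").to_csv(paths["L"], sep="\t", float_format=None)
    params = {
        "tau": fit.params.tau,
        "alpha": fit.params.alpha,
        "rank": K,
        "loglik_trace": [float(v) for v in fit.loglik_trace],
        "n_iters": fit.n_iters,
        "converged": bool(fit.converged),
        "relative_library_size": [float(t) for t in fit.T],
        "seed": seed,
        "package_version": __version__,
    }
    paths["params"] = out / "params.json"
    paths["params"].write_text(json.dumps(params, indent=2))
    if cv is not None:
        paths["cv"] = out / "cv.tsv"
        pd.DataFrame({"rank": cv.ranks, "cv_loglik": cv.cv_loglik}).to_csv(
            paths["cv"], sep="\t", index=False
        )
    return paths
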