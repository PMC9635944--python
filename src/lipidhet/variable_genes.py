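"""Standardized-variance (vst-style) gene ranking and variable-gene selection.

The heterogeneity analysis ranks genes by how much more variable they are than
expected for their mean expression.  The procedure, on raw counts:

1. compute per-gene mean and (sample) variance across cells;
2. fit a smooth trend of log10(variance) on log10(mean) across genes with a
   local polynomial regression (degree 2, span 0.3 — tricube-weighted
   quadratic fits over the nearest 30% of genes);
3. standardize each count by the trend-predicted standard deviation and clip
   standardized values at sqrt(n_cells) (upper clip, as in the reference vst
   implementation — counts are bounded below so large negative residuals do
   not occur);
4. the gene's score is the variance of the clipped standardized values,
   computed with the pre-clip mean and an n-1 denominator.

Constant (zero-variance) genes score 0.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from anndata import AnnData

from ._utils import to_dense

__all__ = [
    "loess_fit",
    "standardized_variance",
    "rank_genes",
    "select_variable_genes",
]


def loess_fit(
    x: np.ndarray,
    y: np.ndarray,
    x_eval: np.ndarray | None = None,
    span: float = 0.3,
    degree: int = 2,
) -> np.ndarray:
    """Local polynomial regression with tricube weights.

    For each evaluation point the nearest ``ceil(span * n)`` observations are
    fit with a weighted polynomial of the given degree; the fitted value at
    the point is returned.  Evaluation points equal to observation points
    reproduce a classical loess fit.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x_eval is None:
        x_eval = x
    n = x.size
    k = max(int(np.ceil(span * n)), degree + 1)
    order = np.argsort(x)
    xs, ys = x[order], y[order]
    out = np.empty(x_eval.size)
    for i, x0 in enumerate(np.asarray(x_eval, dtype=float)):
        # contiguous window of the k nearest neighbours in x
        pos = np.searchsorted(xs, x0)
        lo = min(max(pos - k, 0), n - k)
        hi = lo + k
        while hi < n and (xs[hi] - x0) < (x0 - xs[lo]):
            lo += 1
            hi += 1
        xw, yw = xs[lo:hi], ys[lo:hi]
        d = np.abs(xw - x0)
        dmax = d.max()
        if dmax == 0:
            out[i] = yw.mean()
            continue
        w = (1 - (d / dmax) ** 3) ** 3
        w = np.clip(w, 1e-12, None)
        basis = np.vander(xw - x0, degree + 1, increasing=True)
        sw = np.sqrt(w)
        coef, *_ = np.linalg.lstsq(basis * sw[:, None], yw * sw, rcond=None)
        out[i] = coef[0]
    return out


def standardized_variance(
    adata: AnnData, span: float = 0.3, degree: int = 2
) -> pd.Series:
    """Per-gene vst standardized variance from raw counts.

    Returns a Series indexed by gene in the input order.  Requires at least
    two cells.  All-zero input yields all-zero scores with a warning.
    """
    if adata.n_obs < 2:
        raise ValueError("standardized variance requires at least 2 cells")
    X = to_dense(adata.X)
    n = X.shape[0]
    mean = X.mean(axis=0)
    var = X.var(axis=0, ddof=1)
    scores = np.zeros(X.shape[1])
    usable = (var > 0) & (mean > 0)
    if not usable.any():
        warnings.warn("all genes are constant; all scores set to 0", stacklevel=2)
        return pd.Series(scores, index=adata.var_names, name="standardized_variance")

    log_mean = np.log10(mean[usable])
    log_var = np.log10(var[usable])
    trend = loess_fit(log_mean, log_var, span=span, degree=degree)
    exp_sd = np.sqrt(10.0 ** trend)

    clip = np.sqrt(n)
    Z = (X[:, usable] - mean[usable]) / exp_sd
    np.minimum(Z, clip, out=Z)
    scores[usable] = (Z**2).sum(axis=0) / (n - 1)
    return pd.Series(scores, index=adata.var_names, name="standardized_variance")


def rank_genes(scores: pd.Series) -> pd.DataFrame:
    """Descending score order; ties broken lexicographically by gene ID."""
    df = scores.rename("score").rename_axis("gene").reset_index()
    df = df.sort_values(["score", "gene"], ascending=[False, True], kind="mergesort")
    return df.reset_index(drop=True)


def select_variable_genes(
    normalized: pd.DataFrame,
    scores: pd.Series,
    mean_bounds: tuple[float, float] = (0.125, 3.0),
    min_std_variance: float = 0.5,
) -> list[str]:
    """Variable genes: mean normalized expression within ``mean_bounds``
    (inclusive) and standardized variance strictly above ``min_std_variance``.

    ``normalized`` is a cell x gene matrix of normalized (typically
    log-transformed) expression.  Returns the selected genes in input order;
    warns when the selection is empty.
    """
    means = normalized.mean(axis=0)
    lo, hi = mean_bounds
    keep = (means >= lo) & (means <= hi) & (scores.reindex(means.index) > min_std_variance)
    selected = list(means.index[keep])
    if not selected:
        warnings.warn("no variable genes passed the selection thresholds", stacklevel=2)
    return selected
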