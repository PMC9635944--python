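"""GSVA-style per-cell meta-module scores and their sub-cluster Z-summary.

The score of a gene module in one cell is a rank-based single-sample
enrichment statistic:

1. counts are size-factor normalized (cell total / median total) and
   log(1+x) transformed;
2. per gene, expression is mapped through a Gaussian-kernel smoothed
   cumulative distribution across cells (bandwidth = gene sd / 4);
3. per cell, genes are ranked by that statistic (descending) and the ranks
   symmetrically centered: s = |n_genes/2 - rank|;
4. a weighted Kolmogorov-Smirnov random walk over the per-cell ranking
   (hit increments |s|^tau normalized over the module, miss decrements
   1/(n_genes - module size)); the score is the maximum positive deviation
   minus the magnitude of the maximum negative deviation, hence bounded in
   [-1, 1].

Per-cell scores are averaged within each sub-cluster and the averages
converted to Z-scores across sub-clusters with the sample (n-1) sd.

This is an O(n_cells^2 x n_genes) computation; it is intended for count
matrices restricted to the sub-clusters of interest.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from anndata import AnnData
from scipy.special import ndtr

from ._utils import to_dense
from .genesets import GeneSetCollection
from .profiles import zscore_across_columns

__all__ = [
    "MetaModuleScores",
    "size_factor_log_normalize",
    "gsva_scores",
    "gsva_meta_scores",
]


@dataclass
class MetaModuleScores:
    cell_scores: pd.DataFrame  # cell x module
    subcluster_means: pd.DataFrame  # module x subcluster
    z: pd.DataFrame  # module x subcluster


def size_factor_log_normalize(adata: AnnData) -> pd.DataFrame:
    """Median-of-totals size-factor normalization followed by log1p."""
    X = to_dense(adata.X)
    totals = X.sum(axis=1)
    if np.any(totals <= 0):
        raise ValueError("cells with zero total counts cannot be normalized")
    sf = totals / np.median(totals)
    return pd.DataFrame(
        np.log1p(X / sf[:, None]), index=adata.obs_names, columns=adata.var_names
    )


def _kernel_cdf(expr: np.ndarray) -> np.ndarray:
    """Gaussian-kernel CDF statistic per gene (columns) across cells (rows)."""
    n, g = expr.shape
    out = np.empty_like(expr)
    sd = expr.std(axis=0, ddof=1)
    h = sd / 4.0
    for j in range(g):
        diff = (expr[:, j][:, None] - expr[:, j][None, :]) / h[j]
        out[:, j] = ndtr(diff).mean(axis=1)
    return out


def _walk_scores(stat_ranked: np.ndarray, hit_ranks: np.ndarray, tau: float) -> float:
    """Max-deviation-difference KS walk score for one cell."""
    n = stat_ranked.size
    s = hit_ranks.size
    inc = stat_ranked[hit_ranks] ** tau
    tot = inc.sum()
    if tot == 0:
        inc = np.ones(s)
        tot = float(s)
    cumw = np.cumsum(inc) / tot
    k = np.arange(s)
    drop = (hit_ranks - k) / (n - s)
    after = cumw - drop
    before = after - inc / tot
    max_pos = max(after.max(), 0.0)
    min_neg = min(before.min(), 0.0)
    return float(max_pos + min_neg)


def gsva_scores(
    expr: pd.DataFrame,
    modules: GeneSetCollection,
    tau: float = 1.0,
) -> pd.DataFrame:
    """Per-cell module scores on a normalized cell x gene matrix.

    Zero-variance genes are dropped before kernel estimation with a warning;
    modules empty after restriction to the remaining genes are skipped.
    """
    var = expr.var(axis=0, ddof=1)
    flat = var == 0
    if flat.any():
        warnings.warn(
            f"dropping {int(flat.sum())} zero-variance gene(s) before GSVA",
            stacklevel=2)
        expr = expr.loc[:, ~flat]
    genes = expr.columns.to_numpy()
    n_genes = genes.size
    gene_index = {g: i for i, g in enumerate(genes)}

    z = _kernel_cdf(expr.to_numpy(dtype=float))
    # per cell: rank genes by decreasing statistic, symmetric centered ranks
    order = np.argsort(-z, axis=1, kind="stable")
    ranks = np.empty_like(order)
    rows = np.arange(z.shape[0])[:, None]
    ranks[rows, order] = np.arange(1, n_genes + 1)
    stat = np.abs(n_genes / 2.0 - ranks)  # cell x gene, in gene order

    scores = {}
    for name, members in modules:
        idx = np.array(sorted(gene_index[g] for g in members if g in gene_index))
        if idx.size == 0 or idx.size >= n_genes:
            warnings.warn(f"module {name!r} unusable after gene restriction; skipped",
                          stacklevel=2)
            continue
        col = np.empty(z.shape[0])
        for c in range(z.shape[0]):
            ranked_stat = stat[c, order[c]]
            hit_ranks = np.sort(ranks[c, idx] - 1)
            col[c] = _walk_scores(ranked_stat, hit_ranks, tau)
        scores[name] = col
    return pd.DataFrame(scores, index=expr.index)


def gsva_meta_scores(
    adata: AnnData,
    modules: GeneSetCollection,
    labels: pd.Series,
    tau: float = 1.0,
) -> MetaModuleScores:
    """Meta-module scores per cell, averaged and Z-scored per sub-cluster."""
    expr = size_factor_log_normalize(adata)
    cell_scores = gsva_scores(expr, modules, tau=tau)
    labels = labels.reindex(cell_scores.index)
    means = cell_scores.groupby(labels, observed=True).mean().T  # module x SC
    return MetaModuleScores(
        cell_scores=cell_scores,
        subcluster_means=means,
        z=zscore_across_columns(means),
    )
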