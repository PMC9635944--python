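"""Preranked gene-set enrichment on a variance-ranked gene list.

Genes are ranked by their standardized variance across cells; the normalized
enrichment score (NES) of a gene set on that ranking quantifies how
concentrated the set is among the most variable genes, i.e. the degree of
expression heterogeneity of the pathway.

The enrichment score is the classic weighted Kolmogorov-Smirnov running sum:
walking down the ranking, a gene in the set ("hit") increments the sum by
|score|^p normalized by the sum of |score|^p over set members, and a gene
outside the set ("miss") decrements it by 1/(N - |S|).  ES is the deviation
of maximum magnitude (signed).  Significance comes from gene-label
permutations: null ES values for random sets of the same size, with

    NES        = ES / mean(|null ES| of the same sign)
    nominal p  = (1 + #{null as or more extreme, same sign})
                 / (1 + #{null of same sign})

so p is never exactly zero.  FDR across sets is Benjamini-Hochberg.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from ._utils import bh_fdr
from .genesets import GeneSetCollection

__all__ = ["enrichment_score", "gsea_preranked"]


def _hit_weights(scores: np.ndarray, hit_pos: np.ndarray, weight: float) -> np.ndarray:
    """Normalized hit increments |score|^p / sum over hits.

    Falls back to equal weights when every hit score is zero (the p=0
    behaviour), so the running sum remains well defined.
    """
    w = np.abs(scores[..., :])  # ranked |scores|
    if weight == 0:
        inc = np.ones(hit_pos.shape)
    else:
        inc = np.take(w, hit_pos) ** weight
    tot = inc.sum(axis=-1, keepdims=True)
    if np.any(tot == 0):
        inc = np.where(tot == 0, 1.0, inc)
        tot = inc.sum(axis=-1, keepdims=True)
    return inc / tot


def _es_from_positions(
    scores: np.ndarray, hit_pos: np.ndarray, weight: float
) -> np.ndarray:
    """Vectorized ES for one or many hit-position vectors of equal size.

    ``hit_pos`` has shape (..., s) with 0-based positions into the ranking,
    sorted ascending along the last axis.  Uses the fact that the running
    sum is piecewise linear, so its extrema occur immediately before or
    after a hit.
    """
    n = scores.shape[-1]
    s = hit_pos.shape[-1]
    if s == 0 or s >= n:
        raise ValueError("gene set must be a non-empty strict subset of the ranking")
    miss_dec = 1.0 / (n - s)
    inc = _hit_weights(scores, hit_pos, weight)
    cumw = np.cumsum(inc, axis=-1)
    k = np.arange(s)
    drop = (hit_pos - k) * miss_dec  # misses accumulated before each hit
    after = cumw - drop
    before = after - inc
    max_dev = after.max(axis=-1)
    min_dev = np.minimum(before.min(axis=-1), 0.0)
    # signed maximum-magnitude deviation; exact magnitude ties (within float
    # noise) break toward the positive deviation
    return np.where(max_dev + 1e-12 >= -min_dev, max_dev, min_dev)


def enrichment_score(
    ranked: pd.DataFrame, gene_set, weight: float = 1.0
) -> float:
    """ES of ``gene_set`` on a ranked list.

    ``ranked`` is a DataFrame with columns ``gene`` and ``score`` sorted in
    descending score order.  Raises ``ValueError`` when the set is empty
    after restriction to the ranking, or covers the whole ranking.
    """
    genes = ranked["gene"].to_numpy()
    scores = ranked["score"].to_numpy(dtype=float)
    members = set(gene_set)
    hit_pos = np.flatnonzero(np.fromiter((g in members for g in genes), bool, len(genes)))
    if hit_pos.size == 0:
        raise ValueError("gene set shares no genes with the ranking")
    if hit_pos.size == len(genes):
        raise ValueError("gene set covers the entire ranking")
    return float(_es_from_positions(scores, hit_pos, weight))


def gsea_preranked(
    ranked: pd.DataFrame,
    sets: GeneSetCollection,
    n_perm: int = 10_000,
    weight: float = 1.0,
    min_size: int = 5,
    seed: int | None = None,
) -> pd.DataFrame:
    """Permutation preranked enrichment for a collection of gene sets.

    Returns a DataFrame indexed by set name with columns ``es``, ``nes``,
    ``pval``, ``fdr`` and ``size`` (set size after restriction to the
    ranking).  Sets smaller than ``min_size`` after restriction are skipped
    with a warning.  Null distributions are built from ``n_perm`` random
    same-size gene subsets and shared between sets of equal size; results
    are deterministic given ``seed``.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be at least 100")
    genes = ranked["gene"].to_numpy()
    scores = ranked["score"].to_numpy(dtype=float)
    n = len(genes)
    index = {g: i for i, g in enumerate(genes)}
    rng = np.random.default_rng(seed)

    restricted: dict[str, np.ndarray] = {}
    for name, members in sets:
        pos = np.sort(np.fromiter(
            (index[g] for g in members if g in index), dtype=int))
        if pos.size < min_size:
            warnings.warn(
                f"set {name!r} has {pos.size} genes in the ranking "
                f"(< {min_size}); skipped", stacklevel=2)
            continue
        if pos.size == n:
            warnings.warn(f"set {name!r} covers the whole ranking; skipped",
                          stacklevel=2)
            continue
        restricted[name] = pos

    null_by_size: dict[int, np.ndarray] = {}
    chunk = max(1, int(2**22 // max(n, 1)))  # bound scratch memory
    for size in sorted({p.size for p in restricted.values()}):
        null = np.empty(n_perm)
        done = 0
        while done < n_perm:
            m = min(chunk, n_perm - done)
            # m random size-subsets of the ranking, rows sorted
            perm = np.argpartition(rng.random((m, n)), size - 1, axis=1)[:, :size]
            perm.sort(axis=1)
            null[done:done + m] = _es_from_positions(scores, perm, weight)
            done += m
        null_by_size[size] = null

    rows = []
    for name, pos in restricted.items():
        es = float(_es_from_positions(scores, pos, weight))
        null = null_by_size[pos.size]
        if es >= 0:
            same = null[null >= 0]
            extreme = int((same >= es).sum())
        else:
            same = null[null < 0]
            extreme = int((same <= es).sum())
        pval = (1 + extreme) / (1 + same.size)
        if same.size == 0:
            warnings.warn(f"no same-sign null ES for set {name!r}; NES undefined",
                          stacklevel=2)
            nes = np.nan
        else:
            nes = es / np.abs(same).mean()
        rows.append((name, es, nes, pval, pos.size))

    res = pd.DataFrame(rows, columns=["set", "es", "nes", "pval", "size"])
    res = res.set_index("set")
    res["fdr"] = bh_fdr(res["pval"].to_numpy())
    return res[["es", "nes", "pval", "fdr", "size"]]
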