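"""Cluster marker tests: Wilcoxon rank-sum and a two-part hurdle test.

For every gene, a cluster is compared against all other cells with

* a two-sided Wilcoxon rank-sum (Mann-Whitney U) test on log-normalized
  expression (exact p for small tie-free samples, normal approximation
  otherwise);
* a two-part hurdle test for zero-inflated expression: a likelihood-ratio
  test on the detection rate (fraction of cells expressing the gene,
  binomial, 1 df) combined with a Welch t test on log expression among
  expressing cells (t^2 treated as chi-square with 1 df), summed into a
  single chi-square statistic with summed degrees of freedom;
* a linear fold change on CP100k means with a pseudocount of 1:
  (mean_in + 1) / (mean_out + 1).

p-values are Benjamini-Hochberg adjusted across genes, separately per test.
Genes expressed in neither group get p = 1 by convention.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import scipy.stats as st

from ._utils import bh_fdr

__all__ = ["de_markers", "hurdle_test"]


def _binom_ll(k, n, p):
    from scipy.special import xlogy

    return xlogy(k, p) + xlogy(n - k, 1 - p)


def hurdle_test(x: np.ndarray, y: np.ndarray) -> tuple[float, float, int]:
    """Two-part hurdle test for one gene.

    ``x`` and ``y`` are log-normalized expression vectors for the two groups
    (zeros = not detected).  Returns ``(p, chi2, df)``.  Components that are
    undefined (no detection difference possible, or fewer than two expressing
    cells in a group) are dropped, reducing the degrees of freedom; with no
    usable component p = 1.
    """
    n1, n2 = len(x), len(y)
    k1, k2 = int((x > 0).sum()), int((y > 0).sum())
    chi2 = 0.0
    df = 0
    ktot, ntot = k1 + k2, n1 + n2
    if 0 < ktot < ntot:
        p0 = ktot / ntot
        ll0 = _binom_ll(k1, n1, p0) + _binom_ll(k2, n2, p0)
        ll1 = _binom_ll(k1, n1, k1 / n1) + _binom_ll(k2, n2, k2 / n2)
        chi2 += 2.0 * (ll1 - ll0)
        df += 1
    xe, ye = x[x > 0], y[y > 0]
    if len(xe) >= 2 and len(ye) >= 2 and (xe.var(ddof=1) > 0 or ye.var(ddof=1) > 0):
        t, _ = st.ttest_ind(xe, ye, equal_var=False)
        if np.isfinite(t):
            chi2 += float(t) ** 2
            df += 1
    if df == 0:
        return 1.0, 0.0, 0
    return float(st.chi2.sf(chi2, df)), chi2, df


def de_markers(
    cp100k: pd.DataFrame,
    labels: pd.Series,
    cluster,
) -> pd.DataFrame:
    """Marker table for one cluster versus all other cells.

    ``cp100k`` is the cell x gene CP100k matrix; ``labels`` maps cells to
    cluster IDs.  Returns a DataFrame indexed by gene with columns
    ``fold_change``, ``p_wilcoxon``, ``p_hurdle``, ``fdr_wilcoxon`` and
    ``fdr_hurdle``.
    """
    labels = labels.reindex(cp100k.index)
    in_mask = (labels == cluster).to_numpy()
    n_in, n_out = int(in_mask.sum()), int((~in_mask).sum())
    if n_in < 2:
        raise ValueError(f"cluster {cluster!r} has fewer than 2 cells")
    if n_out == 0:
        raise ValueError("out-group is empty")

    M = cp100k.to_numpy(dtype=float)
    logM = np.log1p(M)
    Xin, Xout = logM[in_mask], logM[~in_mask]

    mean_in = M[in_mask].mean(axis=0)
    mean_out = M[~in_mask].mean(axis=0)
    fold = (mean_in + 1.0) / (mean_out + 1.0)

    n_genes = M.shape[1]
    p_wil = np.ones(n_genes)
    p_hur = np.ones(n_genes)
    expressed = (M > 0).any(axis=0)
    for j in np.flatnonzero(expressed):
        a, b = Xin[:, j], Xout[:, j]
        if np.ptp(np.concatenate([a, b])) == 0:
            p_wil[j] = 1.0
        else:
            p_wil[j] = st.mannwhitneyu(a, b, alternative="two-sided").pvalue
        p_hur[j], _, _ = hurdle_test(a, b)

    out = pd.DataFrame(
        {
            "fold_change": fold,
            "p_wilcoxon": p_wil,
            "p_hurdle": p_hur,
            "fdr_wilcoxon": bh_fdr(p_wil),
            "fdr_hurdle": bh_fdr(p_hur),
        },
        index=cp100k.columns,
    )
    return out
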