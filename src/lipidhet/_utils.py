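"""Small shared helpers."""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp


def to_dense(X) -> np.ndarray:
    """Densify an AnnData .X-like array (sparse or ndarray) to float64."""
    if sp.issparse(X):
        X = X.toarray()
    return np.asarray(X, dtype=np.float64)


def bh_fdr(pvals: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (NaNs passed through)."""
    from statsmodels.stats.multitest import multipletests

    p = np.asarray(pvals, dtype=float)
    out = np.full_like(p, np.nan)
    ok = np.isfinite(p)
    if ok.any():
        out[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return out
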