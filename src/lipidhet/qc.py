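"""Per-cell quality control and CP100k normalization.

Cells are kept when they satisfy all of: library size (nUMI) at or above a
minimum, detected-gene count (nGene) within a window, and percent of counts on
mitochondrial genes at or below a ceiling.  The removal rules are strict
inequalities (a cell is removed when nUMI < min_umi, nGene < min_genes,
nGene > max_genes or pct_mito > max_pct_mito), so the kept side is inclusive
at every boundary.

Normalization is counts-per-100k (CP100k): each cell's gene counts divided by
the cell's total UMI count and scaled by 1e5.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from anndata import AnnData

from ._utils import to_dense

__all__ = [
    "QCThresholds",
    "compute_cell_qc",
    "qc_filter_cells",
    "normalize_cp100k",
    "log_normalize",
]

CP100K_SCALE = 1e5


@dataclass(frozen=True)
class QCThresholds:
    """Cell-filtering thresholds.

    Defaults correspond to removing cells with < 401 UMIs, < 200 or > 6000
    expressed genes, or > 20% of counts on mitochondrial genes.
    """

    min_umi: int = 401
    min_genes: int = 200
    max_genes: int = 6000
    max_pct_mito: float = 20.0

    def __post_init__(self) -> None:
        if self.min_umi <= 0 or self.min_genes <= 0 or self.max_genes <= 0:
            raise ValueError("QC thresholds must be positive")
        if self.min_genes >= self.max_genes:
            raise ValueError("min_genes must be below max_genes")


def compute_cell_qc(adata: AnnData, mito_col: str = "mito") -> pd.DataFrame:
    """Per-cell QC metrics: nUMI, nGene and pct_mito (0-100).

    ``pct_mito`` is computed on raw counts, using the boolean ``mito_col``
    column of ``adata.var`` when present; otherwise it is NaN.
    """
    X = to_dense(adata.X)
    n_umi = X.sum(axis=1)
    n_gene = (X > 0).sum(axis=1)
    qc = pd.DataFrame(
        {"nUMI": n_umi, "nGene": n_gene},
        index=adata.obs_names,
    )
    if mito_col in adata.var:
        mito = np.asarray(adata.var[mito_col], dtype=bool)
        mito_counts = X[:, mito].sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            qc["pct_mito"] = np.where(n_umi > 0, 100.0 * mito_counts / n_umi, 0.0)
    else:
        qc["pct_mito"] = np.nan
    return qc


def qc_filter_cells(
    adata: AnnData,
    thresholds: QCThresholds | None = None,
    mito_col: str = "mito",
) -> tuple[AnnData, pd.DataFrame, pd.DataFrame]:
    """Filter cells by QC thresholds.

    Returns ``(filtered, qc_table, removal_log)``.  The removal log has one
    row per removed cell with the first rule that removed it
    (``low_umi`` / ``low_genes`` / ``high_genes`` / ``high_mito``).

    Raises ``ValueError`` on an empty matrix, or when the mitochondrial rule
    is active but no mito flags are available.  Emits a warning (and returns
    an empty AnnData) when no cell survives.
    """
    if adata.n_obs == 0 or adata.n_vars == 0:
        raise ValueError("cannot QC-filter an empty count matrix")
    thresholds = thresholds or QCThresholds()
    qc = compute_cell_qc(adata, mito_col=mito_col)
    mito_active = np.isfinite(thresholds.max_pct_mito)
    if mito_active and qc["pct_mito"].isna().any():
        raise ValueError(
            "mitochondrial filter is active but adata.var has no "
            f"boolean {mito_col!r} column"
        )

    reasons = pd.Series("", index=adata.obs_names, dtype=object)
    reasons[qc["nUMI"] < thresholds.min_umi] = "low_umi"
    mask = reasons == ""
    reasons[mask & (qc["nGene"] < thresholds.min_genes)] = "low_genes"
    mask = reasons == ""
    reasons[mask & (qc["nGene"] > thresholds.max_genes)] = "high_genes"
    if mito_active:
        mask = reasons == ""
        reasons[mask & (qc["pct_mito"] > thresholds.max_pct_mito)] = "high_mito"

    keep = reasons == ""
    removal_log = pd.DataFrame(
        {"cell": reasons.index[~keep], "reason": reasons[~keep].to_numpy()}
    ).reset_index(drop=True)
    if not keep.any():
        warnings.warn("QC filtering removed every cell", stacklevel=2)
    filtered = adata[keep.to_numpy()].copy()
    return filtered, qc, removal_log


def normalize_cp100k(adata: AnnData, layer: str | None = None) -> pd.DataFrame:
    """CP100k normalization: counts / cell total * 1e5.

    Returns a cell x gene DataFrame whose rows each sum to 100,000.
    Raises ``ValueError`` naming the first offending cell if any cell has a
    zero total count.
    """
    X = to_dense(adata.layers[layer] if layer else adata.X)
    totals = X.sum(axis=1)
    if np.any(totals <= 0):
        bad = adata.obs_names[int(np.argmax(totals <= 0))]
        raise ValueError(f"cell {bad!r} has zero total counts; cannot normalize")
    norm = X / totals[:, None] * CP100K_SCALE
    return pd.DataFrame(norm, index=adata.obs_names, columns=adata.var_names)


def log_normalize(cp100k: pd.DataFrame) -> pd.DataFrame:
    """Natural-log transform ln(1 + CP100k) of a normalized matrix."""
    return np.log1p(cp100k)
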