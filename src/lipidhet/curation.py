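"""Resolution selection and sub-cluster curation.

A candidate clustering passes the marker constraint when every one of its
clusters has at least ``min_markers`` genes that are significant under both
the Wilcoxon and hurdle tests (FDR below ``fdr``) with a fold change of at
least ``min_fold``.  Among passing candidates the one with the largest
resolution is selected — maximal granularity under the objective rule.

Curation then removes, in order and with a logged reason:

1. singleton/tiny clusters (fewer than ``min_cells`` cells);
2. patient-specific clusters: the top patient contributes strictly more than
   ``single_patient_frac`` of cells, or the top two patients together
   contribute at least ``two_patient_frac``;
3. low-quality clusters: median nUMI AND median nGene both below
   ``lowq_frac`` times the corresponding median over the cells of all other
   surviving clusters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import pandas as pd

from .markers import de_markers

__all__ = [
    "Labeling",
    "CurationParams",
    "NoPassingResolution",
    "count_qualifying_markers",
    "select_resolution",
    "curate_subclusters",
]


@dataclass
class Labeling:
    """A candidate clustering at one resolution: cell -> cluster ID."""

    resolution: float
    clusters: pd.Series

    def cluster_ids(self) -> list:
        return sorted(self.clusters.unique())


@dataclass(frozen=True)
class CurationParams:
    min_cells: int = 2
    single_patient_frac: float = 0.75
    two_patient_frac: float = 0.85
    lowq_frac: float = 0.5


class NoPassingResolution(RuntimeError):
    """No candidate labeling satisfied the marker constraint."""

    def __init__(self, audit: pd.DataFrame):
        super().__init__("no candidate resolution passed the marker constraint")
        self.audit = audit


def count_qualifying_markers(
    marker_table: pd.DataFrame, fdr: float = 0.01, min_fold: float = 2.0
) -> int:
    ok = (
        (marker_table["fdr_wilcoxon"] < fdr)
        & (marker_table["fdr_hurdle"] < fdr)
        & (marker_table["fold_change"] >= min_fold)
    )
    return int(ok.sum())


def select_resolution(
    cp100k: pd.DataFrame,
    candidates: list[Labeling],
    min_markers: int = 10,
    fdr: float = 0.01,
    min_fold: float = 2.0,
) -> tuple[Labeling, pd.DataFrame]:
    """Choose the largest-resolution candidate passing the marker rule.

    Returns ``(chosen, audit)`` where the audit lists, per candidate and
    cluster, the qualifying-marker count.  Raises :class:`NoPassingResolution`
    (carrying the audit) when nothing passes.
    """
    if not candidates:
        raise ValueError("at least one candidate labeling is required")
    rows = []
    passing: list[Labeling] = []
    for cand in candidates:
        all_ok = True
        for cl in cand.cluster_ids():
            table = de_markers(cp100k, cand.clusters, cl)
            n_ok = count_qualifying_markers(table, fdr=fdr, min_fold=min_fold)
            rows.append((cand.resolution, cl, n_ok, n_ok >= min_markers))
            all_ok &= n_ok >= min_markers
        if all_ok:
            passing.append(cand)
    audit = pd.DataFrame(rows, columns=["resolution", "cluster", "n_markers", "pass"])
    if not passing:
        raise NoPassingResolution(audit)
    chosen = max(passing, key=lambda c: c.resolution)
    return chosen, audit


def curate_subclusters(
    labels: pd.Series,
    patients: pd.Series,
    cell_qc: pd.DataFrame,
    params: CurationParams | None = None,
) -> tuple[list, pd.DataFrame]:
    """Apply the sub-cluster removal rules.

    ``labels`` maps cells to sub-cluster IDs, ``patients`` maps cells to
    patient IDs, and ``cell_qc`` provides per-cell ``nUMI`` and ``nGene``.
    Returns ``(retained_cluster_ids, removal_log)``; the log has columns
    ``cluster`` and ``reason`` (``singleton`` / ``patient_specific`` /
    ``low_quality``).  Warns when every cluster is removed.
    """
    params = params or CurationParams()
    patients = patients.reindex(labels.index)
    cell_qc = cell_qc.reindex(labels.index)
    removed: list[tuple] = []
    surviving = sorted(labels.unique())

    keep = []
    for cl in surviving:
        n = int((labels == cl).sum())
        if n < params.min_cells:
            removed.append((cl, "singleton"))
        else:
            keep.append(cl)
    surviving = keep

    keep = []
    for cl in surviving:
        shares = (
            patients[labels == cl].value_counts(normalize=True).sort_values(
                ascending=False
            )
        )
        top1 = float(shares.iloc[0])
        top2 = float(shares.iloc[:2].sum())
        if top1 > params.single_patient_frac or top2 >= params.two_patient_frac:
            removed.append((cl, "patient_specific"))
        else:
            keep.append(cl)
    surviving = keep

    # low-quality: compare each cluster against cells of all other survivors
    keep = []
    for cl in surviving:
        others = labels.isin([c for c in surviving if c != cl])
        if not others.any():
            keep.append(cl)
            continue
        in_cl = labels == cl
        med_umi = cell_qc.loc[in_cl, "nUMI"].median()
        med_gene = cell_qc.loc[in_cl, "nGene"].median()
        out_umi = cell_qc.loc[others, "nUMI"].median()
        out_gene = cell_qc.loc[others, "nGene"].median()
        if med_umi < params.lowq_frac * out_umi and med_gene < params.lowq_frac * out_gene:
            removed.append((cl, "low_quality"))
        else:
            keep.append(cl)
    surviving = keep

    if not surviving:
        warnings.warn("curation removed every sub-cluster", stacklevel=2)
    log = pd.DataFrame(removed, columns=["cluster", "reason"])
    return surviving, log
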