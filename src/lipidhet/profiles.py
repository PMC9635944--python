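"""Sub-cluster expression Z-scores and fatty-acid program classification.

For each gene g and sub-cluster SC the mean CP100k expression E[g,SC] is
converted to a Z-score across sub-clusters:

    Z[g,SC] = (E[g,SC] - mean_SC(E[g])) / sd_SC(E[g])

with the sample (n-1) standard deviation over sub-clusters.  Programs are
called from the Z-scores of SCD, FADS2 and FASN: a gene is "high" in a
sub-cluster when Z >= tau and "low" when Z <= -tau; all three high gives
Triple-Hi, all three low Triple-low, exactly one high "<gene>-Hi", several
(but not all) high a composite label such as "SCD+FASN-Hi", and none high
Unclassified.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "SubclusterZProfile",
    "cluster_mean_zscores",
    "classify_fa_programs",
    "zscore_across_columns",
    "FA_GENES",
]

FA_GENES = ("SCD", "FADS2", "FASN")


@dataclass
class SubclusterZProfile:
    """Mean expression and Z-scores per (gene, sub-cluster)."""

    mean_expression: pd.DataFrame  # gene x subcluster
    z: pd.DataFrame  # gene x subcluster


def zscore_across_columns(means: pd.DataFrame) -> pd.DataFrame:
    """Row-wise Z-scores across columns with the sample (n-1) sd.

    Rows with zero sd get Z = 0 with a warning.
    """
    if means.shape[1] < 2:
        raise ValueError("Z-scores require at least 2 sub-clusters")
    mu = means.mean(axis=1)
    sd = means.std(axis=1, ddof=1)
    flat = sd == 0
    if flat.any():
        warnings.warn(
            f"{int(flat.sum())} row(s) have identical means across sub-clusters; "
            "Z set to 0", stacklevel=2)
    z = means.sub(mu, axis=0).div(sd.where(~flat, np.inf), axis=0)
    return z


def cluster_mean_zscores(
    cp100k: pd.DataFrame,
    labels: pd.Series,
    genes=FA_GENES,
) -> SubclusterZProfile:
    """Per-gene sub-cluster mean CP100k expression and Z-scores.

    ``cp100k`` is cell x gene; ``labels`` maps cells to sub-cluster IDs.
    """
    missing = [g for g in genes if g not in cp100k.columns]
    if missing:
        raise KeyError(f"genes not in the expression matrix: {missing}")
    labels = labels.reindex(cp100k.index)
    means = (
        cp100k[list(genes)]
        .groupby(labels, observed=True)
        .mean()
        .T  # gene x subcluster
    )
    return SubclusterZProfile(mean_expression=means, z=zscore_across_columns(means))


def classify_fa_programs(
    profile: SubclusterZProfile,
    tau: float = 0.5,
    genes=FA_GENES,
) -> dict:
    """Map each sub-cluster to a fatty-acid program label."""
    z = profile.z.loc[list(genes)]
    labels = {}
    for sc in z.columns:
        high = [g for g in genes if z.loc[g, sc] >= tau]
        low = [g for g in genes if z.loc[g, sc] <= -tau]
        if len(high) == len(genes):
            labels[sc] = "Triple-Hi"
        elif len(low) == len(genes):
            labels[sc] = "Triple-low"
        elif len(high) == 1:
            labels[sc] = f"{high[0]}-Hi"
        elif high:
            labels[sc] = "+".join(high) + "-Hi"
        else:
            labels[sc] = "Unclassified"
    return labels
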