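"""Cell Death Index from live-imaging time series.

The index at a timepoint is the number of dead (Sytox-positive) cells in a
well divided by the well's phase confluence (percent, 0-100] at the same
timepoint.  It scales linearly with the dead count at fixed confluence and
inversely with confluence at a fixed count.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["cell_death_index", "summarize_conditions"]

REQUIRED_COLUMNS = ("well", "condition", "hours", "dead_count", "confluence")


def cell_death_index(series: pd.DataFrame) -> pd.DataFrame:
    """Add a ``death_index`` column to a tidy assay table.

    ``series`` needs columns well, condition, hours, dead_count and
    confluence.  Timepoints with confluence <= 0 get a missing (NaN) index
    rather than a fabricated value.  Hours must be strictly increasing
    within each well.
    """
    missing = [c for c in REQUIRED_COLUMNS if c not in series.columns]
    if missing:
        raise ValueError(f"assay table is missing columns: {missing}")
    if (series["dead_count"] < 0).any():
        raise ValueError("dead-cell counts must be non-negative")
    for well, grp in series.groupby("well"):
        hours = grp["hours"].to_numpy()
        if np.any(np.diff(hours) <= 0):
            raise ValueError(f"hours are not strictly increasing in well {well!r}")
    out = series.copy()
    conf = out["confluence"]
    out["death_index"] = np.where(conf > 0, out["dead_count"] / conf, np.nan)
    return out


def summarize_conditions(indexed: pd.DataFrame) -> pd.DataFrame:
    """Mean and sd of the death index across replicate wells.

    Aggregates wells of the same condition at matching timepoints; returns a
    tidy frame (condition, hours, mean_index, sd_index, n_wells).
    """
    if "death_index" not in indexed.columns:
        indexed = cell_death_index(indexed)
    grp = indexed.groupby(["condition", "hours"])["death_index"]
    out = grp.agg(mean_index="mean", sd_index="std", n_wells="count").reset_index()
    return out
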