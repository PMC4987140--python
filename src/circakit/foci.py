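"""Per-cell nuclear-foci (paraspeckle) count summaries and ANOVA.

Counts arrive as one row per imaged cell (well, time point after the
medium change, number of foci).  Two summaries mirror the two reported
readouts: the total number of foci per well, and the mean number of
foci per focus-positive cell (cells with zero foci are excluded from
the mean but contribute to well totals).  Time-of-day differences are
tested by ordinary one-way ANOVA.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "FOCI_COLUMNS",
    "FociSummary",
    "AnovaResult",
    "summarize_foci",
    "one_way_anova",
    "anova_well_totals",
    "anova_cell_counts",
]

FOCI_COLUMNS = ("cell_id", "well_id", "time_point", "n_foci")


@dataclass(frozen=True)
class FociSummary:
    """Per-well totals and positive-cell means, plus per-time aggregates."""

    well_totals: pd.DataFrame      # time_point, well_id, total_foci, n_cells,
                                   # n_positive, positive_cell_mean (NaN if none)
    per_time: pd.DataFrame         # time_point, total_foci, positive_cell_mean,
                                   # n_positive
    all_zero_wells: tuple[str, ...]


@dataclass(frozen=True)
class AnovaResult:
    f_statistic: float
    df_between: int
    df_within: int
    p_value: float
    flagged: str | None = None


def _validate(table: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in FOCI_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"foci table is missing columns {missing}")
    if table.empty:
        raise ValueError("empty foci table")
    n = pd.to_numeric(table["n_foci"], errors="raise")
    if (n < 0).any() or not np.allclose(n, n.astype(int)):
        raise ValueError("n_foci must be non-negative integers")
    dup = table.duplicated(subset=["cell_id"])
    if dup.any():
        raise ValueError(f"cells assigned twice: {table.loc[dup, 'cell_id'].tolist()}")
    return table.assign(n_foci=n.astype(int))


def summarize_foci(table: pd.DataFrame) -> FociSummary:
    """Per-well foci totals and mean foci per focus-positive cell."""
    table = _validate(table)
    rows = []
    zero_wells = []
    for (tp, well), grp in table.groupby(["time_point", "well_id"], sort=True):
        positive = grp.loc[grp["n_foci"] > 0, "n_foci"]
        total = int(grp["n_foci"].sum())
        if positive.empty:
            zero_wells.append(str(well))
        rows.append({
            "time_point": tp,
            "well_id": well,
            "total_foci": total,
            "n_cells": len(grp),
            "n_positive": len(positive),
            "positive_cell_mean": positive.mean() if len(positive) else np.nan,
        })
    wells = pd.DataFrame(rows)
    per_time_rows = []
    for tp, grp in table.groupby("time_point", sort=True):
        positive = grp.loc[grp["n_foci"] > 0, "n_foci"]
        per_time_rows.append({
            "time_point": tp,
            "total_foci": int(grp["n_foci"].sum()),
            "positive_cell_mean": positive.mean() if len(positive) else np.nan,
            "n_positive": len(positive),
        })
    return FociSummary(
        well_totals=wells,
        per_time=pd.DataFrame(per_time_rows),
        all_zero_wells=tuple(zero_wells),
    )


def one_way_anova(groups: Sequence[Sequence[float]]) -> AnovaResult:
    """Ordinary one-way ANOVA: F = MS_between / MS_within.

    Requires at least two groups with at least two values each.  If all
    values are identical the F statistic is undefined and the result is
    flagged instead of raising.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise ValueError("need at least two groups")
    if any(a.size < 2 for a in arrays):
        raise ValueError("every group needs at least two values")
    n_total = sum(a.size for a in arrays)
    k = len(arrays)
    if n_total <= k:
        raise ValueError("total sample size must exceed the number of groups")
    pooled = np.concatenate(arrays)
    if np.ptp(pooled) == 0:
        return AnovaResult(f_statistic=float("nan"), df_between=k - 1,
                           df_within=n_total - k, p_value=float("nan"),
                           flagged="degenerate_variance")
    f_stat, p = stats.f_oneway(*arrays)
    return AnovaResult(f_statistic=float(f_stat), df_between=k - 1,
                       df_within=n_total - k, p_value=float(p))


def anova_well_totals(summary: FociSummary) -> AnovaResult:
    """ANOVA of per-well total foci counts grouped by time point."""
    groups = [grp["total_foci"].to_numpy(dtype=float)
              for _, grp in summary.well_totals.groupby("time_point")]
    return one_way_anova(groups)


def anova_cell_counts(table: pd.DataFrame) -> AnovaResult:
    """ANOVA of per-cell foci counts grouped by time point."""
    table = _validate(table)
    groups = [grp["n_foci"].to_numpy(dtype=float)
              for _, grp in table.groupby("time_point")]
    return one_way_anova(groups)
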