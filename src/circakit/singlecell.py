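"""Single-cell fluorescence trace QC, classification and line comparison.

Time-lapse recordings (96 h, one frame every 30 min) yield one
fluorescence track per cell plus a per-field background level.  A cell
enters the analysis only if it was tracked for at least 48 h and its
mean fluorescence is at least 10% above background (both bounds
inclusive).  Retained cells are classified by the damped cosinor fit
with the period fixed at 24 h, and the percent of rhythmic cells is
compared between cell lines.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cosinor import RhythmConfig, RhythmicityCall, TimeSeries, classify_rhythmic

__all__ = [
    "CellTrace",
    "QCResult",
    "LineSummary",
    "LineComparison",
    "qc_trace",
    "classify_cells",
    "compare_lines",
]

FRAME_SPACING_H = 0.5
MIN_TRACKED_HOURS = 48.0
BACKGROUND_FACTOR = 1.10


@dataclass(frozen=True)
class CellTrace:
    """One cell's fluorescence track at fixed 0.5-h frame spacing."""

    cell_id: str
    line_id: str
    frame_times: np.ndarray
    fluorescence: np.ndarray
    background_mean: float | None

    def __post_init__(self) -> None:
        t = np.asarray(self.frame_times, dtype=float).ravel()
        f = np.asarray(self.fluorescence, dtype=float).ravel()
        if t.size != f.size:
            raise ValueError(f"{self.cell_id}: frame/fluorescence length mismatch")
        if t.size < 2:
            raise ValueError(f"{self.cell_id}: need at least 2 frames")
        spacing = np.diff(t)
        if not np.allclose(spacing, FRAME_SPACING_H, rtol=0.0, atol=1e-6):
            raise ValueError(
                f"{self.cell_id}: frame spacing must be constant at "
                f"{FRAME_SPACING_H} h"
            )
        if np.any(f < 0):
            raise ValueError(f"{self.cell_id}: negative fluorescence")
        if self.background_mean is not None and not (
            np.isfinite(self.background_mean) and self.background_mean > 0
        ):
            raise ValueError(f"{self.cell_id}: background_mean must be positive")
        object.__setattr__(self, "frame_times", t)
        object.__setattr__(self, "fluorescence", f)

    @property
    def tracked_hours(self) -> float:
        return float(self.frame_times[-1] - self.frame_times[0])

    @property
    def mean_fluorescence(self) -> float:
        return float(self.fluorescence.mean())


@dataclass(frozen=True)
class QCResult:
    cell_id: str
    retained: bool
    reasons: tuple[str, ...]
    tracked_hours: float
    mean_fluorescence: float
    background_mean: float | None


@dataclass(frozen=True)
class LineSummary:
    """Per-line retention and rhythmicity counts."""

    line_id: str
    n_retained: int
    n_rhythmic: int

    @property
    def percent_rhythmic(self) -> float:
        if self.n_retained == 0:
            return float("nan")
        return 100.0 * self.n_rhythmic / self.n_retained

    @property
    def empty(self) -> bool:
        return self.n_retained == 0


@dataclass(frozen=True)
class LineComparison:
    line_a: str
    line_b: str
    statistic: float
    p_value: float
    method: str


def qc_trace(
    trace: CellTrace,
    min_hours: float = MIN_TRACKED_HOURS,
    background_factor: float = BACKGROUND_FACTOR,
) -> QCResult:
    """Trace retention rule: tracked >= ``min_hours`` AND mean
    fluorescence >= ``background_factor`` x background (both inclusive).

    A trace with no background measurement is rejected with reason
    ``missing_background``.
    """
    def below(value: float, bound: float) -> bool:
        # inclusive bounds: equality (to fp tolerance) passes
        return value < bound and not math.isclose(value, bound, rel_tol=1e-12)

    reasons: list[str] = []
    if trace.background_mean is None:
        reasons.append("missing_background")
    if below(trace.tracked_hours, min_hours):
        reasons.append("duration")
    if trace.background_mean is not None and below(
        trace.mean_fluorescence, background_factor * trace.background_mean
    ):
        reasons.append("brightness")
    return QCResult(
        cell_id=trace.cell_id,
        retained=not reasons,
        reasons=tuple(reasons),
        tracked_hours=trace.tracked_hours,
        mean_fluorescence=trace.mean_fluorescence,
        background_mean=trace.background_mean,
    )


def _trace_to_series(trace: CellTrace) -> TimeSeries:
    return TimeSeries.build(trace.frame_times, trace.fluorescence,
                            series_id=trace.cell_id)


def classify_cells(
    traces: Iterable[CellTrace],
    config: RhythmConfig | None = None,
    min_hours: float = MIN_TRACKED_HOURS,
    background_factor: float = BACKGROUND_FACTOR,
) -> tuple[pd.DataFrame, dict[str, LineSummary]]:
    """QC every trace, fit retained cells, and summarise per line.

    Returns a per-cell table (one row per input trace: QC outcome, fit
    R^2, rhythmic flag, reason) and a ``LineSummary`` per line.  Fit
    failures on retained traces count as non-rhythmic with a reason.
    """
    cfg = config or RhythmConfig(fit_replicate_means=False)
    rows: list[dict] = []
    counts: dict[str, list[int]] = {}
    for trace in traces:
        qc = qc_trace(trace, min_hours=min_hours,
                      background_factor=background_factor)
        row = {
            "cell_id": trace.cell_id,
            "line_id": trace.line_id,
            "retained": qc.retained,
            "qc_reasons": "+".join(qc.reasons),
            "tracked_hours": qc.tracked_hours,
            "mean_fluorescence": qc.mean_fluorescence,
            "rhythmic": False,
            "r_squared": np.nan,
            "reason": "",
        }
        counts.setdefault(trace.line_id, [0, 0])
        if qc.retained:
            call = classify_rhythmic(_trace_to_series(trace), cfg)
            row["rhythmic"] = call.rhythmic
            row["r_squared"] = call.fit.r_squared if call.fit else np.nan
            row["reason"] = call.reason or ""
            counts[trace.line_id][0] += 1
            counts[trace.line_id][1] += int(call.rhythmic)
        else:
            row["reason"] = "qc:" + "+".join(qc.reasons)
        rows.append(row)
    summaries = {
        line: LineSummary(line_id=line, n_retained=c[0], n_rhythmic=c[1])
        for line, c in counts.items()
    }
    return pd.DataFrame(rows), summaries


def compare_lines(a: LineSummary, b: LineSummary,
                  method: str = "fisher") -> LineComparison:
    """Two-sided comparison of percent-rhythmic between two lines.

    Default is Fisher's exact test on the pooled 2x2 table of
    (rhythmic, non-rhythmic) counts.
    """
    if a.n_retained < 1 or b.n_retained < 1:
        raise ValueError("both lines need at least one retained cell")
    if method != "fisher":
        raise ValueError(f"unknown method {method!r}")
    table = [
        [a.n_rhythmic, a.n_retained - a.n_rhythmic],
        [b.n_rhythmic, b.n_retained - b.n_rhythmic],
    ]
    odds, p = stats.fisher_exact(table, alternative="two-sided")
    return LineComparison(line_a=a.line_id, line_b=b.line_id,
                          statistic=float(odds), p_value=float(p),
                          method="fisher_exact")
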