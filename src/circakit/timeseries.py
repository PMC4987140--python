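"""Normalization of population-level measurements into time series.

Western-blot, RT-qPCR and RIP quantities arrive as long tables with a
matched loading-control / reference value per observation (ATF2,
tubulin, Gapdh, 36B4, RNA input).  The functions here form the standard
derived series: ratio to reference, percent of the value at an anchor
time, nuclear/cytoplasmic ratio and fold enrichment, then hand the
result to the cosinor machinery.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .cosinor import RhythmConfig, RhythmicityCall, TimeSeries, classify_rhythmic

__all__ = [
    "MEASUREMENT_COLUMNS",
    "COMPARTMENTS",
    "normalize_to_reference",
    "percent_of_time0",
    "nc_ratio",
    "fold_enrichment",
    "analyze_panel",
    "rhythm_lost",
    "PanelReport",
]

MEASUREMENT_COLUMNS = ("analyte", "time_h", "quantity", "reference_quantity",
                       "replicate")
COMPARTMENTS = ("total", "nuclear", "cytoplasmic")


def _check_columns(table: pd.DataFrame, required: Sequence[str]) -> None:
    missing = [c for c in required if c not in table.columns]
    if missing:
        raise ValueError(f"measurement table is missing columns {missing}")


def normalize_to_reference(table: pd.DataFrame) -> TimeSeries:
    """Divide each quantity by its matched reference value.

    The table must describe a single analyte (and a single compartment if
    that column is present); the pairing of quantity and reference is
    preserved per replicate and time point.

    Raises
    ------
    ValueError
        Missing, zero or negative reference values (offending row
        indices are listed), or a table mixing several analytes.
    """
    _check_columns(table, MEASUREMENT_COLUMNS)
    analytes = table["analyte"].unique()
    if analytes.size != 1:
        raise ValueError(f"expected a single analyte, got {list(analytes)}")
    series_id = str(analytes[0])
    if "compartment" in table.columns:
        comps = table["compartment"].unique()
        if comps.size != 1:
            raise ValueError(f"expected a single compartment, got {list(comps)}")
        bad_comp = [c for c in comps if c not in COMPARTMENTS]
        if bad_comp:
            raise ValueError(
                f"unknown compartment labels {bad_comp}; expected one of "
                f"{COMPARTMENTS}"
            )
        if comps[0] != "total":
            series_id = f"{series_id}:{comps[0]}"
    ref = pd.to_numeric(table["reference_quantity"], errors="coerce")
    bad = table.index[ref.isna() | (ref <= 0)]
    if len(bad):
        raise ValueError(
            f"{series_id}: reference_quantity missing or non-positive at rows "
            f"{list(bad)}"
        )
    values = table["quantity"].to_numpy(dtype=float) / ref.to_numpy(dtype=float)
    return TimeSeries(
        times=table["time_h"].to_numpy(dtype=float),
        values=values,
        replicates=table["replicate"].to_numpy(),
        series_id=series_id,
    )


def percent_of_time0(series: TimeSeries, t0: float | None = None,
                     anchor: str = "first") -> TimeSeries:
    """Express values as a percent of the replicate-mean value at an anchor time.

    ``t0`` picks an explicit anchor time; otherwise ``anchor`` selects the
    earliest ("first", default) or latest ("last") sampled time.
    """
    if t0 is None:
        if anchor == "first":
            t0 = float(series.times.min())
        elif anchor == "last":
            t0 = float(series.times.max())
        else:
            raise ValueError(f"anchor must be 'first' or 'last', got {anchor!r}")
    at_anchor = np.isclose(series.times, t0, rtol=0.0, atol=1e-9)
    if not at_anchor.any():
        raise ValueError(
            f"{series.series_id}: no observation at anchor time {t0} h "
            f"(sampled times: {np.unique(series.times).tolist()})"
        )
    anchor_mean = float(series.values[at_anchor].mean())
    if anchor_mean == 0:
        raise ValueError(f"{series.series_id}: anchor mean is zero")
    return TimeSeries(
        times=series.times,
        values=100.0 * series.values / anchor_mean,
        replicates=series.replicates,
        series_id=f"{series.series_id}:pct_of_t{t0:g}",
    )


def nc_ratio(nuclear: TimeSeries, cytoplasmic: TimeSeries) -> TimeSeries:
    """Nuclear / cytoplasmic ratio per matched (time, replicate) observation.

    Both series must already be normalized to the same reference.
    Unmatched observations on either side are an error.
    """
    def keyed(s: TimeSeries) -> dict[tuple[float, str], float]:
        out: dict[tuple[float, str], float] = {}
        for t, v, r in zip(s.times, s.values, s.replicates):
            key = (round(float(t), 9), str(r))
            if key in out:
                raise ValueError(f"{s.series_id}: duplicate observation {key}")
            out[key] = v
        return out

    nuc, cyt = keyed(nuclear), keyed(cytoplasmic)
    only_nuc = sorted(set(nuc) - set(cyt))
    only_cyt = sorted(set(cyt) - set(nuc))
    if only_nuc or only_cyt:
        raise ValueError(
            "unmatched (time, replicate) observations: "
            f"nuclear-only {only_nuc}, cytoplasmic-only {only_cyt}"
        )
    zero = [k for k, v in cyt.items() if v == 0]
    if zero:
        raise ValueError(f"zero cytoplasmic value at {zero}")
    keys = sorted(nuc)
    return TimeSeries(
        times=np.array([k[0] for k in keys]),
        values=np.array([nuc[k] / cyt[k] for k in keys]),
        replicates=np.array([k[1] for k in keys]),
        series_id=f"{nuclear.series_id}/{cytoplasmic.series_id}",
    )


def fold_enrichment(specific: Sequence[float], control: Sequence[float]) -> float:
    """Ratio of means: specific pull-down / irrelevant-control pull-down."""
    specific = np.asarray(specific, dtype=float)
    control = np.asarray(control, dtype=float)
    if specific.size == 0 or control.size == 0:
        raise ValueError("empty input vectors")
    cmean = float(control.mean())
    if cmean <= 0:
        raise ValueError(f"control mean must be positive, got {cmean}")
    return float(specific.mean() / cmean)


@dataclass(frozen=True)
class PanelReport:
    """Batch rhythmicity calls over a panel of series."""

    calls: dict[str, RhythmicityCall]
    config: RhythmConfig

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for sid, call in self.calls.items():
            fit = call.fit
            amp = call.amplitude_test
            rows.append({
                "series_id": sid,
                "rhythmic": call.rhythmic,
                "r_squared": fit.r_squared if fit else np.nan,
                "baseline": fit.baseline if fit else np.nan,
                "amplitude": fit.amplitude if fit else np.nan,
                "damping_rate": fit.damping_rate if fit else np.nan,
                "phase": fit.phase if fit else np.nan,
                "period_h": fit.period if fit else np.nan,
                "amp_ci_low": amp.ci_low if amp else np.nan,
                "amp_ci_high": amp.ci_high if amp else np.nan,
                "r2_pass": call.r2_pass,
                "amplitude_pass": call.amplitude_pass,
                "reason": call.reason or "",
                "detail": call.detail,
            })
        return pd.DataFrame(rows)

    @property
    def n_rhythmic(self) -> int:
        return sum(c.rhythmic for c in self.calls.values())


def analyze_panel(series: Iterable[TimeSeries],
                  config: RhythmConfig | None = None) -> PanelReport:
    """Classify every series in a panel; per-series failures are recorded
    in the report (reason ``fit_error``) and do not abort the run."""
    cfg = config or RhythmConfig()
    calls: dict[str, RhythmicityCall] = {}
    for s in series:
        calls[s.series_id] = classify_rhythmic(s, cfg)
    return PanelReport(calls=calls, config=cfg)


def rhythm_lost(control: RhythmicityCall, treated: RhythmicityCall) -> bool:
    """Knockdown-abolishes-rhythm contrast: the control series is rhythmic
    and the treated series is not, under identical configuration."""
    return bool(control.rhythmic and not treated.rhythmic)
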