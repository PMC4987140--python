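"""Readers/writers for the package's tabular dialects plus run provenance.

Long-format CSV/TSV (header mandatory, '.' decimal point) is the single
tabular interchange dialect; gene lists are one-symbol-per-line text;
reports are JSON (with provenance) and TSV.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cosinor import TimeSeries
from .singlecell import CellTrace

__all__ = [
    "read_table",
    "write_table",
    "read_timeseries",
    "write_timeseries",
    "read_traces",
    "write_traces",
    "read_gene_list",
    "write_gene_list",
    "read_expression_table",
    "read_foci_table",
    "load_config",
    "config_hash",
    "write_json_report",
    "check_overwrite",
]

TIMESERIES_COLUMNS = ("series_id", "time_h", "value", "replicate")
TRACE_COLUMNS = ("cell_id", "line_id", "time_h", "fluorescence")


def _sep_for(path: Path) -> str:
    return "\t" if path.suffix.lower() in (".tsv", ".tab") else ","


def read_table(path: str | Path, required: tuple[str, ...] = ()) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep=_sep_for(path))
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}; "
                         f"found {list(df.columns)}")
    return df


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    path = Path(path)
    df.to_csv(path, sep=_sep_for(path), index=False)


def read_timeseries(path: str | Path) -> dict[str, TimeSeries]:
    """Read a long-format time-series table into one TimeSeries per id."""
    df = read_table(path, TIMESERIES_COLUMNS)
    out: dict[str, TimeSeries] = {}
    for sid, grp in df.groupby("series_id", sort=True):
        out[str(sid)] = TimeSeries(
            times=grp["time_h"].to_numpy(dtype=float),
            values=grp["value"].to_numpy(dtype=float),
            replicates=grp["replicate"].to_numpy(),
            series_id=str(sid),
        )
    return out


def write_timeseries(series: TimeSeries | list[TimeSeries],
                     path: str | Path) -> None:
    if isinstance(series, TimeSeries):
        series = [series]
    frames = [
        pd.DataFrame({
            "series_id": s.series_id, "time_h": s.times, "value": s.values,
            "replicate": s.replicates,
        })
        for s in series
    ]
    write_table(pd.concat(frames, ignore_index=True), path)


def read_traces(trace_path: str | Path,
                background_path: str | Path) -> list[CellTrace]:
    """Read long-format traces plus a background table.

    The background table carries ``background_mean`` keyed by ``cell_id``
    or, for a per-field/per-line scalar, by ``line_id``.
    """
    df = read_table(trace_path, TRACE_COLUMNS)
    bg = read_table(Path(background_path), ("background_mean",))
    if "cell_id" in bg.columns:
        bg_map = dict(zip(bg["cell_id"].astype(str), bg["background_mean"]))
        key = "cell_id"
    elif "line_id" in bg.columns:
        bg_map = dict(zip(bg["line_id"].astype(str), bg["background_mean"]))
        key = "line_id"
    else:
        raise ValueError(f"{background_path}: needs a cell_id or line_id column")
    traces = []
    for cid, grp in df.groupby("cell_id", sort=True):
        grp = grp.sort_values("time_h")
        line = str(grp["line_id"].iloc[0])
        lookup = str(cid) if key == "cell_id" else line
        bmean = bg_map.get(lookup)
        traces.append(CellTrace(
            cell_id=str(cid), line_id=line,
            frame_times=grp["time_h"].to_numpy(dtype=float),
            fluorescence=grp["fluorescence"].to_numpy(dtype=float),
            background_mean=float(bmean) if bmean is not None else None,
        ))
    return traces


def write_traces(traces: list[CellTrace], trace_path: str | Path,
                 background_path: str | Path) -> None:
    frames = [
        pd.DataFrame({
            "cell_id": t.cell_id, "line_id": t.line_id,
            "time_h": t.frame_times, "fluorescence": t.fluorescence,
        })
        for t in traces
    ]
    write_table(pd.concat(frames, ignore_index=True), trace_path)
    bg = pd.DataFrame({
        "cell_id": [t.cell_id for t in traces],
        "background_mean": [t.background_mean for t in traces],
    })
    write_table(bg, background_path)


def read_gene_list(path: str | Path) -> list[str]:
    """One symbol per line; blank lines and '#' comments ignored."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    out = []
    for line in path.read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            out.append(line)
    return out


def write_gene_list(symbols, path: str | Path) -> None:
    Path(path).write_text("\n".join(sorted(symbols)) + "\n")


def read_expression_table(path: str | Path) -> pd.DataFrame:
    return read_table(path, ("gene_id", "symbol", "fpkm", "library_id"))


def read_foci_table(path: str | Path) -> pd.DataFrame:
    return read_table(path, ("cell_id", "well_id", "time_point", "n_foci"))


def load_config(path: str | Path) -> dict:
    """YAML or JSON configuration file -> dict."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        return json.loads(text)
    return yaml.safe_load(text) or {}


def _jsonable(obj: Any) -> Any:
    if isinstance(obj, Mapping):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (set, frozenset)):
        return [_jsonable(v) for v in sorted(obj)]
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, float) and not np.isfinite(obj):
        return None
    return obj


def config_hash(config: Mapping) -> str:
    """Short stable hash of a configuration mapping."""
    canon = json.dumps(_jsonable(config), sort_keys=True)
    return hashlib.sha256(canon.encode()).hexdigest()[:12]


def write_json_report(payload: Mapping, path: str | Path,
                      config: Mapping | None = None) -> None:
    """Write a JSON report with tool-version and config-hash provenance."""
    doc = {
        "provenance": {
            "tool": "circakit",
            "version": __version__,
            "config_hash": config_hash(config or {}),
        },
    }
    if config is not None:
        doc["config"] = _jsonable(config)
    doc.update(_jsonable(payload))
    Path(path).write_text(json.dumps(doc, indent=2, sort_keys=False) + "\n")


def check_overwrite(paths, force: bool) -> None:
    """Refuse to silently overwrite existing outputs without --force."""
    if force:
        return
    existing = [str(p) for p in paths if Path(p).exists()]
    if existing:
        raise FileExistsError(
            f"output files exist (use --force to overwrite): {existing}"
        )
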