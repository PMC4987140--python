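"""Synthetic inputs with known ground truth for every pipeline stage.

Each generator emulates one experimental data stream:

* ``gen_population_series`` — population-level time courses (Western
  blot / qPCR / RIP style): a damped 24-h cosinor sampled every 4 h from
  2 h after synchronization, with independent Gaussian replicate noise.
* ``gen_cell_traces`` — 96-h single-cell fluorescence recordings at
  30-min frame spacing with a per-field background, a rhythmic cell
  fraction, bleaching-like damping, early track loss and deliberately
  dim cells to exercise QC.
* ``gen_pulldown_tables`` — two hybridization-capture expression
  libraries sharing a true target set, plus external circadian gene
  lists built to hit exact configured intersection counts.
* ``gen_foci_counts`` — Poisson per-cell nuclear-foci counts whose mean
  follows a cosine time-of-day profile with a trough 15 h after the
  medium change.

All generators are deterministic under a fixed seed and return a
machine-readable truth record sufficient to score downstream calls.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

from .cosinor import TWO_PI, TimeSeries, damped_cosinor
from .overlap import GeneSet
from .singlecell import CellTrace

__all__ = [
    "PopulationConfig",
    "CellPanelConfig",
    "PulldownConfig",
    "ExternalListSpec",
    "FociConfig",
    "gen_population_series",
    "gen_cell_traces",
    "gen_pulldown_tables",
    "gen_foci_counts",
    "PulldownData",
]


def _rng(seed: int | np.random.Generator | None) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# population-level series
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PopulationConfig:
    """Population time-course generator settings.

    Values are scaled as percent-of-initial-value series: baseline 100,
    amplitude 30 and replicate noise SD 10 give the visual signal-to-
    noise of a clearly rhythmic Western-blot or qPCR course.  Sampling
    is every 4 h from 2 h to 30 h after synchronization (8 points); the
    ``extended_grid`` option runs to 38 h (10 points).
    """

    baseline: float = 100.0
    amplitude: float = 30.0
    damping_rate: float = 0.02
    period: float = 24.0
    phase: float = 1.0
    noise_sd: float = 10.0
    times: tuple[float, ...] = tuple(float(t) for t in range(2, 31, 4))
    extended_grid: bool = False
    n_replicates: int = 3
    series_id: str = "synthetic"

    def sample_times(self) -> np.ndarray:
        if self.extended_grid:
            return np.arange(2.0, 38.0 + 1e-9, 4.0)
        return np.asarray(self.times, dtype=float)

    def validate(self) -> None:
        errors = []
        if self.noise_sd < 0:
            errors.append("noise_sd must be >= 0")
        if self.n_replicates < 1:
            errors.append("n_replicates must be >= 1")
        if self.period <= 0:
            errors.append("period must be > 0")
        if self.damping_rate < 0:
            errors.append("damping_rate must be >= 0")
        if len(self.sample_times()) < 4:
            errors.append("times must hold at least 4 points")
        if errors:
            raise ValueError("invalid PopulationConfig: " + "; ".join(errors))


def gen_population_series(
    config: PopulationConfig | None = None,
    seed: int | np.random.Generator | None = None,
) -> tuple[TimeSeries, dict]:
    """One population time course plus its generating truth record."""
    cfg = config or PopulationConfig()
    cfg.validate()
    rng = _rng(seed)
    t = cfg.sample_times()
    clean = damped_cosinor(t, cfg.baseline, cfg.amplitude, cfg.damping_rate,
                           cfg.period, cfg.phase)
    times, values, reps = [], [], []
    for r in range(cfg.n_replicates):
        noise = rng.normal(0.0, cfg.noise_sd, size=t.size) if cfg.noise_sd else 0.0
        times.append(t)
        values.append(clean + noise)
        reps.append(np.repeat(f"r{r + 1}", t.size))
    series = TimeSeries(
        times=np.concatenate(times), values=np.concatenate(values),
        replicates=np.concatenate(reps), series_id=cfg.series_id,
    )
    truth = {
        "baseline": cfg.baseline, "amplitude": cfg.amplitude,
        "damping_rate": cfg.damping_rate, "period": cfg.period,
        "phase": cfg.phase, "noise_sd": cfg.noise_sd,
        "rhythmic": cfg.amplitude > 0,
    }
    return series, truth


# ---------------------------------------------------------------------------
# single-cell traces
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CellPanelConfig:
    """Single-cell fluorescence panel generator settings.

    Defaults emulate a high signal-to-noise recording: retained rhythmic
    cells oscillate with amplitude equal to half their excess brightness
    over background, slow damping, per-frame noise of 3% of the cell's
    level; non-rhythmic cells drift slowly around a flat baseline.
    ``dropout_rate`` is the fraction of cells whose track is lost before
    48 h; ``dim_fraction`` the fraction set below the 1.10 x background
    brightness gate.  ``rhythmic_fraction`` applies to cells passing QC.
    """

    n_cells: int = 200
    rhythmic_fraction: float = 0.5
    duration_h: float = 96.0
    frame_h: float = 0.5
    background_mean: float = 100.0
    brightness_factor_range: tuple[float, float] = (1.3, 2.5)
    dim_fraction: float = 0.05
    dim_factor_range: tuple[float, float] = (0.95, 1.07)
    dropout_rate: float = 0.10
    short_hours_range: tuple[float, float] = (8.0, 47.0)
    amplitude_frac: float = 0.5
    damping_rate: float = 0.005
    damping_sd: float = 0.002
    phase_mean: float = math.pi
    phase_sd: float = 0.5
    noise_frac: float = 0.03
    drift_slope_sd: float = 0.0015
    period: float = 24.0
    line_id: str = "synthetic"

    def validate(self) -> None:
        errors = []
        for name in ("rhythmic_fraction", "dropout_rate", "dim_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                errors.append(f"{name} must be in [0, 1]")
        if self.n_cells < 1:
            errors.append("n_cells must be >= 1")
        if self.duration_h <= 0 or self.frame_h <= 0:
            errors.append("duration_h and frame_h must be > 0")
        if self.background_mean <= 0:
            errors.append("background_mean must be > 0")
        if not self.short_hours_range[1] < 48.0:
            errors.append("short_hours_range must stay below 48 h")
        if errors:
            raise ValueError("invalid CellPanelConfig: " + "; ".join(errors))


def gen_cell_traces(
    config: CellPanelConfig | None = None,
    seed: int | np.random.Generator | None = None,
) -> tuple[list[CellTrace], pd.DataFrame]:
    """Cell trace collection plus a per-cell truth table.

    Truth columns: ``cell_id``, ``line_id``, ``rhythmic`` (generator
    label), ``qc_fail_reasons`` ('' when the trace should be retained),
    and the generating per-cell parameters.
    """
    cfg = config or CellPanelConfig()
    cfg.validate()
    rng = _rng(seed)
    full_times = np.arange(0.0, cfg.duration_h + cfg.frame_h / 2, cfg.frame_h)
    traces: list[CellTrace] = []
    rows: list[dict] = []
    for i in range(cfg.n_cells):
        cell_id = f"{cfg.line_id}_c{i:04d}"
        is_short = rng.random() < cfg.dropout_rate
        is_dim = rng.random() < cfg.dim_fraction
        qc_reasons = []
        if is_short:
            qc_reasons.append("duration")
        if is_dim:
            qc_reasons.append("brightness")
        is_rhythmic = (not qc_reasons) and (rng.random() < cfg.rhythmic_fraction)

        if is_dim:
            factor = rng.uniform(*cfg.dim_factor_range)
        else:
            factor = rng.uniform(*cfg.brightness_factor_range)
        level = cfg.background_mean * factor

        if is_short:
            cut = rng.uniform(*cfg.short_hours_range)
            times = full_times[full_times <= cut + 1e-9]
        else:
            times = full_times

        noise_sd = cfg.noise_frac * level
        if is_rhythmic:
            amp = cfg.amplitude_frac * max(level - cfg.background_mean, 0.0)
            k = max(rng.normal(cfg.damping_rate, cfg.damping_sd), 0.0)
            phase = rng.normal(cfg.phase_mean, cfg.phase_sd) % TWO_PI
            signal = damped_cosinor(times, level, amp, k, cfg.period, phase)
            slope = 0.0
        else:
            amp, k, phase = 0.0, 0.0, float("nan")
            slope = rng.normal(0.0, cfg.drift_slope_sd)
            signal = level * (1.0 + slope * (times - times.mean()))
        values = np.clip(signal + rng.normal(0.0, noise_sd, size=times.size), 0.0,
                         None)
        traces.append(CellTrace(
            cell_id=cell_id, line_id=cfg.line_id, frame_times=times,
            fluorescence=values, background_mean=cfg.background_mean,
        ))
        rows.append({
            "cell_id": cell_id, "line_id": cfg.line_id,
            "rhythmic": is_rhythmic,
            "qc_fail_reasons": "+".join(qc_reasons),
            "level": level, "amplitude": amp, "damping_rate": k,
            "phase": phase, "drift_slope": slope,
            "tracked_hours": float(times[-1] - times[0]),
        })
    return traces, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# pull-down expression libraries and external lists
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ExternalListSpec:
    """External circadian gene list: size and overlap with the truth set."""

    name: str
    size: int
    n_in_targets: int


@dataclass(frozen=True)
class PulldownConfig:
    """Pull-down library and external-list generator settings.

    The default external-list geometry reproduces the published overlap
    scenario: a 362-gene pituitary circadian list sharing 68 genes with
    the target set, a 675-gene liver post-transcriptional list sharing
    182, the two lists sharing 24 genes of which 6 are also targets.
    Library sizes are desk-scale (hundreds of genes, not thousands);
    the overlap arithmetic is size-independent.
    """

    n_true_targets: int = 500
    n_background_genes: int = 1500
    sensitivity: tuple[float, float] = (1.0, 1.0)
    bg_present_prob: float = 0.5
    fpkm_lognormal_mu: float = 1.0
    fpkm_lognormal_sigma: float = 1.0
    bg_lognormal_mu: float = -0.3
    bg_lognormal_sigma: float = 1.0
    multi_transcript_prob: float = 0.1
    library_ids: tuple[str, str] = ("S_oligo_1", "S_oligo_2")
    external_a: ExternalListSpec = field(
        default_factory=lambda: ExternalListSpec("pituitary_circadian", 362, 68))
    external_b: ExternalListSpec = field(
        default_factory=lambda: ExternalListSpec("liver_posttranscriptional", 675,
                                                 182))
    pair_overlap: int = 24
    pair_overlap_in_targets: int = 6

    def validate(self) -> None:
        errors = []
        for name in ("sensitivity",):
            for v in getattr(self, name):
                if not 0.0 <= v <= 1.0:
                    errors.append(f"{name} values must be in [0, 1]")
        if not 0.0 <= self.bg_present_prob <= 1.0:
            errors.append("bg_present_prob must be in [0, 1]")
        if self.n_true_targets < 1 or self.n_background_genes < 0:
            errors.append("gene counts must be positive")
        a, b = self.external_a, self.external_b
        tri = self.pair_overlap_in_targets
        if tri > self.pair_overlap:
            errors.append("triple overlap exceeds pair overlap")
        if a.n_in_targets > a.size or b.n_in_targets > b.size:
            errors.append("list-target overlap exceeds list size")
        if tri > min(a.n_in_targets, b.n_in_targets):
            errors.append("triple overlap exceeds a list-target overlap")
        pair_only = self.pair_overlap - tri
        if a.size - a.n_in_targets - pair_only < 0:
            errors.append(f"{a.name}: size too small for configured overlaps")
        if b.size - b.n_in_targets - pair_only < 0:
            errors.append(f"{b.name}: size too small for configured overlaps")
        needed = (a.n_in_targets - tri) + (b.n_in_targets - tri) + tri
        if needed > self.n_true_targets:
            errors.append(
                f"need {needed} distinct target genes for the configured "
                f"overlaps but only {self.n_true_targets} true targets"
            )
        if errors:
            raise ValueError("invalid PulldownConfig: " + "; ".join(errors))


@dataclass(frozen=True)
class PulldownData:
    expression: pd.DataFrame          # gene_id, symbol, fpkm, library_id
    true_targets: GeneSet
    externals: dict[str, GeneSet]
    truth: dict


def gen_pulldown_tables(
    config: PulldownConfig | None = None,
    seed: int | np.random.Generator | None = None,
) -> PulldownData:
    """Two expression libraries, the true target set and external lists.

    True targets appear above 1 FPKM in each library with the configured
    per-library sensitivity; background genes appear sporadically and
    may pass the cutoff in both libraries (shared noise).  External
    lists draw their in-target members from the true target set and
    their remaining members from fresh symbols outside the expression
    universe, so the configured intersection counts hold exactly against
    the true target set.
    """
    cfg = config or PulldownConfig()
    cfg.validate()
    rng = _rng(seed)

    target_syms = [f"TGT{i:05d}" for i in range(cfg.n_true_targets)]
    bg_syms = [f"BKG{i:05d}" for i in range(cfg.n_background_genes)]

    rows: list[dict] = []

    def emit(symbol: str, lib: str, fpkm: float) -> None:
        n_tx = 2 if rng.random() < cfg.multi_transcript_prob else 1
        for tx in range(n_tx):
            # extra transcripts carry a lower FPKM so the max-collapse matters
            tx_fpkm = fpkm if tx == 0 else fpkm * rng.uniform(0.1, 0.9)
            rows.append({"gene_id": f"{symbol}.{tx + 1}", "symbol": symbol,
                         "fpkm": round(float(tx_fpkm), 4), "library_id": lib})

    for lib, sens in zip(cfg.library_ids, cfg.sensitivity):
        for sym in target_syms:
            if rng.random() < sens:
                fpkm = 1.0 + rng.lognormal(cfg.fpkm_lognormal_mu,
                                           cfg.fpkm_lognormal_sigma)
            else:
                fpkm = rng.uniform(0.05, 1.0)
            emit(sym, lib, fpkm)
        for sym in bg_syms:
            if rng.random() < cfg.bg_present_prob:
                emit(sym, lib, rng.lognormal(cfg.bg_lognormal_mu,
                                             cfg.bg_lognormal_sigma))

    a, b = cfg.external_a, cfg.external_b
    tri = cfg.pair_overlap_in_targets
    pair_only = cfg.pair_overlap - tri
    picks = rng.choice(cfg.n_true_targets,
                       size=(a.n_in_targets - tri) + (b.n_in_targets - tri) + tri,
                       replace=False)
    triple = [target_syms[i] for i in picks[:tri]]
    a_targets = [target_syms[i] for i in picks[tri:tri + (a.n_in_targets - tri)]]
    b_targets = [target_syms[i] for i in picks[tri + (a.n_in_targets - tri):]]
    shared_out = [f"SHARED{i:05d}" for i in range(pair_only)]
    a_out = [f"EXTA{i:05d}" for i in range(a.size - a.n_in_targets - pair_only)]
    b_out = [f"EXTB{i:05d}" for i in range(b.size - b.n_in_targets - pair_only)]

    externals = {
        a.name: GeneSet(a.name, frozenset(triple + a_targets + shared_out + a_out)),
        b.name: GeneSet(b.name, frozenset(triple + b_targets + shared_out + b_out)),
    }
    truth = {
        "n_true_targets": cfg.n_true_targets,
        "library_ids": list(cfg.library_ids),
        "sensitivity": list(cfg.sensitivity),
        "external_sizes": {a.name: a.size, b.name: b.size},
        "external_in_targets": {a.name: a.n_in_targets, b.name: b.n_in_targets},
        "pair_overlap": cfg.pair_overlap,
        "pair_overlap_in_targets": tri,
    }
    return PulldownData(
        expression=pd.DataFrame(rows),
        true_targets=GeneSet("true_targets", frozenset(target_syms)),
        externals=externals,
        truth=truth,
    )


# ---------------------------------------------------------------------------
# foci counts
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FociConfig:
    """Poisson foci-count generator settings.

    The per-cell mean follows a cosine time-of-day profile with its
    trough at ``trough_time_h`` (15 h after the medium change by
    default, where paraspeckle numbers bottom out).
    """

    time_points: tuple[float, ...] = (3.0, 9.0, 15.0, 21.0)
    n_wells_per_time: int = 6
    n_cells_per_well: int = 25
    base_mean: float = 2.5
    rel_amplitude: float = 0.5
    trough_time_h: float = 15.0
    period: float = 24.0

    def mean_at(self, t: float) -> float:
        return self.base_mean * (
            1.0 - self.rel_amplitude * math.cos(TWO_PI * (t - self.trough_time_h)
                                                / self.period)
        )

    def validate(self) -> None:
        errors = []
        if not 0.0 <= self.rel_amplitude <= 1.0:
            errors.append("rel_amplitude must be in [0, 1]")
        if self.base_mean < 0:
            errors.append("base_mean must be >= 0")
        if self.n_wells_per_time < 1 or self.n_cells_per_well < 1:
            errors.append("well/cell counts must be positive")
        if len(self.time_points) < 2:
            errors.append("need at least two time points")
        if errors:
            raise ValueError("invalid FociConfig: " + "; ".join(errors))


def gen_foci_counts(
    config: FociConfig | None = None,
    seed: int | np.random.Generator | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Per-cell Poisson foci counts plus the true mean per time point."""
    cfg = config or FociConfig()
    cfg.validate()
    rng = _rng(seed)
    rows = []
    truth_means = {}
    cell = 0
    for tp in cfg.time_points:
        mean = cfg.mean_at(tp)
        truth_means[float(tp)] = mean
        for w in range(cfg.n_wells_per_time):
            well_id = f"t{tp:g}_w{w + 1}"
            counts = rng.poisson(mean, size=cfg.n_cells_per_well)
            for c in counts:
                rows.append({"cell_id": f"cell{cell:05d}", "well_id": well_id,
                             "time_point": float(tp), "n_foci": int(c)})
                cell += 1
    return pd.DataFrame(rows), {"mean_by_time": truth_means}
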