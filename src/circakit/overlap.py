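"""Pull-down target-list construction and gene-set overlap arithmetic.

Two hybridization-capture libraries (one per specific antisense
oligonucleotide) are each reduced to the set of gene symbols expressed
above 1 FPKM; the intersection of the two sets is the target list.
That list is then compared with external circadian gene lists by simple
set overlap, with percentages quoted against the external list's size.
Cross-species comparison (rat vs mouse) is done purely on uppercased
official gene symbols.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GeneSet",
    "OverlapResult",
    "CrossResult",
    "HarmonizeResult",
    "harmonize_symbols",
    "filter_fpkm",
    "cross_libraries",
    "overlap_stats",
    "venn3",
    "hypergeom_enrichment",
]

EXPRESSION_COLUMNS = ("gene_id", "symbol", "fpkm", "library_id")


@dataclass(frozen=True)
class GeneSet:
    """A named set of uppercase official gene symbols."""

    name: str
    symbols: frozenset[str]

    @property
    def size(self) -> int:
        return len(self.symbols)

    def __contains__(self, symbol: str) -> bool:
        return symbol.upper() in self.symbols


@dataclass(frozen=True)
class HarmonizeResult:
    gene_set: GeneSet
    n_dropped: int


@dataclass(frozen=True)
class OverlapResult:
    set_a_name: str
    set_b_name: str
    n_a: int
    n_b: int
    n_common: int

    @property
    def percent_of_b(self) -> float:
        """100 * n_common / n_b, rounded to one decimal."""
        return round(100.0 * self.n_common / self.n_b, 1)


@dataclass(frozen=True)
class CrossResult:
    intersection: GeneSet
    frac_of_a: float
    frac_of_b: float


def harmonize_symbols(
    raw: Iterable[str],
    alias_map: Mapping[str, str] | None = None,
    name: str = "gene_set",
) -> HarmonizeResult:
    """Uppercase, de-duplicate and optionally remap a list of symbols.

    Entries without a usable symbol (empty, None, NaN) are dropped and
    counted.  ``alias_map`` is applied before uppercasing.
    """
    kept: set[str] = set()
    dropped = 0
    for entry in raw:
        if entry is None or (isinstance(entry, float) and math.isnan(entry)):
            dropped += 1
            continue
        sym = str(entry).strip()
        if not sym or sym.lower() in ("nan", "-"):
            dropped += 1
            continue
        if alias_map is not None and sym in alias_map:
            sym = alias_map[sym]
        kept.add(sym.upper())
    return HarmonizeResult(gene_set=GeneSet(name=name, symbols=frozenset(kept)),
                           n_dropped=dropped)


def filter_fpkm(table: pd.DataFrame, min_fpkm: float = 1.0,
                name: str | None = None) -> GeneSet:
    """Expressed-gene set: symbols whose FPKM is strictly above the cutoff.

    Multiple transcripts of the same symbol are collapsed to the maximum
    FPKM per symbol before thresholding.  Rows without a symbol are
    dropped; a negative FPKM anywhere is an error.
    """
    missing = [c for c in ("symbol", "fpkm") if c not in table.columns]
    if missing:
        raise ValueError(f"expression table is missing columns {missing}")
    if table.empty:
        raise ValueError("empty expression table")
    fpkm = pd.to_numeric(table["fpkm"], errors="raise")
    if not np.all(np.isfinite(fpkm)):
        raise ValueError("non-finite FPKM values")
    if (fpkm < 0).any():
        bad = table.index[fpkm < 0]
        raise ValueError(f"negative FPKM at rows {list(bad)}")
    if name is None:
        libs = table["library_id"].unique() if "library_id" in table.columns else []
        name = str(libs[0]) if len(libs) == 1 else "expressed"
    sub = pd.DataFrame({"symbol": table["symbol"], "fpkm": fpkm}).dropna(
        subset=["symbol"])
    sub = sub[sub["symbol"].astype(str).str.strip() != ""]
    per_symbol = sub.groupby(sub["symbol"].astype(str).str.upper())["fpkm"].max()
    kept = per_symbol.index[per_symbol > min_fpkm]
    return GeneSet(name=name, symbols=frozenset(kept))


def cross_libraries(a: GeneSet, b: GeneSet) -> CrossResult:
    """Intersect the two library gene sets (the specificity cross).

    Also reports the intersection as a fraction of each input list.
    """
    common = a.symbols & b.symbols
    inter = GeneSet(name=f"{a.name}&{b.name}", symbols=frozenset(common))
    return CrossResult(
        intersection=inter,
        frac_of_a=len(common) / a.size if a.size else float("nan"),
        frac_of_b=len(common) / b.size if b.size else float("nan"),
    )


def overlap_stats(target: GeneSet, external: GeneSet) -> OverlapResult:
    """Overlap of the target list with an external circadian gene list.

    The percentage is quoted against the external list's size.
    """
    if external.size == 0:
        raise ValueError("external gene set is empty")
    common = target.symbols & external.symbols
    return OverlapResult(
        set_a_name=target.name, set_b_name=external.name,
        n_a=target.size, n_b=external.size, n_common=len(common),
    )


def venn3(targets: GeneSet, list_a: GeneSet, list_b: GeneSet) -> dict[str, int]:
    """Counts of all seven disjoint regions of a three-set Venn diagram.

    Keys: ``targets_only``, ``a_only``, ``b_only``, ``targets_a``,
    ``targets_b``, ``a_b`` (pairwise-exclusive regions) and
    ``targets_a_b`` (the triple intersection).
    """
    t, a, b = targets.symbols, list_a.symbols, list_b.symbols
    triple = t & a & b
    return {
        "targets_only": len(t - a - b),
        "a_only": len(a - t - b),
        "b_only": len(b - t - a),
        "targets_a": len((t & a) - b),
        "targets_b": len((t & b) - a),
        "a_b": len((a & b) - t),
        "targets_a_b": len(triple),
    }


def hypergeom_enrichment(target: GeneSet, external: GeneSet,
                         universe_size: int) -> float:
    """Hypergeometric over-representation p-value (extension; the overlap
    report itself carries raw percentages only).

    ``universe_size`` is the number of genes the two lists were drawn
    from; the p-value is P(overlap >= observed) under random draws.
    """
    n_common = len(target.symbols & external.symbols)
    if universe_size < max(target.size, external.size):
        raise ValueError("universe smaller than one of the gene sets")
    return float(stats.hypergeom.sf(n_common - 1, universe_size,
                                    target.size, external.size))
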