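"""Base composition, A+T content and AT/GC strand-skew statistics.

AT skew = (A − T)/(A + T) and GC skew = (G − C)/(G + C), computed over A/C/G/T
only (IUPAC ambiguity codes are tallied separately and excluded from both
numerator and denominator). Whole-genome skews are reported on the deposited H
strand; per-gene skews on the reading strand of each gene.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass

import pandas as pd

from .mito_model import (
    IUPAC_CHARS,
    MitogenomeRecord,
    extract_region,
    feature_sequence,
)


@dataclass(frozen=True)
class BaseCounts:
    a: int
    c: int
    g: int
    t: int
    ambiguous: int = 0

    @property
    def total(self) -> int:
        return self.a + self.c + self.g + self.t + self.ambiguous

    def __add__(self, other: "BaseCounts") -> "BaseCounts":
        return BaseCounts(
            self.a + other.a, self.c + other.c, self.g + other.g,
            self.t + other.t, self.ambiguous + other.ambiguous,
        )


@dataclass(frozen=True)
class SkewStats:
    at_skew: float | None  # None when A+T = 0 (undefined, not zero)
    gc_skew: float | None
    at_content: float | None  # percent of unambiguous total
    gc_content: float | None


def count_bases(seq: str) -> BaseCounts:
    """Exact per-base tally; U counts as T; non-IUPAC characters are errors."""
    c = Counter(seq.upper())
    bad = set(c) - IUPAC_CHARS
    if bad:
        up = seq.upper()
        pos = min(up.index(ch) for ch in bad)
        raise ValueError(f"non-IUPAC character {up[pos]!r} at position {pos + 1}")
    a, cc, g, t = c["A"], c["C"], c["G"], c["T"] + c["U"]
    return BaseCounts(a=a, c=cc, g=g, t=t, ambiguous=len(seq) - (a + cc + g + t))


def skew_stats(counts: BaseCounts) -> SkewStats:
    at = counts.a + counts.t
    gc = counts.g + counts.c
    acgt = at + gc
    return SkewStats(
        at_skew=(counts.a - counts.t) / at if at else None,
        gc_skew=(counts.g - counts.c) / gc if gc else None,
        at_content=100.0 * at / acgt if acgt else None,
        gc_content=100.0 * gc / acgt if acgt else None,
    )


def round_half_away(x: float, ndigits: int) -> float:
    """Round half away from zero (the convention of the printed values)."""
    factor = 10 ** ndigits
    return math.copysign(math.floor(abs(x) * factor + 0.5) / factor, x)


def display_skew(x: float | None) -> str:
    return "" if x is None else f"{round_half_away(x, 4):.4f}"


def display_percent(x: float | None) -> str:
    return "" if x is None else f"{round_half_away(x, 1):.1f}"


def regional_composition(record: MitogenomeRecord) -> pd.DataFrame:
    """Per-region composition/skew report.

    Rows: whole genome (H strand), each PCG and each rRNA (reading strand),
    concatenated PCGs and concatenated tRNAs (reading-strand sequences joined
    in genome order), CR and OL. Columns carry unrounded values plus counts.
    """
    if record.sequence is None:
        raise ValueError(
            "record has no sequence; coordinate-only operations (layout, gene "
            "order) are available without one"
        )
    rows = []

    def add_row(region: str, strand: str, seq: str) -> None:
        bc = count_bases(seq)
        sk = skew_stats(bc)
        rows.append({
            "region": region, "strand": strand, "length": len(seq),
            "a": bc.a, "c": bc.c, "g": bc.g, "t": bc.t, "ambiguous": bc.ambiguous,
            "at_skew": sk.at_skew, "gc_skew": sk.gc_skew,
            "at_content": sk.at_content, "gc_content": sk.gc_content,
        })

    add_row("genome", "H", record.sequence)
    pcg_parts, trna_parts = [], []
    for f in record.features:
        seq = feature_sequence(record, f)
        if f.category == "PCG":
            pcg_parts.append(seq)
            add_row(f.name, f.strand, seq)
        elif f.category == "tRNA":
            trna_parts.append(seq)
        elif f.category == "rRNA":
            add_row(f.name, f.strand, seq)
        elif f.category in ("CR", "OL"):
            add_row(f.name, f.strand, seq)
    if pcg_parts:
        add_row("PCGs_concatenated", "reading", "".join(pcg_parts))
    if trna_parts:
        add_row("tRNAs_concatenated", "reading", "".join(trna_parts))
    return pd.DataFrame(rows)


def composition_table_row(record: MitogenomeRecord) -> dict:
    """One comparative-table row (record, length, base %s, A+T%, skews)."""
    if record.sequence is None:
        raise ValueError("sequence required for composition")
    bc = count_bases(record.sequence)
    sk = skew_stats(bc)
    acgt = bc.total - bc.ambiguous
    return {
        "record": record.record_id,
        "length": record.length,
        "A%": 100.0 * bc.a / acgt,
        "G%": 100.0 * bc.g / acgt,
        "T%": 100.0 * bc.t / acgt,
        "C%": 100.0 * bc.c / acgt,
        "A+T%": sk.at_content,
        "AT_skew": sk.at_skew,
        "GC_skew": sk.gc_skew,
    }
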