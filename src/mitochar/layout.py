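"""Gene-layout accounting: spacers, overlaps and gene-order comparison.

The adjacency gap between consecutive features is
``downstream.start − upstream.end − 1`` under 1-based inclusive coordinates:
positive = intergenic spacer, negative = overlap, zero = abutting. By default
the replication origin OL and the control region are excluded from the gene
ledger — the published spacer/overlap column is computed between *genes*, so
e.g. the trnN–trnC spacer spans the OL region.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .mito_model import MitogenomeRecord, sort_features


@dataclass(frozen=True)
class AdjacencyEntry:
    upstream: str
    downstream: str
    gap: int
    wrap: bool = False  # last→first closure across the excluded region


@dataclass
class LedgerSummary:
    total_overlap_bp: int = 0
    overlap_count: int = 0
    longest_overlap: tuple[int, str, str] | None = None  # (bp, upstream, downstream)
    total_spacer_bp: int = 0
    spacer_count: int = 0
    longest_spacer: tuple[int, str, str] | None = None


def build_ledger(
    record: MitogenomeRecord,
    include_ol: bool = False,
    include_cr: bool = False,
) -> list[AdjacencyEntry]:
    """Pairwise-consecutive gap ledger over the start-sorted, filtered features.

    On circular records, when the control region is excluded a final
    wrap-flagged entry (last feature → first feature, across the CR) is
    appended; wrap entries are excluded from summary totals.
    """
    skip = set()
    if not include_ol:
        skip.add("OL")
    if not include_cr:
        skip.add("CR")
    feats = [f for f in sort_features(record.features) if f.category not in skip]
    if len(feats) < 2:
        import logging
        logging.getLogger(__name__).warning(
            "fewer than 2 features after filtering; empty ledger")
        return []
    entries = [
        AdjacencyEntry(up.name, down.name, down.start - up.end - 1)
        for up, down in zip(feats, feats[1:])
    ]
    if record.circular and not include_cr:
        last, first = feats[-1], feats[0]
        gap = (first.start - 1) + (record.length - last.end)
        entries.append(AdjacencyEntry(last.name, first.name, gap, wrap=True))
    return entries


def summarize_ledger(entries: list[AdjacencyEntry]) -> LedgerSummary:
    """Totals and extrema over non-wrap entries; ties broken by ledger order."""
    s = LedgerSummary()
    for e in entries:
        if e.wrap:
            continue
        if e.gap < 0:
            s.total_overlap_bp += -e.gap
            s.overlap_count += 1
            if s.longest_overlap is None or -e.gap > s.longest_overlap[0]:
                s.longest_overlap = (-e.gap, e.upstream, e.downstream)
        elif e.gap > 0:
            s.total_spacer_bp += e.gap
            s.spacer_count += 1
            if s.longest_spacer is None or e.gap > s.longest_spacer[0]:
                s.longest_spacer = (e.gap, e.upstream, e.downstream)
    return s


@dataclass(frozen=True)
class GeneOrderSignature:
    order: tuple[tuple[str, str], ...]  # (canonical name, strand), H direction

    def __len__(self) -> int:
        return len(self.order)


def gene_order_signature(record: MitogenomeRecord) -> GeneOrderSignature:
    """Rotation-normalized gene order, anchored at trnF (or the
    lexicographically smallest feature name when trnF is absent)."""
    feats = sort_features(record.features)
    names = [f.name for f in feats]
    if "trnF" in names:
        anchor = names.index("trnF")
    else:
        anchor = names.index(min(names))
    rotated = feats[anchor:] + feats[:anchor]
    return GeneOrderSignature(tuple((f.name, f.strand) for f in rotated))


@dataclass
class OrderComparison:
    identical: bool
    differences: list[tuple[int, tuple[str, str] | None, tuple[str, str] | None]] = field(
        default_factory=list)
    breakpoints: int = 0  # adjacencies of a absent from b (circular)


def _adjacency_set(sig: GeneOrderSignature) -> set[tuple[str, str]]:
    names = [n for n, _ in sig.order]
    return {(names[i], names[(i + 1) % len(names)]) for i in range(len(names))}


def compare_orders(a: GeneOrderSignature, b: GeneOrderSignature) -> OrderComparison:
    identical = a.order == b.order
    diffs = []
    if not identical:
        la, lb = len(a.order), len(b.order)
        for i in range(max(la, lb)):
            ea = a.order[i] if i < la else None
            eb = b.order[i] if i < lb else None
            if ea != eb:
                diffs.append((i, ea, eb))
    bp = len(_adjacency_set(a) - _adjacency_set(b)) if a.order and b.order else 0
    return OrderComparison(identical=identical, differences=diffs, breakpoints=bp)
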