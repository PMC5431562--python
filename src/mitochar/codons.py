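"""Codon-level analysis of mitochondrial protein-coding genes.

Works under the vertebrate mitochondrial genetic code (NCBI translation table
2: TGA=Trp, ATA=Met, AGA/AGG=stop). Handles the incomplete stop codons (a
terminal T or TA completed to TAA by post-transcriptional polyadenylation)
that are common at mitochondrial gene boundaries, tabulates start/stop usage
per gene, and computes codon counts and relative synonymous codon usage
(RSCU): RSCU(c) = count(c) · |family(c)| / Σ counts over c's synonymous
family, so a family's RSCU values average 1 when usage is unbiased.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field

import pandas as pd
from Bio.Data import CodonTable

from .mito_model import GeneFeature, MitogenomeRecord, feature_sequence

log = logging.getLogger(__name__)

_BASES = "TCAG"
ALL_CODONS = tuple(a + b + c for a in _BASES for b in _BASES for c in _BASES)


@dataclass(frozen=True)
class GeneticCode:
    """Codon → amino-acid map with explicit start/stop sets."""

    table: dict  # codon -> one-letter aa, stops as "*"
    start_codons: frozenset
    stop_codons: frozenset
    name: str = "vertebrate mitochondrial"

    def families(self, include_stops: bool = False) -> dict[str, tuple[str, ...]]:
        """Synonymous families keyed by amino acid (stops under '*')."""
        fam: dict[str, list[str]] = {}
        for codon in ALL_CODONS:
            aa = self.table[codon]
            if aa == "*" and not include_stops:
                continue
            fam.setdefault(aa, []).append(codon)
        return {aa: tuple(cs) for aa, cs in fam.items()}


def vertebrate_mito_code() -> GeneticCode:
    ncbi = CodonTable.unambiguous_dna_by_id[2]
    table = dict(ncbi.forward_table)
    for stop in ncbi.stop_codons:
        table[stop] = "*"
    # The published annotations use only ATG and the canonical alternative GTG.
    return GeneticCode(
        table=table,
        start_codons=frozenset({"ATG", "GTG"}),
        stop_codons=frozenset(ncbi.stop_codons),  # TAA, TAG, AGA, AGG
    )


VERTEBRATE_MITO = vertebrate_mito_code()


@dataclass
class CodonExtraction:
    gene: str
    codons: list[str]  # in-frame full codons, including a complete stop if any
    start_codon: str
    stop_class: str  # "complete:TAA", "incomplete:T", "incomplete:TA", "annotated:XXX"
    cds_length: int
    incomplete_tail: str = ""
    warnings: list[str] = field(default_factory=list)

    @property
    def coding_codons(self) -> list[str]:
        """Codons excluding a complete stop codon (for usage counting)."""
        if self.stop_class.startswith("complete:"):
            return self.codons[:-1]
        return self.codons


def extract_cds(
    record: MitogenomeRecord,
    feature: GeneFeature,
    code: GeneticCode = VERTEBRATE_MITO,
) -> CodonExtraction:
    """Extract the reading-strand CDS of a PCG and classify its start/stop.

    Frame starts at feature position 1. A trailing 1–2 nt remainder of T or TA
    is an incomplete stop (polyadenylation-completed); any other remainder is
    reported as an annotated anomaly. Internal stop codons draw a warning.
    """
    if feature.category != "PCG":
        raise ValueError(f"{feature.name} is not a PCG")
    seq = feature_sequence(record, feature).upper()
    n = len(seq)
    tail_len = n % 3
    codons = [seq[i:i + 3] for i in range(0, n - tail_len, 3)]
    tail = seq[n - tail_len:] if tail_len else ""
    warnings: list[str] = []

    if tail_len == 0:
        last = codons[-1] if codons else ""
        if last in code.stop_codons:
            stop_class = f"complete:{last}"
        else:
            stop_class = f"annotated:{last}"
            warnings.append(
                f"{feature.name}: final codon {last} is not a stop under the "
                f"{code.name} code")
    elif tail in ("T", "TA"):
        stop_class = f"incomplete:{tail}"
    else:
        stop_class = f"annotated:{tail}"
        warnings.append(
            f"{feature.name}: trailing {tail_len} nt {tail!r} is neither T nor TA")

    interior = codons[:-1] if (tail_len == 0 and codons) else codons
    for i, codon in enumerate(interior):
        if codon in code.stop_codons:
            warnings.append(f"{feature.name}: internal stop {codon} at codon {i + 1}")
    for w in warnings:
        log.warning(w)
    return CodonExtraction(
        gene=feature.name,
        codons=codons,
        start_codon=codons[0] if codons else "",
        stop_class=stop_class,
        cds_length=n,
        incomplete_tail=tail,
        warnings=warnings,
    )


def classify_codons(
    record: MitogenomeRecord, code: GeneticCode = VERTEBRATE_MITO
) -> pd.DataFrame:
    """Per-gene start/stop table with flags for non-canonical codons."""
    pcgs = record.by_category("PCG")
    if len(pcgs) < 13:
        log.warning("only %d of 13 PCGs present", len(pcgs))
    rows = []
    for f in pcgs:
        ex = extract_cds(record, f, code)
        rows.append({
            "gene": f.name,
            "strand": f.strand,
            "cds_length": ex.cds_length,
            "start_codon": ex.start_codon,
            "start_canonical": ex.start_codon in code.start_codons,
            "stop_class": ex.stop_class,
            "stop_canonical": not ex.stop_class.startswith("annotated:"),
            "declared_start": f.declared_start_codon or "",
            "declared_stop": f.declared_stop_codon or "",
        })
    return pd.DataFrame(rows)


@dataclass
class CodonUsageTable:
    counts: dict
    rscu: dict  # codon -> float, or None for codons in all-zero families
    aa_totals: dict
    grand_total: int
    include_stops: bool = False

    def as_frame(self, code: GeneticCode = VERTEBRATE_MITO) -> pd.DataFrame:
        rows = []
        for codon in ALL_CODONS:
            if codon not in self.counts and codon not in self.rscu:
                continue
            rows.append({
                "codon": codon,
                "amino_acid": code.table[codon],
                "count": self.counts.get(codon, 0),
                "rscu": self.rscu.get(codon),
            })
        return pd.DataFrame(rows)


def codon_usage_rscu(
    extractions: list[CodonExtraction],
    include_stops: bool = False,
    code: GeneticCode = VERTEBRATE_MITO,
) -> CodonUsageTable:
    """Pooled codon counts and RSCU over a set of gene extractions.

    Complete stop codons and incomplete tails are excluded unless
    ``include_stops``; families with zero total get RSCU None (undefined, not
    zero).
    """
    if not extractions:
        raise ValueError("at least one extraction required")
    counts: Counter = Counter()
    for ex in extractions:
        counts.update(ex.codons if include_stops else ex.coding_codons)
    families = code.families(include_stops=include_stops)
    rscu: dict = {}
    aa_totals: dict = {}
    for aa, fam in families.items():
        fam_total = sum(counts.get(c, 0) for c in fam)
        aa_totals[aa] = fam_total
        for c in fam:
            rscu[c] = (counts.get(c, 0) * len(fam) / fam_total) if fam_total else None
    relevant = set().union(*families.values())
    grand_total = sum(v for c, v in counts.items() if c in relevant)
    return CodonUsageTable(
        counts=dict(counts), rscu=rscu, aa_totals=aa_totals,
        grand_total=grand_total, include_stops=include_stops,
    )


def translate_mito(
    seq: str,
    code: GeneticCode = VERTEBRATE_MITO,
    initiator_rule: bool = False,
) -> str:
    """Translate under the vertebrate mitochondrial code.

    An incomplete trailing codon is dropped; stops render as '*'; codons with
    ambiguity codes render as 'X'. With ``initiator_rule`` the first codon is
    rendered Met when it is a member of the start set (GTG initiates Met).
    """
    seq = seq.upper().replace("U", "T")
    aas = []
    for i in range(0, len(seq) - len(seq) % 3, 3):
        codon = seq[i:i + 3]
        if codon in code.table:
            aa = code.table[codon]
        else:
            aa = "X"
        if i == 0 and initiator_rule and codon in code.start_codons:
            aa = "M"
        aas.append(aa)
    return "".join(aas)
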