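"""Core data model for circular annotated mitochondrial genomes.

A vertebrate mitogenome is a closed circular molecule of ~16.5 kb carrying 37
canonical genes — 13 protein-coding genes (PCGs), 2 rRNAs, 22 tRNAs — plus the
control region (CR) and the light-strand replication origin (OL). Coordinates
are 1-based inclusive on the heavy (H) strand throughout, matching GenBank
convention; light (L) strand features keep H-strand coordinates and are
reverse-complemented only at sequence extraction.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import FeatureLocation, SeqFeature
from Bio.SeqRecord import SeqRecord

log = logging.getLogger(__name__)

CATEGORIES = ("PCG", "tRNA", "rRNA", "OL", "CR")

#: The 13 canonical mitochondrial protein-coding genes.
PCG_NAMES = (
    "cox1", "cox2", "cox3",
    "nad1", "nad2", "nad3", "nad4", "nad4l", "nad5", "nad6",
    "atp6", "atp8", "cob",
)

#: The 22 canonical tRNAs. S1 = Ser(AGN), S2 = Ser(UCN); L1 = Leu(CUN),
#: L2 = Leu(UUR) — standard mitogenomics convention.
TRNA_NAMES = (
    "trnF", "trnV", "trnL2", "trnI", "trnQ", "trnM", "trnW", "trnA", "trnN",
    "trnC", "trnY", "trnS2", "trnD", "trnK", "trnG", "trnR", "trnH", "trnS1",
    "trnL1", "trnE", "trnT", "trnP",
)

RRNA_NAMES = ("rrnS", "rrnL")

CANONICAL_NAMES = PCG_NAMES + TRNA_NAMES + RRNA_NAMES + ("OL", "CR")

#: L-strand genes in the canonical vertebrate arrangement: nad6 plus eight tRNAs.
CANONICAL_L_STRAND = frozenset(
    {"nad6", "trnQ", "trnA", "trnN", "trnC", "trnY", "trnS2", "trnE", "trnP"}
)

_COMPLEMENT = str.maketrans(
    "ACGTUacgtuRYSWKMBDHVNryswkmbdhvn",
    "TGCAAtgcaaYRSWMKVHDBNyrswmkvhdbn",
)

IUPAC_CHARS = frozenset("ACGTURYSWKMBDHVN")


def revcomp(seq: str) -> str:
    """Reverse complement over the IUPAC DNA alphabet (case-preserving)."""
    return seq.translate(_COMPLEMENT)[::-1]


class NameError_(ValueError):
    """Raised for a feature label with no known canonical synonym."""


def _build_name_map() -> dict[str, str]:
    m: dict[str, str] = {}

    def add(canon: str, *raws: str) -> None:
        for raw in (canon,) + raws:
            m[_normalize_label(raw)] = canon

    add("cox1", "COI", "CO1", "COXI", "cytochrome c oxidase subunit 1", "coi")
    add("cox2", "COII", "CO2", "COXII", "cytochrome c oxidase subunit 2")
    add("cox3", "COIII", "CO3", "COXIII", "cytochrome c oxidase subunit 3")
    add("nad1", "ND1", "NADH1", "NADH dehydrogenase subunit 1")
    add("nad2", "ND2", "NADH2", "NADH dehydrogenase subunit 2")
    add("nad3", "ND3", "NADH3", "NADH dehydrogenase subunit 3")
    add("nad4", "ND4", "NADH4", "NADH dehydrogenase subunit 4")
    add("nad4l", "ND4L", "NADH4L", "NADH dehydrogenase subunit 4L")
    add("nad5", "ND5", "NADH5", "NADH dehydrogenase subunit 5")
    add("nad6", "ND6", "NADH6", "NADH dehydrogenase subunit 6")
    add("atp6", "ATPase6", "ATPase 6", "ATP synthase F0 subunit 6", "ATP6")
    add("atp8", "ATPase8", "ATPase 8", "ATP synthase F0 subunit 8", "ATP8")
    add("cob", "CytB", "CYTB", "cyt b", "cytochrome b")
    add("rrnS", "12S rRNA", "12S", "s-rRNA", "12S ribosomal RNA", "small subunit ribosomal RNA", "rrn12")
    add("rrnL", "16S rRNA", "16S", "l-rRNA", "16S ribosomal RNA", "large subunit ribosomal RNA", "rrn16")
    add("OL", "O_L", "OriL", "origin of L-strand replication", "L-strand origin", "rep_origin")
    add("CR", "D-loop", "control region", "Dloop", "putative control region")

    _one_letter = {
        "F": "Phe", "V": "Val", "I": "Ile", "Q": "Gln", "M": "Met", "W": "Trp",
        "A": "Ala", "N": "Asn", "C": "Cys", "Y": "Tyr", "D": "Asp", "K": "Lys",
        "G": "Gly", "R": "Arg", "H": "His", "E": "Glu", "T": "Thr", "P": "Pro",
    }
    for letter, aa in _one_letter.items():
        canon = f"trn{letter}"
        add(canon, f"tRNA-{aa}", f"tRNA-{aa}({letter})", f"tRNA-{aa} ({letter})",
            f"trn{aa}", f"tRNA {aa}")
    # Duplicated isoacceptors need an explicit codon-family tag; bare trnL/trnS
    # are ambiguous and deliberately unmapped.
    add("trnL1", "tRNA-Leu(CUN)", "tRNA-Leu (CUN)", "trnL(CUN)", "tRNA-Leu (L1)", "trnL CUN")
    add("trnL2", "tRNA-Leu(UUR)", "tRNA-Leu (UUR)", "trnL(UUR)", "tRNA-Leu (L2)", "trnL UUR")
    add("trnS1", "tRNA-Ser(AGN)", "tRNA-Ser (AGN)", "trnS(AGN)", "tRNA-Ser (S1)", "trnS AGN")
    add("trnS2", "tRNA-Ser(UCN)", "tRNA-Ser (UCN)", "trnS(UCN)", "tRNA-Ser (S2)", "trnS UCN")
    return m


def _normalize_label(raw: str) -> str:
    s = raw.strip().lower()
    s = re.sub(r"[\s\-_()\.]+", "", s)
    return s


class NameMap:
    """Synonym table mapping raw feature labels to the 39 canonical names."""

    def __init__(self, extra: dict[str, str] | None = None):
        self._map = _build_name_map()
        if extra:
            for raw, canon in extra.items():
                if canon not in CANONICAL_NAMES:
                    raise ValueError(f"unknown canonical target {canon!r}")
                self._map[_normalize_label(raw)] = canon

    def canonical(self, raw: str) -> str:
        key = _normalize_label(raw)
        if key not in self._map:
            raise NameError_(
                f"feature label {raw!r} has no known canonical synonym "
                "(duplicated isoacceptors trnL/trnS need a CUN/UUR/AGN/UCN tag)"
            )
        return self._map[key]

    def try_canonical(self, raw: str) -> str | None:
        return self._map.get(_normalize_label(raw))


DEFAULT_NAME_MAP = NameMap()


@dataclass(frozen=True)
class GeneFeature:
    """One annotated feature with 1-based inclusive H-strand coordinates."""

    name: str
    category: str
    strand: str  # "H" or "L"
    start: int
    end: int
    anticodon: str | None = None
    declared_start_codon: str | None = None
    declared_stop_codon: str | None = None
    wraps_origin: bool = False

    def __post_init__(self):
        if self.category not in CATEGORIES:
            raise ValueError(f"{self.name}: category {self.category!r} not in {CATEGORIES}")
        if self.strand not in ("H", "L"):
            raise ValueError(f"{self.name}: strand must be H or L, got {self.strand!r}")
        if self.start < 1:
            raise ValueError(f"{self.name}: start must be >= 1, got {self.start}")
        if self.end < self.start and not self.wraps_origin:
            raise ValueError(
                f"{self.name}: end {self.end} < start {self.start} on a feature "
                "not flagged origin-spanning"
            )
        if self.category == "PCG" and self.name not in PCG_NAMES:
            raise ValueError(f"PCG name {self.name!r} is not one of the 13 canonical genes")

    def span(self, genome_length: int | None = None) -> int:
        """Feature length in bp (wrap-aware when origin-spanning)."""
        if self.wraps_origin:
            if genome_length is None:
                raise ValueError("genome_length required for origin-spanning span")
            return genome_length - self.start + 1 + self.end
        return self.end - self.start + 1


@dataclass
class MitogenomeRecord:
    """A circular annotated mitogenome; sequence is optional."""

    record_id: str
    length: int
    circular: bool = True
    sequence: str | None = None
    features: list[GeneFeature] = field(default_factory=list)

    def __post_init__(self):
        if self.sequence is not None and len(self.sequence) != self.length:
            raise ValueError(
                f"sequence length {len(self.sequence)} != declared length {self.length}"
            )
        for f in self.features:
            if f.end > self.length or f.start > self.length:
                raise ValueError(
                    f"feature {f.name} [{f.start}..{f.end}] exceeds genome length {self.length}"
                )
        if sum(1 for f in self.features if f.category == "CR") > 1:
            raise ValueError("more than one control-region feature")
        self.features = sort_features(self.features)

    def feature(self, name: str) -> GeneFeature:
        for f in self.features:
            if f.name == name:
                return f
        raise KeyError(name)

    def by_category(self, *categories: str) -> list[GeneFeature]:
        return [f for f in self.features if f.category in categories]


def sort_features(features: Iterable[GeneFeature]) -> list[GeneFeature]:
    """Sort by start; ties broken by longer span first (deterministic ledger order)."""
    return sorted(features, key=lambda f: (f.start, -(f.end - f.start), f.name))


# ---------------------------------------------------------------------------
# Feature-table I/O (tab-separated; header: feature, category, strand, start,
# end, start_codon, stop_codon, anticodon)

_TABLE_COLUMNS = ("feature", "category", "strand", "start", "end",
                  "start_codon", "stop_codon", "anticodon")


def read_feature_table(
    path: str | Path,
    genome_length: int,
    record_id: str,
    name_map: NameMap = DEFAULT_NAME_MAP,
    circular: bool = True,
) -> MitogenomeRecord:
    """Read a plain tab-separated annotation table into a coordinate-only record.

    Raises ``NameError_`` (naming the row) for labels with no synonym and
    ``ValueError`` for swapped start/end on a non-wrapping feature.
    """
    path = Path(path)
    feats: list[GeneFeature] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        missing = set(_TABLE_COLUMNS[:5]) - set(header)
        if missing:
            raise ValueError(f"{path}: missing required columns {sorted(missing)}")
        idx = {c: header.index(c) for c in header}
        for lineno, line in enumerate(fh, start=2):
            if not line.strip() or line.startswith("#"):
                continue
            cells = line.rstrip("\n").split("\t")

            def cell(col: str) -> str | None:
                i = idx.get(col)
                if i is None or i >= len(cells):
                    return None
                return cells[i].strip() or None

            raw_name = cell("feature")
            try:
                canon = name_map.canonical(raw_name or "")
            except NameError_ as e:
                raise NameError_(f"{path} line {lineno}: {e}") from None
            start, end = int(cell("start")), int(cell("end"))
            wraps = circular and end < start
            try:
                feats.append(GeneFeature(
                    name=canon,
                    category=cell("category"),
                    strand=cell("strand"),
                    start=start,
                    end=end,
                    anticodon=cell("anticodon"),
                    declared_start_codon=cell("start_codon"),
                    declared_stop_codon=cell("stop_codon"),
                    wraps_origin=wraps,
                ))
            except ValueError as e:
                raise ValueError(f"{path} line {lineno} ({raw_name}): {e}") from None
    return MitogenomeRecord(
        record_id=record_id, length=genome_length, circular=circular, features=feats
    )


def write_feature_table(record: MitogenomeRecord, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_TABLE_COLUMNS) + "\n")
        for f in record.features:
            fh.write("\t".join([
                f.name, f.category, f.strand, str(f.start), str(f.end),
                f.declared_start_codon or "", f.declared_stop_codon or "",
                f.anticodon or "",
            ]) + "\n")


# ---------------------------------------------------------------------------
# GenBank flat-file I/O

_GB_CATEGORY = {"CDS": "PCG", "tRNA": "tRNA", "rRNA": "rRNA",
                "D-loop": "CR", "rep_origin": "OL"}


def read_genbank_flatfile(
    path: str | Path, name_map: NameMap = DEFAULT_NAME_MAP
) -> MitogenomeRecord:
    """Read a single-record GenBank flat file.

    CDS features map to PCG, D-loop to CR, rep_origin to OL; ``complement(..)``
    locations become strand L with H-strand coordinates retained. Compound
    locations other than a single origin wrap are rejected.
    """
    records = list(SeqIO.parse(str(path), "genbank"))
    if len(records) != 1:
        raise ValueError(f"{path}: expected exactly one record, found {len(records)}")
    gb = records[0]
    seq = str(gb.seq).upper() if len(gb.seq) else None
    if seq is None:
        log.warning("%s: no ORIGIN block; record is coordinate-only", path)
    length = len(gb.seq) if seq else int(gb.annotations.get("source_length", 0) or len(gb.seq))
    circular = gb.annotations.get("topology", "circular") == "circular"
    feats: list[GeneFeature] = []
    for ft in gb.features:
        if ft.type not in _GB_CATEGORY:
            continue
        loc = ft.location
        parts = list(loc.parts)
        if len(parts) > 2:
            raise ValueError(f"{path}: unsupported compound location {loc}")
        if len(parts) == 2:
            # only a single origin-wrap join is allowed
            p1, p2 = parts
            if not (int(p1.end) == length and int(p2.start) == 0):
                raise ValueError(f"{path}: unsupported compound location {loc}")
            start, end, wraps = int(p1.start) + 1, int(p2.end), True
        else:
            start, end, wraps = int(loc.start) + 1, int(loc.end), False
        strand = "L" if loc.strand == -1 else "H"
        quals = ft.qualifiers
        raw = (quals.get("gene") or quals.get("product") or [ft.type])[0]
        if ft.type == "D-loop":
            raw = "D-loop"
        elif ft.type == "rep_origin":
            raw = "OL"
        canon = name_map.canonical(raw)
        feats.append(GeneFeature(
            name=canon,
            category=_GB_CATEGORY[ft.type],
            strand=strand,
            start=start,
            end=end,
            anticodon=(quals.get("anticodon") or [None])[0],
            declared_start_codon=(quals.get("start_codon") or [None])[0],
            declared_stop_codon=(quals.get("stop_codon") or [None])[0],
            wraps_origin=wraps,
        ))
    return MitogenomeRecord(
        record_id=gb.id or gb.name, length=length, circular=circular,
        sequence=seq, features=feats,
    )


def write_genbank_flatfile(record: MitogenomeRecord, path: str | Path) -> None:
    """Write a record (sequence required) as a GenBank flat file."""
    if record.sequence is None:
        raise ValueError("cannot write a GenBank flat file without sequence")
    _GB_TYPE = {v: k for k, v in _GB_CATEGORY.items()}
    gb = SeqRecord(
        Seq(record.sequence),
        id=record.record_id,
        name=record.record_id[:16],
        description="synthetic mitochondrial genome",
        annotations={
            "molecule_type": "DNA",
            "topology": "circular" if record.circular else "linear",
        },
    )
    for f in record.features:
        loc = FeatureLocation(f.start - 1, f.end, strand=-1 if f.strand == "L" else 1)
        quals: dict[str, list[str]] = {"gene": [f.name]}
        if f.anticodon:
            quals["anticodon"] = [f.anticodon]
        if f.declared_start_codon:
            quals["start_codon"] = [f.declared_start_codon]
        if f.declared_stop_codon:
            quals["stop_codon"] = [f.declared_stop_codon]
        gb.features.append(SeqFeature(loc, type=_GB_TYPE[f.category], qualifiers=quals))
    SeqIO.write([gb], str(path), "genbank")


# ---------------------------------------------------------------------------


def extract_region(
    record: MitogenomeRecord, start: int, end: int, strand: str = "H"
) -> str:
    """H-strand subsequence (strand H) or its reverse complement (strand L).

    ``start > end`` on a circular record denotes an origin-spanning region and
    concatenates the suffix and prefix of the H strand.
    """
    if record.sequence is None:
        raise ValueError("record has no sequence; use coordinate-only operations")
    n = record.length
    if not (1 <= start <= n and 1 <= end <= n):
        raise ValueError(f"coordinates [{start}..{end}] out of range 1..{n}")
    if start <= end:
        sub = record.sequence[start - 1:end]
    else:
        if not record.circular:
            raise ValueError("start > end on a linear record")
        sub = record.sequence[start - 1:] + record.sequence[:end]
    return revcomp(sub) if strand == "L" else sub


def feature_sequence(record: MitogenomeRecord, feat: GeneFeature) -> str:
    """Reading-strand sequence of a feature (wrap- and strand-aware)."""
    if feat.wraps_origin:
        return extract_region(record, feat.start, feat.end, feat.strand)
    return extract_region(record, feat.start, feat.end, feat.strand)


@dataclass(frozen=True)
class Finding:
    level: str  # "info" | "warn"
    message: str


def validate_record(
    record: MitogenomeRecord, overlap_warn_threshold: int = 30
) -> list[Finding]:
    """Report-only sanity checks against the canonical vertebrate organization."""
    findings: list[Finding] = []
    expected = {"PCG": 13, "tRNA": 22, "rRNA": 2, "OL": 1, "CR": 1}
    counts = {cat: 0 for cat in CATEGORIES}
    for f in record.features:
        counts[f.category] += 1
    for cat, want in expected.items():
        got = counts[cat]
        if got == want:
            findings.append(Finding("info", f"{cat} count {got} matches canonical {want}"))
        else:
            findings.append(Finding("warn", f"{cat} count {got} != canonical {want}"))
    present_pcgs = {f.name for f in record.features if f.category == "PCG"}
    for missing in sorted(set(PCG_NAMES) - present_pcgs):
        findings.append(Finding("warn", f"missing PCG: {missing}"))

    l_set = {f.name for f in record.features if f.strand == "L" and f.category != "OL"}
    if l_set == CANONICAL_L_STRAND:
        findings.append(Finding("info", "L-strand features match canonical set"))
    elif l_set:
        extra = sorted(l_set - CANONICAL_L_STRAND)
        missing = sorted(CANONICAL_L_STRAND - l_set)
        findings.append(Finding(
            "warn",
            f"L-strand set differs from canonical (extra={extra}, missing={missing})",
        ))
    feats = [f for f in record.features if not f.wraps_origin]
    for up, down in zip(feats, feats[1:]):
        ov = up.end - down.start + 1
        if ov > overlap_warn_threshold:
            findings.append(Finding(
                "warn", f"overlap {ov} bp between {up.name} and {down.name} "
                        f"exceeds threshold {overlap_warn_threshold}"))
    return findings


def rotate_record(record: MitogenomeRecord, offset: int) -> MitogenomeRecord:
    """Shift the circular origin by ``offset`` bp (testing/simulation helper).

    New coordinate of old position p is ((p - 1 - offset) mod n) + 1. Features
    that come to span the new origin are flagged origin-spanning.
    """
    if not record.circular:
        raise ValueError("cannot rotate a linear record")
    n = record.length
    offset %= n

    def shift(p: int) -> int:
        return (p - 1 - offset) % n + 1

    feats = []
    for f in record.features:
        s, e = shift(f.start), shift(f.end)
        feats.append(replace(f, start=s, end=e, wraps_origin=(e < s)))
    seq = None
    if record.sequence is not None:
        seq = record.sequence[offset:] + record.sequence[:offset]
    return MitogenomeRecord(
        record_id=record.record_id, length=n, circular=True,
        sequence=seq, features=feats,
    )
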