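"""Control-region motif scanning and non-coding/tRNA structure checks.

Four scanners, all exhaustive and deterministic:

* ``scan_consensus`` — best-hit IUPAC consensus matching for control-region
  conserved sequence blocks (CSB-F/E/D/1/2/3) and the ATGTA/TACAT hairpin
  motifs, with an optional order constraint along the region.
* ``find_hairpin`` — exhaustive stem/loop enumeration for the light-strand
  replication origin (OL) hairpin, G–U wobble pairs optionally allowed.
* ``find_tandem_repeats`` — simplified shifted-self-identity repeat search
  (a stand-in for probabilistic tools like Tandem Repeats Finder).
* ``fold_cloverleaf`` — constrained template matching of mitochondrial tRNAs
  against the cloverleaf geometry (acceptor 7 bp, D stem 3–4, anticodon stem
  5 + loop 7, T stem 4–5), scoring Watson–Crick pairs with G–U wobbles
  permitted and counted separately. This is geometry matching, not
  thermodynamic folding.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Iterator

import yaml

IUPAC_SETS = {
    "A": {"A"}, "C": {"C"}, "G": {"G"}, "T": {"T"}, "U": {"T"},
    "R": {"A", "G"}, "Y": {"C", "T"}, "S": {"C", "G"}, "W": {"A", "T"},
    "K": {"G", "T"}, "M": {"A", "C"},
    "B": {"C", "G", "T"}, "D": {"A", "G", "T"}, "H": {"A", "C", "T"},
    "V": {"A", "C", "G"}, "N": {"A", "C", "G", "T"},
}

WC_PAIRS = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")}
GU_PAIRS = {("G", "T"), ("T", "G")}


# ---------------------------------------------------------------------------
# Consensus motif scanning


@dataclass(frozen=True)
class ConsensusMotif:
    name: str
    consensus: str  # IUPAC string
    max_mismatches: int = 0

    def __post_init__(self):
        if not self.consensus:
            raise ValueError("empty consensus")
        bad = set(self.consensus.upper()) - set(IUPAC_SETS)
        if bad:
            raise ValueError(f"non-IUPAC symbols in consensus: {sorted(bad)}")
        if self.max_mismatches >= len(self.consensus):
            raise ValueError("max_mismatches must be < consensus length")


@dataclass(frozen=True)
class MotifHit:
    motif: str
    start: int  # 1-based, region-relative
    strand: str
    mismatches: int


def _mismatches_at(region: str, consensus: str, pos: int) -> int:
    return sum(
        1 for k, sym in enumerate(consensus)
        if region[pos + k] not in IUPAC_SETS[sym]
    )


def scan_consensus(
    region: str,
    motifs: list[ConsensusMotif],
    ordered: bool = False,
) -> list[MotifHit]:
    """Best (fewest-mismatch, tie → leftmost) hit per motif.

    With ``ordered``, hits must appear with strictly increasing starts in the
    given motif order (the canonical control-region order F, E, D, 1, 2, 3);
    motifs that cannot be placed in order within their mismatch budget are
    left out of the result.
    """
    region = region.upper()
    hits: list[MotifHit] = []
    min_start = 0  # 0-based lower bound for ordered mode
    for motif in motifs:
        cons = motif.consensus.upper()
        best: tuple[int, int] | None = None  # (mismatches, pos)
        lo = min_start if ordered else 0
        for pos in range(lo, len(region) - len(cons) + 1):
            mm = _mismatches_at(region, cons, pos)
            if mm <= motif.max_mismatches and (best is None or mm < best[0]):
                best = (mm, pos)
                if mm == 0:
                    break
        if best is not None:
            hits.append(MotifHit(motif.name, best[1] + 1, "H", best[0]))
            if ordered:
                min_start = best[1] + 1
    return hits


def default_csb_motifs() -> list[ConsensusMotif]:
    """Teleost control-region motif set shipped as editable YAML defaults.

    These consensus strings are literature-derived approximations (the CSBs
    vary across teleosts); they are configuration, not measured data, and can
    be replaced without code changes.
    """
    text = resources.files("mitochar.data").joinpath("csb_motifs.yaml").read_text()
    cfg = yaml.safe_load(text)
    return [
        ConsensusMotif(m["name"], m["consensus"], int(m.get("max_mismatches", 0)))
        for m in cfg["motifs"]
    ]


# ---------------------------------------------------------------------------
# OL hairpin


@dataclass(frozen=True)
class HairpinCandidate:
    arm_start: int  # 1-based position of the 5' arm
    stem: int  # paired bases
    loop: int
    score: int  # paired-base count (== stem; G–U counted when allowed)
    gu_pairs: int


def _pairs(a: str, b: str, allow_gu: bool) -> bool:
    return (a, b) in WC_PAIRS or (allow_gu and (a, b) in GU_PAIRS)


def find_hairpin(
    region: str,
    min_stem: int = 5,
    loop_bounds: tuple[int, int] = (3, 12),
    allow_gu: bool = True,
) -> HairpinCandidate | None:
    """Best perfect-stem hairpin by exhaustive (start, stem, loop) scan.

    Ranking: longer stem, then smaller loop, then leftmost. Returns None when
    no candidate reaches ``min_stem`` (absence is a valid result).
    """
    region = region.upper()
    n = len(region)
    lo_loop, hi_loop = loop_bounds
    best: HairpinCandidate | None = None
    for start in range(n):
        for loop in range(lo_loop, hi_loop + 1):
            # stem length s: arm1 = start..start+s-1,
            # arm2 = start+s+loop..start+2s+loop-1, base k pairs arm2[s-1-k]
            max_s = (n - start - loop) // 2
            for s in range(min_stem, max_s + 1):
                ok = True
                gu = 0
                for k in range(s):
                    a = region[start + k]
                    b = region[start + 2 * s + loop - 1 - k]
                    if not _pairs(a, b, allow_gu):
                        ok = False
                        break
                    if (a, b) in GU_PAIRS:
                        gu += 1
                if ok:
                    cand = HairpinCandidate(start + 1, s, loop, s, gu)
                    if (best is None
                            or cand.stem > best.stem
                            or (cand.stem == best.stem and cand.loop < best.loop)):
                        best = cand
    return best


# ---------------------------------------------------------------------------
# Tandem repeats


@dataclass(frozen=True)
class TandemRepeat:
    start: int  # 1-based
    period: int
    length: int  # total span including the first copy
    copies: float
    identity: float


def find_tandem_repeats(
    region: str,
    min_period: int = 2,
    max_period: int = 60,
    min_copies: float = 2.0,
    min_identity: float = 0.85,
    min_length: int = 24,
) -> list[TandemRepeat]:
    """Shifted-self-identity tandem-repeat scan.

    For each period p the region is compared to itself shifted by p; maximal
    runs whose match identity stays ≥ ``min_identity`` are reported when they
    span ≥ ``min_copies`` copies and ≥ ``min_length`` bp in total. Overlapping
    reports are merged keeping the higher-identity (then longer) one. The
    probabilistic alignment model of Tandem Repeats Finder is intentionally
    not reproduced.
    """
    region = region.upper()
    n = len(region)
    found: list[TandemRepeat] = []
    for p in range(min_period, min(max_period, n // 2) + 1):
        matches = [region[i] == region[i + p] for i in range(n - p)]
        i = 0
        while i < len(matches):
            if not matches[i]:
                i += 1
                continue
            # greedy extension keeping running identity above threshold
            hit_count = 0
            j = i
            best_j = i - 1
            while j < len(matches):
                hit_count += matches[j]
                if hit_count / (j - i + 1) >= min_identity:
                    best_j = j
                elif (j - i + 1) * min_identity > hit_count + (len(matches) - j - 1):
                    break
                j += 1
            run = best_j - i + 1
            if run > 0:
                total = run + p
                copies = total / p
                identity = sum(matches[i:best_j + 1]) / run
                if copies >= min_copies and total >= min_length:
                    found.append(TandemRepeat(i + 1, p, total, round(copies, 2),
                                              round(identity, 4)))
            i = max(best_j + 1, i + 1)
    # merge overlaps, preferring higher identity then longer span
    found.sort(key=lambda r: (-r.identity, -r.length, r.start, r.period))
    kept: list[TandemRepeat] = []
    for r in found:
        if all(r.start + r.length <= k.start or k.start + k.length <= r.start
               for k in kept):
            kept.append(r)
    kept.sort(key=lambda r: r.start)
    return kept


# ---------------------------------------------------------------------------
# tRNA cloverleaf template matching


@dataclass(frozen=True)
class CloverleafConfig:
    acceptor_stem: tuple[int, int] = (7, 7)
    spacer1: tuple[int, int] = (1, 3)  # canonical 2
    d_stem: tuple[int, int] = (3, 4)
    d_loop: tuple[int, int] = (4, 12)  # canonical 8
    d_region_loop: tuple[int, int] = (4, 16)  # replaces D arm when absent
    spacer2: tuple[int, int] = (0, 2)  # canonical 1
    ac_stem: tuple[int, int] = (5, 5)
    ac_loop: tuple[int, int] = (7, 7)
    var_loop: tuple[int, int] = (3, 23)  # canonical 4
    t_stem: tuple[int, int] = (4, 5)
    t_loop: tuple[int, int] = (5, 9)  # canonical 7
    tail: tuple[int, int] = (0, 4)  # discriminator (+ any encoded 3' extra)
    allow_gu: bool = True
    d_min_pairs: int = 3  # below this, the D arm is declared absent

    canonical = {
        "acceptor_stem": 7, "spacer1": 2, "d_stem": 4, "d_loop": 8,
        "d_region_loop": 10, "spacer2": 1, "ac_stem": 5, "ac_loop": 7,
        "var_loop": 4, "t_stem": 5, "t_loop": 7, "tail": 1,
    }


@dataclass(frozen=True)
class Geometry:
    """One candidate arm layout (all segment lengths, 5'→3')."""

    acceptor: int
    spacer1: int
    d_stem: int  # 0 = D arm absent
    d_loop: int  # D loop when d_stem > 0, else the whole D-region loop
    spacer2: int
    ac_stem: int
    ac_loop: int
    var_loop: int
    t_stem: int
    t_loop: int
    tail: int

    @property
    def total(self) -> int:
        return (2 * self.acceptor + self.spacer1 + 2 * self.d_stem + self.d_loop
                + self.spacer2 + 2 * self.ac_stem + self.ac_loop + self.var_loop
                + 2 * self.t_stem + self.t_loop + self.tail)

    @property
    def max_pairs(self) -> int:
        return self.acceptor + self.d_stem + self.ac_stem + self.t_stem


@dataclass
class CloverleafModel:
    geometry: Geometry
    acceptor_pairs: int
    d_present: bool
    d_pairs: int
    ac_stem_pairs: int
    ac_loop_len: int
    t_stem_pairs: int
    anticodon: str
    wobble_pairs: int
    unmatched: list[tuple[int, int]] = field(default_factory=list)
    total_pairs: int = 0
    wc_pairs: int = 0


def _canon_order(lo: int, hi: int, canonical: int) -> list[int]:
    """Values lo..hi ordered canonical-first (deterministic tie-breaking)."""
    return sorted(range(lo, hi + 1), key=lambda v: (abs(v - canonical), v))


def enumerate_geometries(length: int, config: CloverleafConfig) -> Iterator[Geometry]:
    """All feasible geometries for a tRNA of ``length`` nt, canonical-first.

    The enumeration order is the tie-breaking order: among equally scoring
    placements the first-enumerated (closest to canonical dimensions) wins.
    """
    c = config.canonical
    for acc in _canon_order(*config.acceptor_stem, c["acceptor_stem"]):
        for tail in _canon_order(*config.tail, c["tail"]):
            for s1 in _canon_order(*config.spacer1, c["spacer1"]):
                for d in sorted(
                    [0] + list(range(config.d_stem[0], config.d_stem[1] + 1)),
                    key=lambda v: (v == 0, abs(v - c["d_stem"])),
                ):
                    dl_range, dl_canon = (
                        (config.d_loop, c["d_loop"]) if d
                        else (config.d_region_loop, c["d_region_loop"])
                    )
                    for dl in _canon_order(*dl_range, dl_canon):
                        for s2 in _canon_order(*config.spacer2, c["spacer2"]):
                            for ac in _canon_order(*config.ac_stem, c["ac_stem"]):
                                for acl in _canon_order(*config.ac_loop, c["ac_loop"]):
                                    for t in _canon_order(*config.t_stem, c["t_stem"]):
                                        for tl in _canon_order(*config.t_loop, c["t_loop"]):
                                            fixed = (2 * acc + s1 + 2 * d + dl + s2
                                                     + 2 * ac + acl + 2 * t + tl + tail)
                                            var = length - fixed
                                            if config.var_loop[0] <= var <= config.var_loop[1]:
                                                yield Geometry(acc, s1, d, dl, s2, ac,
                                                               acl, var, t, tl, tail)


def _score_stem(
    seq: str, a_start: int, b_start: int, stem: int, allow_gu: bool
) -> tuple[int, int, list[tuple[int, int]]]:
    """(paired, gu, mismatched position pairs); arm2 is read antiparallel."""
    paired = gu = 0
    mism: list[tuple[int, int]] = []
    for k in range(stem):
        i = a_start + k
        j = b_start + stem - 1 - k
        a, b = seq[i], seq[j]
        if (a, b) in WC_PAIRS:
            paired += 1
        elif allow_gu and (a, b) in GU_PAIRS:
            paired += 1
            gu += 1
        else:
            mism.append((i + 1, j + 1))
    return paired, gu, mism


def _score_geometry(
    seq: str, g: Geometry, allow_gu: bool
) -> tuple[int, int, int, dict]:
    """Score one layout; returns (total_paired, wc, gu, per-stem detail)."""
    pos = 0
    acc5 = pos; pos += g.acceptor
    pos += g.spacer1
    d5 = pos; pos += g.d_stem
    pos += g.d_loop
    d3 = pos; pos += g.d_stem
    pos += g.spacer2
    ac5 = pos; pos += g.ac_stem
    acl = pos; pos += g.ac_loop
    ac3 = pos; pos += g.ac_stem
    pos += g.var_loop
    t5 = pos; pos += g.t_stem
    pos += g.t_loop
    t3 = pos; pos += g.t_stem
    acc3 = pos; pos += g.acceptor

    detail: dict = {"unmatched": []}
    total = wc = gu = 0
    for key, (x, y, s) in {
        "acceptor": (acc5, acc3, g.acceptor),
        "d": (d5, d3, g.d_stem),
        "ac": (ac5, ac3, g.ac_stem),
        "t": (t5, t3, g.t_stem),
    }.items():
        if s == 0:
            detail[key] = (0, 0)
            continue
        p, w, mism = _score_stem(seq, x, y, s, allow_gu)
        detail[key] = (p, w)
        detail["unmatched"].extend(mism)
        total += p
        gu += w
    wc = total - gu
    detail["anticodon"] = seq[acl + (g.ac_loop - 3) // 2: acl + (g.ac_loop - 3) // 2 + 3]
    return total, wc, gu, detail


def fold_cloverleaf(
    trna_seq: str,
    config: CloverleafConfig = CloverleafConfig(),
) -> CloverleafModel:
    """Best cloverleaf layout by exhaustive constrained search.

    Objective: maximize paired bases (Watson–Crick, with G–U wobbles permitted
    when configured), tie-broken by more Watson–Crick pairs, then by
    canonical-geometry-first enumeration order. A D-stem placement counts only
    when it achieves ≥ ``d_min_pairs`` pairs; otherwise the D region is
    modelled as a plain loop and the D arm reported absent (the mitochondrial
    trnS(AGN) case).
    """
    seq = trna_seq.upper().replace("U", "T")
    if not 55 <= len(seq) <= 95:
        raise ValueError(f"tRNA length {len(seq)} outside [55, 95]")
    best: tuple[int, int, Geometry, dict] | None = None  # (total, wc, geom, detail)
    for g in enumerate_geometries(len(seq), config):
        if best is not None and g.max_pairs < best[0]:
            continue
        total, wc, gu, detail = _score_geometry(seq, g, config.allow_gu)
        if g.d_stem and detail["d"][0] < min(g.d_stem, config.d_min_pairs):
            continue
        if best is None or total > best[0] or (total == best[0] and wc > best[1]):
            best = (total, wc, g, detail)
    if best is None:
        raise ValueError("no feasible cloverleaf geometry for this length/config")
    total, wc, g, detail = best
    gu = total - wc
    return CloverleafModel(
        geometry=g,
        acceptor_pairs=detail["acceptor"][0],
        d_present=g.d_stem > 0,
        d_pairs=detail["d"][0],
        ac_stem_pairs=detail["ac"][0],
        ac_loop_len=g.ac_loop,
        t_stem_pairs=detail["t"][0],
        anticodon=detail["anticodon"],
        wobble_pairs=gu,
        unmatched=detail["unmatched"],
        total_pairs=total,
        wc_pairs=wc,
    )
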