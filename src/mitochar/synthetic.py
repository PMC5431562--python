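"""Synthetic annotated mitogenomes and simulated clades with truth manifests.

The generator emulates the canonical vertebrate mitogenome: 37 genes in the
standard order and strand assignment, planted reading frames under the
vertebrate mitochondrial code, planted cloverleaf tRNAs (with the D-armless
trnS(AGN)), a control region carrying the CSB motif series and the
ATGTA/TACAT pair, an OL hairpin, and configurable spacers/overlaps. Every
planted fact is recorded in a ``TruthManifest`` so each analysis operation can
be tested against ground truth with no external data.

Planted structural facts are made unambiguous by bounded rejection sampling:
a freshly drawn feature is re-drawn (up to a fixed retry budget) if the
corresponding scanner would not recover the planted truth uniquely — e.g. a
random D-region loop that happens to contain a spurious D stem. The manifest
records planted values, never scanner output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import dendropy
import numpy as np

from .mito_model import GeneFeature, MitogenomeRecord, revcomp
from .motifs import (
    CloverleafConfig,
    ConsensusMotif,
    default_csb_motifs,
    enumerate_geometries,
    find_hairpin,
    fold_cloverleaf,
    scan_consensus,
    Geometry,
    IUPAC_SETS,
)

_BASE_IDX = {"A": 0, "C": 1, "G": 2, "T": 3}
_IDX_BASE = "ACGT"
_WC = {"A": "T", "T": "A", "G": "C", "C": "G"}

#: DNA-sense anticodons of the 22 vertebrate mitochondrial tRNAs.
ANTICODONS = {
    "trnF": "GAA", "trnV": "TAC", "trnL2": "TAA", "trnI": "GAT", "trnQ": "TTG",
    "trnM": "CAT", "trnW": "TCA", "trnA": "TGC", "trnN": "GTT", "trnC": "GCA",
    "trnY": "GTA", "trnS2": "TGA", "trnD": "GTC", "trnK": "TTT", "trnG": "TCC",
    "trnR": "TCG", "trnH": "GTG", "trnS1": "GCT", "trnL1": "TAG", "trnE": "TTC",
    "trnT": "TGT", "trnP": "TGG",
}


@dataclass(frozen=True)
class PlannedFeature:
    name: str
    category: str
    strand: str
    length: int
    gap_after: int  # signed gap to the next feature (negative = overlap)
    start_codon: str | None = None  # PCG only
    stop_class: str | None = None  # "complete:TAA" | "incomplete:T" | ...


def canonical_plan_features() -> list[PlannedFeature]:
    """Canonical 39-feature layout with realistic lengths and spacers.

    Lengths and positive spacers follow a typical scorpaeniform genome; the
    20 bp rRNA/tRNA overlap at rrnL/trnL2 is kept (rRNA interiors are
    unconstrained so both features can be realized exactly), while gene–gene
    overlaps that would force two planted reading frames or stems onto shared
    bases are planned as abutting instead.
    """
    F = PlannedFeature
    return [
        F("trnF", "tRNA", "H", 68, 0),
        F("rrnS", "rRNA", "H", 943, 3),
        F("trnV", "tRNA", "H", 72, 0),
        F("rrnL", "rRNA", "H", 1713, -20),
        F("trnL2", "tRNA", "H", 75, 0),
        F("nad1", "PCG", "H", 975, 4, "ATG", "complete:TAA"),
        F("trnI", "tRNA", "H", 70, 0),
        F("trnQ", "tRNA", "L", 71, 0),
        F("trnM", "tRNA", "H", 69, 0),
        F("nad2", "PCG", "H", 1046, 0, "ATG", "incomplete:TA"),
        F("trnW", "tRNA", "H", 71, 1),
        F("trnA", "tRNA", "L", 69, 1),
        F("trnN", "tRNA", "L", 73, 0),
        F("OL", "OL", "L", 36, 0),
        F("trnC", "tRNA", "L", 67, 0),
        F("trnY", "tRNA", "L", 70, 1),
        F("cox1", "PCG", "H", 1551, 0, "GTG", "complete:TAA"),
        F("trnS2", "tRNA", "L", 71, 3),
        F("trnD", "tRNA", "H", 73, 6),
        F("cox2", "PCG", "H", 691, 0, "ATG", "incomplete:T"),
        F("trnK", "tRNA", "H", 74, 1),
        F("atp8", "PCG", "H", 168, 0, "ATG", "complete:TAA"),
        F("atp6", "PCG", "H", 684, 0, "ATG", "complete:TAA"),
        F("cox3", "PCG", "H", 783, 0, "ATG", "complete:TAA"),
        F("trnG", "tRNA", "H", 72, 0),
        F("nad3", "PCG", "H", 351, 0, "ATG", "complete:TAG"),
        F("trnR", "tRNA", "H", 69, 0),
        F("nad4l", "PCG", "H", 297, 0, "ATG", "complete:TAA"),
        F("nad4", "PCG", "H", 1382, 0, "ATG", "incomplete:TA"),
        F("trnH", "tRNA", "H", 69, 0),
        F("trnS1", "tRNA", "H", 68, 4),
        F("trnL1", "tRNA", "H", 73, 0),
        F("nad5", "PCG", "H", 1839, 0, "ATG", "complete:TAA"),
        F("nad6", "PCG", "L", 522, 0, "ATG", "complete:TAA"),
        F("trnE", "tRNA", "L", 69, 5),
        F("cob", "PCG", "H", 1141, 0, "ATG", "incomplete:T"),
        F("trnT", "tRNA", "H", 72, 0),
        F("trnP", "tRNA", "L", 70, 0),
        F("CR", "CR", "H", 838, 0),
    ]


@dataclass
class GenerationPlan:
    features: list[PlannedFeature] = field(default_factory=canonical_plan_features)
    # H-strand proportions A, C, G, T for unconstrained positions; defaults
    # follow the published whole-genome base counts of C. kumu (/16,495).
    composition: tuple[float, float, float, float] = (
        4393 / 16495, 5135 / 16495, 2811 / 16495, 4156 / 16495)
    codon_bias: dict | None = None  # codon -> weight over sense codons
    plant_repeat: tuple[int, float] | None = None  # (period, copies) in CR
    cloverleaf_config: CloverleafConfig = field(default_factory=CloverleafConfig)
    seed: int = 0

    @property
    def genome_length(self) -> int:
        return sum(f.length + f.gap_after for f in self.features)

    def validate(self) -> None:
        if abs(sum(self.composition) - 1.0) > 1e-9:
            raise ValueError("composition proportions must sum to 1")
        n = self.genome_length
        if n <= 0:
            raise ValueError("planned gaps exceed planned lengths")
        pos = 1
        for f in self.features:
            if pos < 1 or pos + f.length - 1 > n:
                raise ValueError(f"feature {f.name} falls outside the planned genome")
            pos += f.length + f.gap_after


@dataclass
class TruthManifest:
    record_id: str
    seed: int
    length: int
    features: list[dict] = field(default_factory=list)
    pcg_truth: dict = field(default_factory=dict)  # gene -> start/stop classes
    trna_truth: dict = field(default_factory=dict)  # name -> geometry/anticodon
    ol_hairpin: dict | None = None
    csb_hits: list[dict] = field(default_factory=list)  # CR-relative positions
    repeat: dict | None = None
    base_counts: dict = field(default_factory=dict)  # region -> {a,c,g,t}

    def to_dict(self) -> dict:
        d = asdict(self)
        for name, tr in d["trna_truth"].items():
            if isinstance(tr.get("geometry"), Geometry):  # pragma: no cover
                tr["geometry"] = asdict(tr["geometry"])
        return d


class PlantingError(RuntimeError):
    """Raised when a planted structure cannot be made unambiguous."""


_MAX_TRIES = 60


def _sample_bases(rng: np.random.Generator, n: int, props) -> str:
    return "".join(_IDX_BASE[i] for i in rng.choice(4, size=n, p=list(props)))


def _realize_iupac(rng: np.random.Generator, consensus: str) -> str:
    return "".join(sorted(IUPAC_SETS[s])[rng.integers(len(IUPAC_SETS[s]))]
                   for s in consensus.upper())


# ---------------------------------------------------------------------------
# tRNA construction


def generate_trna(
    name: str,
    length: int,
    rng: np.random.Generator,
    config: CloverleafConfig = CloverleafConfig(),
    d_armless: bool | None = None,
    props=(0.25, 0.25, 0.25, 0.25),
) -> tuple[str, Geometry, str]:
    """Build a tRNA with a planted perfect-WC cloverleaf; returns
    (sequence, geometry, anticodon).

    The planted geometry is the first feasible one in the folder's
    canonical-first enumeration (so equal-scoring ties resolve to it), and the
    draw is rejected while the folder would not recover the planted arms
    exactly (spurious pairings in loops).
    """
    if d_armless is None:
        d_armless = name == "trnS1"
    geoms = [g for g in enumerate_geometries(length, config)
             if (g.d_stem == 0) == d_armless]
    if not geoms:
        raise PlantingError(f"{name}: no feasible geometry for length {length}")
    g = geoms[0]
    anticodon = ANTICODONS.get(name) or "NNN"
    if anticodon == "NNN":
        anticodon = _sample_bases(rng, 3, props)
    for _ in range(_MAX_TRIES):
        seq = _build_trna_seq(g, anticodon, rng, props)
        model = fold_cloverleaf(seq, config)
        if (model.geometry == g and model.total_pairs == g.max_pairs
                and model.wobble_pairs == 0):
            return seq, g, anticodon
    raise PlantingError(f"{name}: could not plant an unambiguous cloverleaf")


def _build_trna_seq(
    g: Geometry, anticodon: str, rng: np.random.Generator, props
) -> str:
    def stem_arms(s: int) -> tuple[str, str]:
        arm5 = _sample_bases(rng, s, props)
        return arm5, "".join(_WC[b] for b in reversed(arm5))

    acc5, acc3 = stem_arms(g.acceptor)
    d5, d3 = stem_arms(g.d_stem)
    ac5, ac3 = stem_arms(g.ac_stem)
    t5, t3 = stem_arms(g.t_stem)
    pre = (g.ac_loop - 3) // 2
    ac_loop = (_sample_bases(rng, pre, props) + anticodon
               + _sample_bases(rng, g.ac_loop - 3 - pre, props))
    parts = [
        acc5,
        _sample_bases(rng, g.spacer1, props),
        d5, _sample_bases(rng, g.d_loop, props), d3,
        _sample_bases(rng, g.spacer2, props),
        ac5, ac_loop, ac3,
        _sample_bases(rng, g.var_loop, props),
        t5, _sample_bases(rng, g.t_loop, props), t3,
        acc3,
        _sample_bases(rng, g.tail, props),
    ]
    return "".join(parts)


# ---------------------------------------------------------------------------
# PCG construction


_SENSE_CODONS = None


def _sense_codons():
    global _SENSE_CODONS
    if _SENSE_CODONS is None:
        from .codons import VERTEBRATE_MITO, ALL_CODONS
        _SENSE_CODONS = tuple(
            c for c in ALL_CODONS if c not in VERTEBRATE_MITO.stop_codons
        )
    return _SENSE_CODONS


def composition_codon_bias(composition) -> dict:
    """Sense-codon weights matching a target base composition: a codon's
    weight is the product of its bases' target proportions (stops excluded),
    so realized ORF composition tracks the genome-wide target."""
    pa, pc, pg, pt = composition
    p = {"A": pa, "C": pc, "G": pg, "T": pt}
    return {c: p[c[0]] * p[c[1]] * p[c[2]] for c in _sense_codons()}


def generate_cds(
    length: int,
    start_codon: str,
    stop_class: str,
    rng: np.random.Generator,
    codon_bias: dict | None = None,
) -> str:
    """An open reading frame of exactly ``length`` nt with the planted
    start/stop; body codons drawn from ``codon_bias`` (uniform over the 60
    sense codons by default), never in-frame stops."""
    tail = ""
    if stop_class.startswith("incomplete:"):
        tail = stop_class.split(":", 1)[1]
        stop = ""
    else:
        stop = stop_class.split(":", 1)[1]
    body_nt = length - 3 - len(stop) - len(tail)
    if body_nt < 0 or body_nt % 3:
        raise ValueError(
            f"length {length} incompatible with stop class {stop_class}")
    codons = _sense_codons()
    if codon_bias:
        weights = np.array([codon_bias.get(c, 0.0) for c in codons], dtype=float)
        weights /= weights.sum()
    else:
        weights = None
    idx = rng.choice(len(codons), size=body_nt // 3, p=weights)
    return start_codon + "".join(codons[i] for i in idx) + stop + tail


# ---------------------------------------------------------------------------
# Non-coding construction


def _generate_ol(length: int, rng, props) -> tuple[str, dict]:
    """OL reading-strand sequence with a planted perfect hairpin."""
    stem = max(5, (length - 9) // 2 - 1)
    loop = 5
    flank = length - (2 * stem + loop)
    left = flank // 2
    for _ in range(_MAX_TRIES):
        arm5 = _sample_bases(rng, stem, props)
        arm3 = "".join(_WC[b] for b in reversed(arm5))
        seq = (_sample_bases(rng, left, props) + arm5
               + _sample_bases(rng, loop, props) + arm3
               + _sample_bases(rng, flank - left, props))
        best = find_hairpin(seq, min_stem=5, loop_bounds=(3, 12), allow_gu=True)
        if best and best.arm_start == left + 1 and best.stem == stem and best.loop == loop:
            return seq, {"arm_start": left + 1, "stem": stem, "loop": loop}
    raise PlantingError("could not plant an unambiguous OL hairpin")


def _generate_cr(
    length: int, rng, props,
    plant_repeat: tuple[int, float] | None,
) -> tuple[str, list[dict], dict | None]:
    """Control region with the CSB series planted in canonical order plus the
    ATGTA/TACAT motif pair; optional perfect tandem repeat."""
    motifs = default_csb_motifs()
    import yaml
    from importlib import resources
    cfg = yaml.safe_load(
        resources.files("mitochar.data").joinpath("csb_motifs.yaml").read_text())
    hairpin_pair = [ConsensusMotif(m["name"], m["consensus"], m["max_mismatches"])
                    for m in cfg["hairpin_motifs"]]

    for _ in range(_MAX_TRIES):
        seq = list(_sample_bases(rng, length, props))
        planted: list[dict] = []
        pos = 8
        for motif in [hairpin_pair[0], hairpin_pair[1]] + motifs:
            realization = _realize_iupac(rng, motif.consensus)
            seq[pos - 1:pos - 1 + len(realization)] = realization
            planted.append({"motif": motif.name, "start": pos})
            pos += len(realization) + int(rng.integers(40, 70))
        if pos + 40 > length:
            raise PlantingError("control region too short for the motif series")
        repeat_info = None
        if plant_repeat:
            period, copies = plant_repeat
            unit = _sample_bases(rng, period, props)
            total = int(round(period * copies))
            rep = (unit * math.ceil(copies))[:total]
            rstart = pos + 10
            if rstart + total > length:
                raise PlantingError("control region too short for planted repeat")
            seq[rstart - 1:rstart - 1 + total] = rep
            repeat_info = {"start": rstart, "period": period,
                           "copies": round(total / period, 2)}
        text = "".join(seq)
        # unambiguity check: ordered scan must land exactly on planted starts
        hits = scan_consensus(text, motifs, ordered=True)
        want = {p["motif"]: p["start"] for p in planted}
        if (len(hits) == len(motifs)
                and all(h.start == want[h.motif] and h.mismatches == 0 for h in hits)):
            return text, planted, repeat_info
    raise PlantingError("could not plant an unambiguous CSB series")


# ---------------------------------------------------------------------------


def generate_mitogenome(
    plan: GenerationPlan | None = None,
) -> tuple[MitogenomeRecord, TruthManifest]:
    """Deterministically realize a plan into an annotated, sequenced record.

    Features are written in start order; where the plan specifies an overlap
    the later-starting feature overwrites, and structural truths are only
    guaranteed for features whose planted bases survive (the default plan is
    arranged so they all do).
    """
    plan = plan or GenerationPlan()
    plan.validate()
    rng = np.random.default_rng(plan.seed)
    n = plan.genome_length
    props = plan.composition

    genome = list(_sample_bases(rng, n, props))
    manifest = TruthManifest(record_id=f"SYN{plan.seed:06d}", seed=plan.seed, length=n)
    features: list[GeneFeature] = []
    codon_bias = plan.codon_bias or composition_codon_bias(props)

    pos = 1
    for pf in plan.features:
        start, end = pos, pos + pf.length - 1
        pos = end + pf.gap_after + 1
        reading: str | None = None
        declared_start = declared_stop = None
        anticodon = None
        if pf.category == "PCG":
            reading = generate_cds(pf.length, pf.start_codon or "ATG",
                                   pf.stop_class or "complete:TAA", rng,
                                   codon_bias)
            manifest.pcg_truth[pf.name] = {
                "start_codon": pf.start_codon or "ATG",
                "stop_class": pf.stop_class or "complete:TAA",
            }
            declared_start = pf.start_codon or "ATG"
            declared_stop = (pf.stop_class or "complete:TAA").split(":", 1)[1]
        elif pf.category == "tRNA":
            reading, geom, anticodon = generate_trna(
                pf.name, pf.length, rng, plan.cloverleaf_config, props=props)
            manifest.trna_truth[pf.name] = {
                "geometry": geom,
                "anticodon": anticodon,
                "d_present": geom.d_stem > 0,
                "wobble_pairs": 0,
            }
        elif pf.category == "OL":
            reading, manifest.ol_hairpin = _generate_ol(pf.length, rng, props)
        elif pf.category == "CR":
            reading, manifest.csb_hits, manifest.repeat = _generate_cr(
                pf.length, rng, props, plan.plant_repeat)
        # rRNA and any other unconstrained category keep background bases
        if reading is not None:
            h_strand = revcomp(reading) if pf.strand == "L" else reading
            genome[start - 1:end] = h_strand
        features.append(GeneFeature(
            name=pf.name, category=pf.category, strand=pf.strand,
            start=start, end=end, anticodon=anticodon,
            declared_start_codon=declared_start, declared_stop_codon=declared_stop,
        ))

    sequence = "".join(genome)
    record = MitogenomeRecord(
        record_id=manifest.record_id, length=n, circular=True,
        sequence=sequence, features=features,
    )

    # realized (not target) composition, per region and whole genome
    from collections import Counter

    def counts_of(s: str) -> dict:
        c = Counter(s)
        return {"a": c["A"], "c": c["C"], "g": c["G"], "t": c["T"]}

    manifest.base_counts["genome"] = counts_of(sequence)
    for f in features:
        sub = sequence[f.start - 1:f.end]
        if f.strand == "L":
            sub = revcomp(sub)
        manifest.base_counts[f.name] = counts_of(sub)
    manifest.features = [
        {"name": f.name, "category": f.category, "strand": f.strand,
         "start": f.start, "end": f.end}
        for f in features
    ]
    return record, manifest


# ---------------------------------------------------------------------------
# Clade simulation (Jukes–Cantor, no indels)


def evolve_clade(
    root_cds: dict[str, str],
    tree_newick: str,
    seed: int = 0,
) -> tuple[dict[str, dict[str, str]], str]:
    """Evolve each root CDS independently along a tree under Jukes–Cantor.

    Branch lengths are expected substitutions per site; each site mutates with
    probability (3/4)(1 − e^(−4d/3)) per branch, to a uniformly chosen
    different base. Returns ({taxon: {gene: seq}}, true tree newick).
    """
    tree = dendropy.Tree.get(data=tree_newick, schema="newick")
    rng = np.random.default_rng(seed)
    root_arrays = {
        g: np.array([_BASE_IDX[b] for b in s.upper()], dtype=np.int8)
        for g, s in root_cds.items()
    }
    out: dict[str, dict[str, str]] = {}

    def descend(node, arrays):
        for child in node.child_nodes():
            d = child.edge.length or 0.0
            if d < 0:
                raise ValueError("negative branch length")
            p = 0.75 * (1.0 - math.exp(-4.0 * d / 3.0))
            child_arrays = {}
            for g, arr in arrays.items():
                arr2 = arr.copy()
                if p > 0:
                    mask = rng.random(arr2.size) < p
                    shifts = rng.integers(1, 4, size=int(mask.sum()))
                    arr2[mask] = (arr2[mask] + shifts) % 4
                child_arrays[g] = arr2
            if child.is_leaf():
                taxon = child.taxon.label
                out[taxon] = {
                    g: "".join(_IDX_BASE[i] for i in a)
                    for g, a in child_arrays.items()
                }
            else:
                descend(child, child_arrays)

    descend(tree.seed_node, root_arrays)
    return out, tree.as_string(schema="newick").strip()
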