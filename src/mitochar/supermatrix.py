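"""Concatenated 13-gene supermatrix construction across mitogenomes.

Per-gene protein sequences are star-aligned (every sequence globally aligned
to a center sequence with affine gap costs, merged under "once a gap, always
a gap"), back-translated to codon-aligned nucleotide blocks, concatenated
with a 1-based partition map, and exported as FASTA / relaxed PHYLIP / NEXUS
(with a partition block). A p-distance neighbor-joining tree is provided as a
packaged sanity check; model-based inference is deliberately out of scope —
the exports feed external tools.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from Bio.Align import substitution_matrices

from .codons import extract_cds, translate_mito
from .mito_model import PCG_NAMES, MitogenomeRecord

GAP = "-"


# ---------------------------------------------------------------------------
# Ortholog collection


@dataclass
class OrthologSets:
    genes: dict  # gene -> {taxon: CDS string (incomplete tail dropped)}
    missing: dict  # gene -> [taxa lacking it]


def collect_orthologs(records: list[MitogenomeRecord]) -> OrthologSets:
    """Bucket each record's PCG CDSs by canonical gene name.

    A record contributing two copies of one gene is an error; records missing
    a gene are flagged and that gene's block is gap-filled for them.
    """
    genes: dict = {g: {} for g in PCG_NAMES}
    for rec in records:
        seen: Counter = Counter(f.name for f in rec.by_category("PCG"))
        dupes = [g for g, k in seen.items() if k > 1]
        if dupes:
            raise ValueError(f"{rec.record_id}: duplicate PCG(s) {dupes}")
        for f in rec.by_category("PCG"):
            ex = extract_cds(rec, f)
            cds = "".join(ex.codons)  # full codons only; incomplete tail dropped
            if ex.stop_class.startswith("complete:"):
                cds = cds[:-3]
            genes[f.name][rec.record_id] = cds
    missing = {
        g: [r.record_id for r in records if r.record_id not in genes[g]]
        for g in PCG_NAMES if any(r.record_id not in genes[g] for r in records)
    }
    return OrthologSets(genes=genes, missing=missing)


# ---------------------------------------------------------------------------
# Pairwise affine-gap global alignment (Gotoh) and star alignment


def affine_global_align(
    a: str,
    b: str,
    matrix=None,
    gap_open: float = 10.0,
    gap_extend: float = 1.0,
) -> tuple[str, str, float]:
    """Optimal global alignment maximizing substitution score minus affine gap
    penalties (a gap of length L costs gap_open + (L−1)·gap_extend).

    Deterministic tie-breaking: match/mismatch preferred over a gap in ``a``,
    preferred over a gap in ``b``.
    """
    if matrix is None:
        matrix = substitution_matrices.load("BLOSUM62")
    la, lb = len(a), len(b)
    if la == 0 or lb == 0:
        raise ValueError("empty sequence")
    NEG = -1e30

    def score(x: str, y: str) -> float:
        try:
            return float(matrix[x, y])
        except KeyError:
            return float(matrix["X", "X"]) if ("X", "X") in matrix else 0.0

    M = np.full((la + 1, lb + 1), NEG)
    X = np.full((la + 1, lb + 1), NEG)  # gap in b (consume a)
    Y = np.full((la + 1, lb + 1), NEG)  # gap in a (consume b)
    M[0, 0] = 0.0
    for i in range(1, la + 1):
        X[i, 0] = -gap_open - (i - 1) * gap_extend
    for j in range(1, lb + 1):
        Y[0, j] = -gap_open - (j - 1) * gap_extend
    for i in range(1, la + 1):
        ai = a[i - 1]
        for j in range(1, lb + 1):
            s = score(ai, b[j - 1])
            M[i, j] = max(M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1]) + s
            X[i, j] = max(M[i - 1, j] - gap_open, X[i - 1, j] - gap_extend,
                          Y[i - 1, j] - gap_open)
            Y[i, j] = max(M[i, j - 1] - gap_open, Y[i, j - 1] - gap_extend,
                          X[i, j - 1] - gap_open)
    # traceback
    out_a: list[str] = []
    out_b: list[str] = []
    i, j = la, lb
    state = int(np.argmax([M[i, j], X[i, j], Y[i, j]]))
    best = float(max(M[i, j], X[i, j], Y[i, j]))
    while i > 0 or j > 0:
        if state == 0:
            s = score(a[i - 1], b[j - 1])
            prev = [M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1]]
            state = int(np.argmax(prev))
            out_a.append(a[i - 1])
            out_b.append(b[j - 1])
            i, j = i - 1, j - 1
        elif state == 1:
            # gap in b; which predecessor?
            if abs(X[i, j] - (M[i - 1, j] - gap_open)) < 1e-9:
                state = 0
            elif abs(X[i, j] - (X[i - 1, j] - gap_extend)) < 1e-9:
                state = 1
            else:
                state = 2
            out_a.append(a[i - 1])
            out_b.append(GAP)
            i -= 1
        else:
            if abs(Y[i, j] - (M[i, j - 1] - gap_open)) < 1e-9:
                state = 0
            elif abs(Y[i, j] - (Y[i, j - 1] - gap_extend)) < 1e-9:
                state = 2
            else:
                state = 1
            out_a.append(GAP)
            out_b.append(b[j - 1])
            j -= 1
        if i == 0 and j > 0:
            state = 2
        elif j == 0 and i > 0:
            state = 1
    return "".join(reversed(out_a)), "".join(reversed(out_b)), best


def _kmer_profile(seq: str, k: int = 2) -> Counter:
    return Counter(seq[i:i + k] for i in range(len(seq) - k + 1))


def _profile_distance(p: Counter, q: Counter) -> float:
    keys = set(p) | set(q)
    num = sum(abs(p[k] - q[k]) for k in keys)
    den = sum(p.values()) + sum(q.values())
    return num / den if den else 0.0


def align_star(
    seqs: dict,
    gap_open: float = 10.0,
    gap_extend: float = 1.0,
    matrix=None,
) -> dict:
    """Star multiple alignment of ``{taxon: sequence}``.

    The center is the sequence minimizing summed pairwise k-mer-profile
    distance (ties → taxon label order); every other sequence is globally
    aligned to the center and the pairwise alignments are merged under "once
    a gap, always a gap". Deterministic under fixed parameters.
    """
    if len(seqs) < 2:
        raise ValueError("need at least 2 sequences")
    for t, s in seqs.items():
        if not s:
            raise ValueError(f"empty sequence for {t}")
    taxa = sorted(seqs)
    profiles = {t: _kmer_profile(seqs[t]) for t in taxa}
    center = min(
        taxa,
        key=lambda t: (sum(_profile_distance(profiles[t], profiles[u])
                           for u in taxa if u != t), t),
    )
    # master center (with accumulated gaps) and per-taxon aligned strings
    master_center = seqs[center]
    aligned: dict = {center: seqs[center]}
    for t in taxa:
        if t == center:
            continue
        ac, at, _ = affine_global_align(seqs[center], seqs[t],
                                        matrix, gap_open, gap_extend)
        # merge master (center vs previous taxa) with the fresh pair (ac, at):
        # "once a gap, always a gap" — gap columns from either side persist
        new_center: list[str] = []
        new_t: list[str] = []
        pads: dict = {u: [] for u in aligned}
        i = j = 0
        while i < len(master_center) or j < len(ac):
            mc = master_center[i] if i < len(master_center) else None
            pc = ac[j] if j < len(ac) else None
            if mc == GAP and pc == GAP:
                new_center.append(GAP)
                new_t.append(at[j])
                for u in pads:
                    pads[u].append(aligned[u][i])
                i += 1
                j += 1
            elif mc == GAP:
                new_center.append(GAP)
                new_t.append(GAP)
                for u in pads:
                    pads[u].append(aligned[u][i])
                i += 1
            elif pc == GAP:
                new_center.append(GAP)
                new_t.append(at[j])
                for u in pads:
                    pads[u].append(GAP)
                j += 1
            else:
                new_center.append(mc)
                new_t.append(at[j])
                for u in pads:
                    pads[u].append(aligned[u][i])
                i += 1
                j += 1
        master_center = "".join(new_center)
        aligned = {u: "".join(cols) for u, cols in pads.items()}
        aligned[t] = "".join(new_t)
    lengths = {len(v) for v in aligned.values()}
    assert len(lengths) == 1, "ragged star alignment"
    return aligned


# ---------------------------------------------------------------------------
# Back-translation


def back_translate(aa_aligned: dict, cds: dict) -> dict:
    """Expand an aligned amino-acid block to a codon-aligned nucleotide block.

    Each residue column becomes its source codon; gaps become '---'. The
    degapped result round-trips to the input CDS.
    """
    out = {}
    for taxon, aa in aa_aligned.items():
        nt = cds[taxon]
        degapped = aa.replace(GAP, "")
        if len(degapped) * 3 != len(nt):
            raise ValueError(
                f"{taxon}: aa length {len(degapped)} × 3 != CDS length {len(nt)}")
        codons = iter(nt[i:i + 3] for i in range(0, len(nt), 3))
        out[taxon] = "".join("---" if c == GAP else next(codons) for c in aa)
    return out


# ---------------------------------------------------------------------------
# Supermatrix bundle


@dataclass
class SupermatrixBundle:
    taxa: list
    aa_blocks: dict  # gene -> {taxon: aligned aa}
    nt_blocks: dict  # gene -> {taxon: codon-aligned nt}
    aa_matrix: dict  # taxon -> concatenated aa
    nt_matrix: dict
    partitions_aa: dict  # gene -> (start, end) 1-based inclusive
    partitions_nt: dict


def build_supermatrix(
    records: list[MitogenomeRecord],
    gap_open: float = 10.0,
    gap_extend: float = 1.0,
) -> SupermatrixBundle:
    orth = collect_orthologs(records)
    taxa = [r.record_id for r in records]
    aa_blocks: dict = {}
    nt_blocks: dict = {}
    for gene in PCG_NAMES:
        bucket = orth.genes[gene]
        if len(bucket) < 2:
            continue
        aa = {t: translate_mito(s, initiator_rule=True).replace("*", "X")
              for t, s in bucket.items()}
        aligned = align_star(aa, gap_open, gap_extend)
        nt_blocks[gene] = back_translate(aligned, bucket)
        width = len(next(iter(aligned.values())))
        for t in taxa:  # gap-fill taxa missing this gene
            if t not in aligned:
                aligned[t] = GAP * width
                nt_blocks[gene][t] = GAP * (3 * width)
        aa_blocks[gene] = aligned
    aa_matrix = {t: "" for t in taxa}
    nt_matrix = {t: "" for t in taxa}
    partitions_aa: dict = {}
    partitions_nt: dict = {}
    pos_aa = pos_nt = 0
    for gene in PCG_NAMES:
        if gene not in aa_blocks:
            continue
        waa = len(next(iter(aa_blocks[gene].values())))
        partitions_aa[gene] = (pos_aa + 1, pos_aa + waa)
        partitions_nt[gene] = (pos_nt + 1, pos_nt + 3 * waa)
        pos_aa += waa
        pos_nt += 3 * waa
        for t in taxa:
            aa_matrix[t] += aa_blocks[gene][t]
            nt_matrix[t] += nt_blocks[gene][t]
    return SupermatrixBundle(
        taxa=taxa, aa_blocks=aa_blocks, nt_blocks=nt_blocks,
        aa_matrix=aa_matrix, nt_matrix=nt_matrix,
        partitions_aa=partitions_aa, partitions_nt=partitions_nt,
    )


# ---------------------------------------------------------------------------
# Distances and neighbor joining


def p_distance_matrix(matrix: dict) -> tuple[list, np.ndarray]:
    """Pairwise proportion of differing aligned sites, ignoring columns where
    either sequence has a gap or ambiguity (non-ACGT / non-standard-aa)."""
    taxa = sorted(matrix)
    n = len(taxa)
    dm = np.zeros((n, n))
    arrs = [np.frombuffer(matrix[t].upper().encode(), dtype=np.uint8) for t in taxa]
    skip_codes = np.frombuffer((GAP + "NX?").encode(), dtype=np.uint8)
    oks = [~np.isin(a, skip_codes) for a in arrs]
    for i in range(n):
        for j in range(i + 1, n):
            valid = oks[i] & oks[j]
            nv = int(valid.sum())
            d = float(((arrs[i] != arrs[j]) & valid).sum()) / nv if nv else 0.0
            dm[i, j] = dm[j, i] = d
    return taxa, dm


def nj_tree(taxa: list, dist: np.ndarray) -> str:
    """Neighbor joining with deterministic tie-breaking; returns newick.

    Ties in the Q criterion resolve to the lexicographically smallest taxon
    label pair; negative branch lengths are clamped to 0.
    """
    n = len(taxa)
    if n < 3:
        raise ValueError("need at least 3 taxa")
    if not np.allclose(dist, dist.T, atol=1e-12):
        raise ValueError("distance matrix is not symmetric")
    import logging
    log = logging.getLogger(__name__)

    nodes = [str(t) for t in taxa]  # newick fragment per active node
    labels = [str(t) for t in taxa]  # tie-breaking key (smallest leaf label)
    d = dist.astype(float).copy()
    active = list(range(n))
    while len(active) > 2:
        m = len(active)
        r = {i: sum(d[i, j] for j in active if j != i) for i in active}
        best = None
        for ai in range(m):
            for bj in range(ai + 1, m):
                i, j = active[ai], active[bj]
                q = (m - 2) * d[i, j] - r[i] - r[j]
                key = tuple(sorted((labels[i], labels[j])))
                if best is None or q < best[0] - 1e-12 or (
                        abs(q - best[0]) <= 1e-12 and key < best[1]):
                    best = (q, key, i, j)
        _, _, i, j = best
        vi = 0.5 * d[i, j] + (r[i] - r[j]) / (2 * (m - 2))
        vj = d[i, j] - vi
        if vi < 0 or vj < 0:
            log.warning("negative NJ branch length clamped to 0")
        vi, vj = max(vi, 0.0), max(vj, 0.0)
        new_row = np.zeros(d.shape[0] + 1)
        d = np.pad(d, ((0, 1), (0, 1)))
        k = d.shape[0] - 1
        for x in active:
            if x in (i, j):
                continue
            d[k, x] = d[x, k] = 0.5 * (d[i, x] + d[j, x] - d[i, j])
        nodes.append(f"({nodes[i]}:{vi:.6f},{nodes[j]}:{vj:.6f})")
        labels.append(min(labels[i], labels[j]))
        active = [x for x in active if x not in (i, j)] + [k]
        del new_row
    i, j = active
    v = max(d[i, j], 0.0)
    return f"({nodes[i]}:{v / 2:.6f},{nodes[j]}:{v / 2:.6f});"


# ---------------------------------------------------------------------------
# Exporters


def write_fasta(matrix: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        for taxon in sorted(matrix):
            fh.write(f">{taxon}\n{matrix[taxon]}\n")


def read_fasta(path: str | Path) -> dict:
    out: dict = {}
    name = None
    parts: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip()
            if line.startswith(">"):
                if name is not None:
                    out[name] = "".join(parts)
                name = line[1:].split()[0]
                parts = []
            elif line:
                parts.append(line)
    if name is not None:
        out[name] = "".join(parts)
    return out


def write_phylip(matrix: dict, path: str | Path) -> None:
    """Relaxed PHYLIP: full names, two-space separator."""
    taxa = sorted(matrix)
    width = len(next(iter(matrix.values())))
    with open(path, "w") as fh:
        fh.write(f"{len(taxa)} {width}\n")
        for t in taxa:
            fh.write(f"{t}  {matrix[t]}\n")


def write_nexus(
    matrix: dict, partitions: dict, path: str | Path, datatype: str = "dna"
) -> None:
    taxa = sorted(matrix)
    width = len(next(iter(matrix.values())))
    with open(path, "w") as fh:
        fh.write("#NEXUS\nbegin data;\n")
        fh.write(f"  dimensions ntax={len(taxa)} nchar={width};\n")
        fh.write(f"  format datatype={datatype} missing=? gap=-;\n  matrix\n")
        for t in taxa:
            fh.write(f"    {t}  {matrix[t]}\n")
        fh.write("  ;\nend;\n\nbegin sets;\n")
        for gene, (s, e) in partitions.items():
            fh.write(f"  charset {gene} = {s}-{e};\n")
        fh.write("end;\n")
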