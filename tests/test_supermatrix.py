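"""Ortholog collection, star alignment, back-translation, NJ."""

import random

import dendropy
import numpy as np
import pytest
from Bio import Align
from Bio.Align import substitution_matrices

from mitochar.mito_model import GeneFeature, MitogenomeRecord
from mitochar.supermatrix import (
    affine_global_align,
    align_star,
    back_translate,
    build_supermatrix,
    collect_orthologs,
    nj_tree,
    p_distance_matrix,
    read_fasta,
    write_fasta,
    write_phylip,
)

AA = "ACDEFGHIKLMNPQRSTVWY"


def _pairwise_oracle_score(a, b, open_=10, ext=1):
    al = Align.PairwiseAligner()
    al.mode = "global"
    al.substitution_matrix = substitution_matrices.load("BLOSUM62")
    al.open_gap_score = -open_
    al.extend_gap_score = -ext
    return al.score(a, b)


class TestCollect:
    def test_thirteen_buckets(self, syn_pair):
        r1, r2 = syn_pair
        orth = collect_orthologs([r1, r2])
        assert len(orth.genes) == 13
        assert all(len(b) == 2 for b in orth.genes.values())
        assert orth.missing == {}

    def test_missing_gene_flagged(self, syn_pair):
        r1, r2 = syn_pair
        feats = [f for f in r2.features if f.name != "atp8"]
        r2b = MitogenomeRecord("NOATP8", r2.length, sequence=r2.sequence,
                               features=feats)
        orth = collect_orthologs([r1, r2b])
        assert orth.missing == {"atp8": ["NOATP8"]}

    def test_duplicate_gene_rejected(self, syn_pair):
        r1, _ = syn_pair
        dup = r1.feature("nad1")
        extra = GeneFeature("nad1", "PCG", "H", dup.start + 3000, dup.end + 3000)
        bad = MitogenomeRecord("DUP", r1.length, sequence=r1.sequence,
                               features=list(r1.features) + [extra])
        with pytest.raises(ValueError, match="nad1"):
            collect_orthologs([r1, bad])


class TestAlign:
    def test_identical_sequences_gapless(self):
        out = align_star({"a": "MKVLW", "b": "MKVLW", "c": "MKVLW"})
        assert set(out.values()) == {"MKVLW"}

    def test_single_gap_forced(self):
        out = align_star({"a": "MKV", "b": "MV"})
        assert out["a"] == "MKV" and out["b"] == "M-V"

    @pytest.mark.parametrize("seed", range(10))
    def test_pairwise_score_equals_dp_oracle(self, seed):
        rng = random.Random(seed)
        a = "".join(rng.choice(AA) for _ in range(rng.randint(10, 60)))
        b = "".join(rng.choice(AA) for _ in range(rng.randint(10, 60)))
        _, _, score = affine_global_align(a, b)
        assert score == pytest.approx(_pairwise_oracle_score(a, b))

    def test_alignment_degaps_to_inputs(self):
        seqs = {"a": "MKVLINSTPW", "b": "MKVINSPW", "c": "MKVLINSTW"}
        out = align_star(seqs)
        for t, s in seqs.items():
            assert out[t].replace("-", "") == s
        assert len({len(v) for v in out.values()}) == 1


class TestBackTranslate:
    def test_round_trip_random_cds(self):
        rng = random.Random(7)
        from mitochar.codons import ALL_CODONS, VERTEBRATE_MITO, translate_mito
        sense = [c for c in ALL_CODONS if c not in VERTEBRATE_MITO.stop_codons]
        cds = {}
        for t in ("a", "b", "c"):
            n = rng.randint(20, 40)
            cds[t] = "".join(rng.choice(sense) for _ in range(n))
        aa = {t: translate_mito(s) for t, s in cds.items()}
        aligned = align_star(aa)
        nt = back_translate(aligned, cds)
        for t in cds:
            assert nt[t].replace("-", "") == cds[t]
            assert len(nt[t]) == 3 * len(aligned[t])

    def test_gap_expands_to_triple(self):
        nt = back_translate({"a": "M-K"}, {"a": "ATGAAA"})
        assert nt["a"] == "ATG---AAA"

    def test_length_mismatch_names_taxon(self):
        with pytest.raises(ValueError, match="a:"):
            back_translate({"a": "MK"}, {"a": "ATGAAATTT"})


def _same_topology(nwk1, nwk2, taxa):
    from conftest import unrooted_rf
    return unrooted_rf(nwk1, nwk2, dendropy.TaxonNamespace(taxa)) == 0


class TestNeighborJoining:
    def test_three_taxa_three_point_formula(self):
        taxa = ["a", "b", "c"]
        d = np.array([[0, 0.4, 0.6], [0.4, 0, 0.8], [0.6, 0.8, 0]])
        nwk = nj_tree(taxa, d)
        t = dendropy.Tree.get(data=nwk, schema="newick")
        lens = {leaf.taxon.label: leaf.edge.length for leaf in t.leaf_node_iter()}
        # v_a = (d_ab + d_ac - d_bc)/2 etc.
        assert lens["a"] == pytest.approx(0.1, abs=1e-6)
        assert lens["b"] == pytest.approx(0.3, abs=1e-6)

    def test_four_taxon_additive_matrix_recovered(self):
        # tree ((a:1,b:2):1,(c:3,d:4):1) -> additive distances
        taxa = ["a", "b", "c", "d"]
        d = np.array([
            [0, 3, 6, 7],
            [3, 0, 7, 8],
            [6, 7, 0, 7],
            [7, 8, 7, 0]], dtype=float)
        nwk = nj_tree(taxa, d)
        assert _same_topology(nwk, "((a,b),(c,d));", taxa)

    def test_asymmetric_matrix_rejected(self):
        d = np.array([[0, 1, 2], [1.5, 0, 1], [2, 1, 0]], dtype=float)
        with pytest.raises(ValueError, match="symmetric"):
            nj_tree(["a", "b", "c"], d)

    @pytest.mark.parametrize("seed", range(5))
    def test_random_additive_trees_recovered(self, seed):
        """NJ is exact on additive distances (random 6-8 leaf trees)."""
        rng = random.Random(seed)
        n = rng.randint(6, 8)
        taxa = [f"t{i}" for i in range(n)]
        tree = dendropy.simulate.treesim.birth_death_tree(
            birth_rate=1.0, death_rate=0.0, num_extant_tips=n,
            rng=random.Random(seed))
        tree.taxon_namespace.clear()
        for leaf, label in zip(tree.leaf_node_iter(), taxa):
            leaf.taxon = tree.taxon_namespace.new_taxon(label)
        for e in tree.preorder_edge_iter():
            if e.length is not None:
                e.length = rng.uniform(0.05, 1.0)
        pdm = tree.phylogenetic_distance_matrix()
        d = np.zeros((n, n))
        for i, ti in enumerate(tree.taxon_namespace):
            for j, tj in enumerate(tree.taxon_namespace):
                d[i, j] = pdm.distance(ti, tj)
        labels = [t.label for t in tree.taxon_namespace]
        nwk = nj_tree(labels, d)
        from conftest import unrooted_rf
        assert unrooted_rf(tree, nwk, tree.taxon_namespace) == 0


class TestBundleAndIO:
    def test_partitions_tile_matrix(self, syn_pair):
        bundle = build_supermatrix(list(syn_pair))
        width = len(next(iter(bundle.nt_matrix.values())))
        spans = sorted(bundle.partitions_nt.values())
        assert spans[0][0] == 1 and spans[-1][1] == width
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            assert s2 == e1 + 1
        for gene, (s, e) in bundle.partitions_nt.items():
            (sa, ea) = bundle.partitions_aa[gene]
            assert e - s + 1 == 3 * (ea - sa + 1)
        assert len({len(v) for v in bundle.aa_matrix.values()}) == 1

    def test_degapped_nt_equals_cds(self, syn_pair):
        from mitochar.codons import extract_cds
        bundle = build_supermatrix(list(syn_pair))
        rec = syn_pair[0]
        for gene, block in bundle.nt_blocks.items():
            f = rec.feature(gene)
            ex = extract_cds(rec, f)
            cds = "".join(ex.codons)
            if ex.stop_class.startswith("complete:"):
                cds = cds[:-3]
            assert block[rec.record_id].replace("-", "") == cds

    def test_fasta_round_trip(self, tmp_path, syn_pair):
        bundle = build_supermatrix(list(syn_pair))
        p = tmp_path / "m.fasta"
        write_fasta(bundle.nt_matrix, p)
        assert read_fasta(p) == bundle.nt_matrix

    def test_phylip_parses(self, tmp_path, syn_pair):
        bundle = build_supermatrix(list(syn_pair))
        p = tmp_path / "m.phy"
        write_phylip(bundle.aa_matrix, p)
        header, *rows = p.read_text().strip().split("\n")
        ntax, nchar = map(int, header.split())
        assert ntax == 2 and all(len(r.split()[1]) == nchar for r in rows)
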