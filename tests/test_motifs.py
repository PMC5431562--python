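"""Consensus scanning, OL hairpin, tandem repeats, tRNA cloverleaf."""

import random

import numpy as np
import pytest

from mitochar.motifs import (
    CloverleafConfig,
    ConsensusMotif,
    IUPAC_SETS,
    default_csb_motifs,
    find_hairpin,
    find_tandem_repeats,
    fold_cloverleaf,
    scan_consensus,
)
from mitochar.mito_model import revcomp
from mitochar.synthetic import generate_trna, _build_trna_seq
from mitochar.motifs import enumerate_geometries


def _random_dna(rng, n):
    return "".join(rng.choice("ACGT") for _ in range(n))


def brute_force_best_hit(region, motif):
    """All-positions Hamming scan (independent oracle)."""
    cons = motif.consensus.upper()
    best = None
    for pos in range(len(region) - len(cons) + 1):
        mm = sum(region[pos + k] not in IUPAC_SETS[c] for k, c in enumerate(cons))
        if mm <= motif.max_mismatches and (best is None or mm < best[0]):
            best = (mm, pos)
    return best


class TestScanConsensus:
    def test_exact_planted_motif(self):
        rng = random.Random(0)
        region = _random_dna(rng, 200)
        region = region[:90] + "ATGTA" + region[95:]
        hits = scan_consensus(region, [ConsensusMotif("ATGTA", "ATGTA", 0)])
        assert hits and hits[0].mismatches == 0
        assert region[hits[0].start - 1:hits[0].start + 4] == "ATGTA"

    def test_absent_motif_no_hit(self):
        hits = scan_consensus("AAAAAAAA", [ConsensusMotif("m", "GGGG", 1)])
        assert hits == []

    def test_zero_mismatch_equals_substring_search(self):
        rng = random.Random(1)
        for _ in range(30):
            region = _random_dna(rng, 120)
            i = rng.randrange(0, 100)
            motif = ConsensusMotif("m", region[i:i + 12], 0)
            hits = scan_consensus(region, [motif])
            assert hits[0].start - 1 == region.find(motif.consensus)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_brute_force_oracle(self, seed):
        rng = random.Random(seed)
        region = _random_dna(rng, 300)
        motifs = [
            ConsensusMotif(f"m{k}", "".join(
                rng.choice("ACGTRYN") for _ in range(rng.randint(6, 12))),
                rng.randint(1, 3))
            for k in range(4)
        ]
        hits = {h.motif: (h.mismatches, h.start - 1)
                for h in scan_consensus(region, motifs)}
        for m in motifs:
            assert hits.get(m.name) == brute_force_best_hit(region, m)

    def test_ordered_mode_rejects_out_of_order(self):
        region = "TTTT" + "CCCCC" + "TTTT" + "GGGGG" + "TTTT"
        motifs = [ConsensusMotif("late", "GGGGG", 0), ConsensusMotif("early", "CCCCC", 0)]
        hits = scan_consensus(region, motifs, ordered=True)
        assert [h.motif for h in hits] == ["late"]  # early cannot follow late

    def test_default_csb_set_loads(self):
        motifs = default_csb_motifs()
        assert [m.name for m in motifs] == [
            "CSB-F", "CSB-E", "CSB-D", "CSB-1", "CSB-2", "CSB-3"]


def brute_force_hairpin(region, min_stem, loop_bounds, allow_gu):
    """Exhaustive stem/loop enumeration (independent oracle)."""
    from mitochar.motifs import WC_PAIRS, GU_PAIRS
    n = len(region)
    best = None
    for start in range(n):
        for loop in range(loop_bounds[0], loop_bounds[1] + 1):
            for s in range(min_stem, (n - start - loop) // 2 + 1):
                ok = all(
                    (region[start + k], region[start + 2 * s + loop - 1 - k])
                    in (WC_PAIRS | (GU_PAIRS if allow_gu else set()))
                    for k in range(s))
                if ok:
                    cand = (s, -loop, -start)
                    if best is None or cand > best:
                        best = cand
    return None if best is None else (best[0], -best[1], -best[2] + 1)


class TestHairpin:
    def test_constructed_palindrome(self):
        hp = find_hairpin("GGGGAAAACCCC", min_stem=4, loop_bounds=(3, 6))
        assert hp.stem == 4 and hp.loop == 4 and hp.arm_start == 1

    def test_absent(self):
        assert find_hairpin("AAAAAAAAAAAA", min_stem=4, loop_bounds=(3, 6)) is None

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_brute_force(self, seed):
        rng = random.Random(seed)
        region = _random_dna(rng, 60)
        got = find_hairpin(region, min_stem=4, loop_bounds=(3, 8), allow_gu=True)
        want = brute_force_hairpin(region, 4, (3, 8), True)
        if want is None:
            assert got is None
        else:
            assert (got.stem, got.loop, got.arm_start) == want

    @pytest.mark.parametrize("seed", range(6))
    def test_revcomp_symmetry(self, seed):
        """Watson–Crick hairpins mirror under reverse complement (a G–U
        wobble does not: it maps to the non-pairing A–C, so GU is off here)."""
        rng = random.Random(100 + seed)
        region = _random_dna(rng, 50)
        a = find_hairpin(region, min_stem=4, loop_bounds=(3, 8), allow_gu=False)
        b = find_hairpin(revcomp(region), min_stem=4, loop_bounds=(3, 8),
                         allow_gu=False)
        assert (a is None) == (b is None)
        if a is not None:
            assert (a.stem, a.loop) == (b.stem, b.loop)


class TestTandemRepeats:
    def test_perfect_triplet(self):
        reps = find_tandem_repeats("ACGTACGTACGT", min_period=4, max_period=6,
                                   min_copies=3, min_length=12)
        assert len(reps) == 1
        assert reps[0].period == 4 and reps[0].copies == pytest.approx(3.0)

    def test_planted_partial_copy_recovered(self):
        rng = random.Random(3)
        unit = _random_dna(rng, 30)
        planted = unit * 2 + unit[:15]  # 2.5 copies
        region = _random_dna(rng, 150) + planted + _random_dna(rng, 150)
        reps = find_tandem_repeats(region)
        assert reps, "planted repeat not found"
        hit = max(reps, key=lambda r: r.length)
        # maximal-run reporting may absorb a few matching flank positions
        assert abs(hit.start - 151) <= hit.period
        assert hit.start + hit.length >= 151 + 75  # planted span covered
        assert hit.copies >= 2.0 and hit.identity >= 0.85

    @pytest.mark.parametrize("seed", range(6))
    def test_clean_random_region_empty(self, seed):
        rng = random.Random(1000 + seed)
        region = _random_dna(rng, 800)
        assert find_tandem_repeats(region, min_identity=0.9) == []


class TestCloverleaf:
    def test_planted_arms_recovered(self):
        rng = np.random.default_rng(11)
        for k, length in enumerate((62, 67, 70, 72, 74, 75)):
            seq, geom, anticodon = generate_trna("trnK", length, rng)
            model = fold_cloverleaf(seq)
            assert model.geometry == geom, f"case {k}"
            assert model.anticodon == anticodon
            assert model.total_pairs == geom.max_pairs
            assert model.wobble_pairs == 0

    def test_d_armless_serine_flagged(self):
        rng = np.random.default_rng(12)
        seq, geom, _ = generate_trna("trnS1", 68, rng)
        model = fold_cloverleaf(seq)
        assert not model.d_present and model.d_pairs == 0

    def test_planted_gu_wobble_counted(self):
        rng = np.random.default_rng(13)
        g = next(iter(g for g in enumerate_geometries(72, CloverleafConfig())
                      if g.d_stem > 0))
        for _ in range(50):
            seq = _build_trna_seq(g, "TTT", rng, (0.25,) * 4)
            # force a G-U pair at acceptor position 1 (G...T instead of G...C)
            if seq[0] != "G":
                continue
            mutated = seq[:len(seq) - g.tail - 1] + "T" + seq[len(seq) - g.tail:]
            model = fold_cloverleaf(mutated)
            if model.geometry == g:
                assert model.wobble_pairs == 1
                assert model.wc_pairs == g.max_pairs - 1
                return
        pytest.skip("no suitable draw found")  # pragma: no cover

    def test_allowing_gu_never_lowers_objective(self):
        rng = np.random.default_rng(14)
        no_gu = CloverleafConfig(allow_gu=False)
        for _ in range(5):
            seq, _, _ = generate_trna("trnM", 69, rng)
            with_gu = fold_cloverleaf(seq).total_pairs
            without = fold_cloverleaf(seq, no_gu).total_pairs
            assert with_gu >= without

    def test_length_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="length"):
            fold_cloverleaf("ACGT" * 10)  # 40 nt
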