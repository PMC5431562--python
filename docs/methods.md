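# Methods

This note documents the models, conventions and numerical choices behind
`mitochar`, and what its synthetic-data tests do and do not establish.

## Coordinate and strand conventions

All coordinates are 1-based inclusive on the heavy (H) strand, the GenBank
convention; a feature on the light (L) strand keeps H-strand coordinates and
is reverse-complemented only when its sequence is extracted. Records are
circular by default; an origin-spanning feature is stored with end < start
and an explicit flag. Feature lists are sorted by start, ties broken by
longer span first, so downstream ledgers are deterministic. Sequence-less
records are first class: every coordinate-only statistic (lengths, spacers,
overlaps, gene order) works without a nucleotide sequence, which is how the
two packaged fixture tables are used.

Feature names are canonicalized through a synonym table covering the common
label variants (COX1/COI/cox1, ND2/nad2, CytB/cob, ATPase 6/atp6, D-loop/CR,
…). The duplicated isoacceptors require a codon-family tag: S1 = Ser(AGN)
(the D-armless one, between trnH and trnL(CUN)), S2 = Ser(UCN) (after cox1),
L1 = Leu(CUN), L2 = Leu(UUR) — the standard mitogenomics convention. Bare
"trnL"/"trnS" labels are deliberately ambiguous and rejected.

## Composition and skew

AT skew = (A − T)/(A + T), GC skew = (G − C)/(G + C). IUPAC ambiguity codes
are tallied separately and enter neither numerator nor denominator. A
zero-denominator skew is reported as undefined, never as 0. Whole-genome
skews are computed on the deposited H strand; per-gene skews on the reading
strand of each gene; concatenated classes (all PCGs, all tRNAs) on
reading-strand sequences joined in genome order. Display rounding is
half-away-from-zero, 4 decimals for skews and 1 for percentages (the
convention under which the published example values 0.0277 / −0.2925 /
51.8% are exactly reproduced); unrounded values are kept internally and in
the machine-readable summaries.

## Layout ledger

Gap = start(downstream) − end(upstream) − 1 between consecutive features of
the filtered, start-sorted list. O_L and the control region are excluded by
default: the conventionally reported trnN–trnC spacer (36/38 bp in the two
fixtures) spans O_L, and the CR is not a gene. On circular records with the
CR excluded, a final last→first entry is emitted flagged `wrap`; wrap
entries are excluded from summary totals, otherwise the CR-sized closure
would be counted as an 800+ bp "spacer". Nested features are compared to
their immediate predecessor in start order (the published per-row column is
plainly pairwise-consecutive). Gene order is summarized as a
rotation-normalized signature anchored at trnF; order comparison reports
positional differences and a breakpoint count over circular adjacency sets.

## Codon analysis

The vertebrate mitochondrial code is taken from NCBI translation table 2.
The start-codon set is {ATG, GTG} — the two initiators reported for fish
mitogenomes (the NCBI table also lists ATT/ATC, which the classifier would
flag as non-canonical rather than silently accept). Stop codons are TAA,
TAG, AGA, AGG. Incomplete-stop detection is sequence-driven: a CDS whose
length mod 3 leaves a trailing T or TA is classified `incomplete:T` /
`incomplete:TA` (polyadenylation-completed); any other trailing remainder,
or a final in-frame codon outside the stop set (e.g. an annotated "TTA"
stop, which is leucine under table 2), is reported as an `annotated:`
anomaly with a warning instead of extending the stop set. Codon usage pools
full codons over genes, excluding complete stops and incomplete tails by
default (a flag flips this; published codon totals do not state their
convention, so reports carry both). RSCU within a synonymous family with
zero total is undefined (blank), not 0.

## Motif and structure scanning

**CSB scan.** The consensus sequences of the teleost conserved sequence
blocks are configuration, not code: a default set ships as an editable YAML
file, clearly labelled as literature-derived approximations, because no
authoritative single consensus exists. Scanning reports the best
(fewest-mismatch, tie → leftmost) hit per motif under a per-motif mismatch
budget; ordered mode additionally enforces the canonical along-region order
(F, E, D, 1, 2, 3) by requiring strictly increasing hit starts, reporting
order-violating motifs as unplaced.

**O_L hairpin.** Exhaustive enumeration of (arm start, stem length, loop
length) with perfect-stem pairing (G–U allowed by default); ranking is
longer stem, then smaller loop, then leftmost. Note the reverse-complement
mirror symmetry of hairpins holds only for Watson–Crick pairs — a G–U pair
maps to the non-pairing A–C under reverse complement — so the symmetry
property is only asserted with wobbles disabled.

**Tandem repeats.** A deliberately simple shifted-self-identity scan (the
probabilistic model of Tandem Repeats Finder is out of scope): for each
period p, maximal runs of the match profile `s[i] == s[i+p]` whose running
identity stays above the threshold are reported when they span ≥ 2 copies
and ≥ 24 bp in total (defaults: period 2–60, identity ≥ 0.85). The 24 bp
floor is what keeps clean random control-region-sized sequences empty at
the default thresholds; maximal-run reporting may absorb a few matching
flank positions, so recovery tests assert that the planted span is covered
rather than exact boundaries.

**Cloverleaf folding.** A constrained template matcher, not thermodynamic
folding (no equivalence with RNAstructure is claimed). All feasible arm
layouts within configured bounds (acceptor 7 bp; D stem 3–4 bp or absent; D
loop 4–12 nt; anticodon stem 5 bp, loop 7 nt; variable loop 3–23 nt; T stem
4–5 bp, loop 5–9 nt; 3′ tail 0–4 nt) are enumerated for the given sequence
length; the objective is maximal paired bases with G–U wobbles permitted
and counted separately, ties broken by more Watson–Crick pairs, then by
canonical-geometry-first enumeration order (dimensions closest to the
canonical cloverleaf are tried first, which makes tie-breaking biologically
sensible and deterministic). A D-stem placement counts only when it pairs at
least 3 bases; otherwise the D region is modelled as a plain loop and the
arm reported absent — the mitochondrial trnS(AGN) case.

## Supermatrix

Center-star multiple alignment replaces an external aligner: the center is
the sequence minimizing summed pairwise 2-mer-profile distance (tie →
taxon label order), every sequence is globally aligned to it with a
hand-written Gotoh affine-gap DP (default BLOSUM62, gap open 10, extend 1;
a gap of length L costs open + (L−1)·extend, matching the convention of
Biopython's PairwiseAligner, which serves as the independent oracle in
tests), and pairwise alignments merge under "once a gap, always a gap".
This is adequate for closely related mitochondrial proteins; no column
masking is applied, which is a divergence risk when comparing against
published filtered alignments. Incomplete stop tails and complete stop
codons are dropped before translation. Back-translation expands each
residue column to its source codon ("---" for gaps) and round-trips to the
input CDS. p-distances ignore columns with gaps or ambiguity in either
sequence. Neighbor joining uses the standard Q criterion with ties resolved
to the lexicographically smallest label pair and negative branch lengths
clamped to zero with a warning; NJ is exact on additive matrices, which is
the basis of its property tests. Tree inference beyond NJ (ML/BI, model
selection) is out of scope; relaxed-PHYLIP/FASTA/NEXUS exports (with a
partition block) feed external engines.

## Synthetic data

The generator realizes a `GenerationPlan` — gene order, per-feature lengths,
signed inter-feature gaps, base-composition targets, codon bias, planted
motifs and arm layouts — into an annotated sequence plus a `TruthManifest`
recording every planted fact and the realized (not target) base counts.
One explicit seed governs all sampling; the same seed yields byte-identical
output.

The default plan mirrors a typical scorpaeniform genome: the canonical
37-gene order and strand assignment, fixture-derived feature lengths, the
published positive spacers (65 bp over 11 regions), composition targets
equal to the published H-strand base frequencies, and a 20 bp rRNA/tRNA
overlap at rrnL/trnL2. Other real-genome overlaps (PCG–PCG, tRNA–tRNA,
1–10 bp) are planned as abutting instead: an overlap would force two
planted reading frames or stems onto shared bases, and the generator's
contract is that every planted structural fact is exactly recoverable.
Under arbitrary user plans, later-starting features overwrite earlier ones
in overlap zones and structural truths are guaranteed only for undamaged
features. PCG body codons are drawn with weights equal to the product of
the target base proportions (stops excluded), so realized whole-genome A+T
tracks the target to within about one percentage point — the residual
shortfall comes from excluding the AT-rich stop codons.

Planted structures are made unambiguous by bounded rejection sampling: a
drawn tRNA (or O_L region, or control region) is re-drawn, up to a fixed
retry budget, when the corresponding scanner would not recover the planted
truth uniquely — e.g. a random D-region loop containing a spurious D stem,
or a random control-region window happening to out-score a planted CSB.
The manifest always records planted values, never scanner output; scanner
correctness is established independently on constructed cases and
brute-force oracles. Consequence for interpretation: a green
planted-recovery test establishes that the scanners invert the generator on
unambiguous inputs, not that they resolve genuinely ambiguous real
sequences.

Clade simulation evolves each CDS independently under Jukes–Cantor (per
branch of length d, a site mutates with probability (3/4)(1 − e^(−4d/3)) to
a uniform different base); there are no indels, no rate heterogeneity and
no realistic substitution model — it exists to give NJ and the supermatrix
a known true topology.

## Known limitations

* The published annotation tables contain internal inconsistencies
  (overlap totals, PCG and rRNA length sums, a reshuffled percentage
  column); the fixtures transcribe coordinates as printed, analyses report
  what coordinates imply, and the affected quantities are excluded from
  golden tests (documented in `src/mitochar/fixtures/README.md`).
* Quantities requiring the deposited nucleotide sequences (exact RSCU
  values, codon totals, control-region A+T contents) cannot be reproduced
  offline and are covered by property-based tests on synthetic data
  instead.
* The cloverleaf matcher scores pairings, not free energies; the tandem
  repeat scan is a screen, not a TRF replacement; star alignment is not a
  progressive aligner.
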