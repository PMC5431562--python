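# Default control-region motif set for teleost mitogenomes.
#
# These IUPAC consensus strings are literature-derived APPROXIMATIONS of the
# teleost conserved sequence blocks (the CSBs vary across lineages and no
# single authoritative consensus exists). They are editable configuration,
# not measured data: replace this file (or pass --motifs) to use a different
# set. Order below is the canonical along-region order (central conserved
# domain F, E, D, then the CSB domain 1, 2, 3).
motifs:
  - name: CSB-F
    consensus: ATGTAYTAYTAYGTACAT
    max_mismatches: 3
  - name: CSB-E
    consensus: CRAGGGGRAAGGGG
    max_mismatches: 2
  - name: CSB-D
    consensus: TCTTATYGGCATCTGGT
    max_mismatches: 3
  - name: CSB-1
    consensus: TTTATTAGACATAWMTG
    max_mismatches: 3
  - name: CSB-2
    consensus: CAAACCCCCCTACCCCC
    max_mismatches: 3
  - name: CSB-3
    consensus: TGCCAAACCCCAAAAACA
    max_mismatches: 3

# The thermostable-hairpin motif pair of the termination-associated region.
hairpin_motifs:
  - name: ATGTA
    consensus: ATGTA
    max_mismatches: 0
  - name: TACAT
    consensus: TACAT
    max_mismatches: 0
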