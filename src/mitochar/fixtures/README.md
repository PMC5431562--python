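# Packaged annotation fixtures

Two coordinate-only feature tables for the mitogenomes of the gurnards
*Chelidonichthys kumu* (GenBank KY379222, 16,495 bp) and *Lepidotrigla
microptera* (KY012348, 16,610 bp), transcribed from the published annotation
table of those records. They carry no nucleotide sequence; every statistic
derivable from coordinates alone (lengths, spacers, overlaps, gene order)
works on them directly.

## Transcription conventions

- Coordinates are 1-based inclusive on the H strand, exactly as printed.
- The published table labels *both* serine tRNAs "tRNA-Ser (S1)" and both
  leucine tRNAs "tRNA-Leu (L1)". Fixtures disambiguate by position using the
  standard convention: Ser(UCN) (= S2) follows cox1 on the L strand; Ser(AGN)
  (= S1, the D-armless one) lies between trnH and trnL(CUN); Leu(UUR) (= L2)
  follows 16S; Leu(CUN) (= L1) precedes nad5.
- The O_L row carries strand L (it templates L-strand synthesis) as printed.

## Known print-vs-coordinate inconsistencies (transcribed, not corrected)

- Overlap totals: the source text states a 48 bp overlap total in ten
  locations for *C. kumu*; the printed coordinates yield eleven negative
  adjacencies summing to 49 bp (the 1 bp nad4/trnH overlap is apparently
  uncounted). For *L. microptera* the text says seven overlap locations;
  coordinates yield nine (the printed per-row column shows 0 for cox3/trnG
  where the coordinates give −1).
- PCG total lengths quoted in the text (11,429 bp / 10,450 bp) do not match
  the sums of the printed per-gene coordinate spans.
- rRNA lengths quoted in the text for *C. kumu* (12S 946 bp, 16S 1,653 bp)
  differ from the coordinate spans (69–1011 = 943 bp, 1087–2799 = 1,713 bp).
- The whole-genome per-base percentages in the comparative table are ordered
  inconsistently with the running text (T% column printed as 31.13 where the
  text has T = 25.2%); the running-text counts are internally consistent with
  the printed skews and are the ones used for golden values.

Analyses in this package report what the coordinates imply; the quantities
affected by these inconsistencies are deliberately not asserted in tests.
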