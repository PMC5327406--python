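# Fixture transcription note

These tables transcribe the published comparative-genomics maps of the
DCC-containing locus in birds at gene-order resolution.  The underlying
annotations are the public ones the field uses: human GRCh37.p13 (Ensembl 83),
duck BGI_duck_1.0 (Ensembl 83), chicken Gallus_gallus-5.0 (NCBI 103), ostrich
ASM69896v1 (NCBI 100), zebra finch Taeniopygia_guttata-3.2.4 (Ensembl 67).

## reference_locus.tsv

The 31-gene reference segment in the ancestral (human/duck-like) arrangement:
9 upstream flank genes (LMAN1..TCF4), the 17-gene segment CCD68..MYO5B that is
disrupted in Galliformes and subsets of Passeriformes, and 5 downstream flank
genes (ACAA2..CTIF).

Caveats, marked `reconstructed`:

- 14 of the 17 segment genes are named in the source text (CCD68, CCD86,
  RAB27B, DYNAP, C18OF54, STARD6, POLI, MBD2, DCC, MEX3C, SMAD4, ME2, SKA1,
  MYO5B).  The remaining three — **ELAC1, MAPK4, MRO** — were reconstructed
  from the human GRCh37 18q21 annotation, which places them between SMAD4 and
  SKA1.  Their exact order relative to ME2 is likewise taken from GRCh37.
- The position of CCD86 (adjacent to CCD68) is reconstructed; the source names
  the gene but not its neighbours.
- Strands are set to `+` throughout: per-gene orientations are drawn in the
  source figure panels but are not recoverable from text, and no downstream
  computation in the worked example depends on reference strand.
- Coordinates are synthetic spacer coordinates (5 kb genes every 10 kb); only
  order and scaffold membership are meaningful.

## chicken.tsv, turkey.tsv

Chicken Z-chromosome arrangement after the locus disruption: both flank blocks
retained, with the downstream flank (ACAA2..CTIF) inverted — the rearrangement
that brought the remainder of the locus toward the telomere.  The five
salvaged genes (DYNAP, MBD2, ME2, SMAD4, SKA1) sit on short scaffolds
(`scaffold_A` carries two of them, matching "scaffolds containing only one or
two genes"); all other segment genes are absent.  Turkey mirrors chicken with
the salvaged genes on singleton scaffolds.  Scaffold ids and coordinates are
synthetic placeholders; the transcription is at presence/arrangement level.

## detection_matrix.tsv

Gene x species matrix of the first evidence tier at which each gene was
detected (`annotation`, `assembly`, `reads`) or `absent`.  Transcribed facts:
10 of the 17 segment genes undetected in all four Galliformes; the five
salvaged genes detected in every Galliform; CCD68 detected only in turkey and
MYO5B only in guineafowl among Galliformes; CCD86, RAB27B, C18OF54, STARD6,
POLI undetected in the Passeriformes shown; DCC undetected in zebra finch and
ground finch; MBD2 and SMAD4..MYO5B detected in all Passeriformes shown.
Tier assignments for quail/guineafowl salvaged genes (`reads`) reflect their
transcriptomic-only evidence.  Entries not fixed by the source prose
(e.g. zebra finch CCD68) default to `absent` and are marked reconstructed by
this note.

## table1.tsv

Species survey of target-gene (DCC) detectability: best assembly hit with the
canonical bait, raw genomic read search, and transcriptome search, for all 20
surveyed species; values transcribed verbatim (`none_available` where the
source had no data set of that kind).
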