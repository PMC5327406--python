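# locusdrift

Diagnosing gene loss, locus disruption, and accelerated evolution of
"salvaged" genes across a species phylogeny.

When a conserved multi-gene locus is disrupted — say by an inversion near a
telomere — its genes meet one of three fates: they stay in place
(*retained*), they survive but relocate out of their ancestral syntenic
context onto short scaffolds (*salvaged*), or they become undetectable
(*lost*).  The motivating case is the DCC-containing locus in birds: a
17-gene segment (CCD68..MYO5B) disrupted independently in Galliformes and in
subsets of Passeriformes, with DCC itself undetectable in chicken and zebra
finch while five salvaged neighbours (DYNAP, MBD2, ME2, SMAD4, SKA1) show
significantly elevated substitution rates.

`locusdrift` implements the full inference chain as a tested Python package,
for comparative genomicists who want these calls to be reproducible rather
than hand-curated:

- **homology** — a three-tier presence/absence cascade (annotation lookup;
  translated Smith-Waterman search of assemblies under a relaxed bit-score
  floor; raw-read retrieval + greedy assembly), with paralog filtering
  (> 40 nt and > 95% identity to the paralog discards a contig) and
  orthology verification (identity > 75% accepts; a fast evolver with
  JC69-corrected divergence > 0.4 substitutions/site needs a consistent
  top-k best-hit vote and ≥ 20 aligned aa).
- **synteny** — signed gene-order comparison: synteny blocks, inversion
  intervals, breakpoints, the maximal disrupted segment, and per-gene fate
  calls.
- **substmap** — gap-column trimming, percent identity/similarity
  (BLOSUM62), Fitch-parsimony ancestral reconstruction, and
  conservative/non-conservative substitution maps.
- **rates** — Felsenstein-pruning branch-length fitting under JC69/K80 on a
  fixed topology, the root-to-tip rate statistic
  (substitutions/site from the ingroup ancestor to each tip), and the
  normality-gated group comparison (D'Agostino-Pearson, then pooled t-test
  or Mann-Whitney U).
- **sim** — a locus-evolution simulator (branch-specific inversion +
  loss/salvage events, post-salvage rate multiplier ρ, indel-free JC69/K80
  sequences, shotgun reads) with a ground-truth event log, so every stage is
  validated by recovery tests.

See `docs/methods.md` for models, assumptions, thresholds and design
decisions.

## Worked example 1: the bundled locus fixtures

The package ships checksummed transcriptions of the bird DCC-locus maps
(reference order, chicken/turkey gene orders, detection matrix).  Running
the fate classifier on them:

```bash
locusdrift run --fixture --out demo/
```

prints (abridged):

```json
{
  "disrupted_segment_size": 17,
  "disrupted_segment_genes": ["CCD68", "...", "MYO5B"],
  "undetected_in_all_galliformes": ["CCD86", "RAB27B", "C18OF54", "STARD6",
                                    "POLI", "DCC", "MEX3C", "ELAC1", "MRO",
                                    "MAPK4"],
  "salvaged_in_all_galliformes": ["DYNAP", "MBD2", "SMAD4", "ME2", "SKA1"],
  "inversions_chicken": [[26, 30]]
}
```

Reading: in chicken, the maximal run of reference genes with no conserved
ancestral adjacency spans 17 genes (CCD68..MYO5B); 10 of those 17 are
undetected in all four Galliformes; 5 are salvaged in all four; and the
downstream flank block (reference indices 26–30, ACAA2..CTIF) is inverted —
the rearrangement that carried the remaining locus toward the telomere.

## Worked example 2: a synthetic scenario with ground truth

```python
from locusdrift.pipeline import RunConfig, run_pipeline
from locusdrift.sim import default_config

cfg = RunConfig(sim=default_config(seed=11), seed=11,
                rate_genes=None)   # None = fit every gene (slow); pass a list to restrict
report = run_pipeline(cfg)
print(report.recovery)
```

On a small variant of the reference scenario (6-gene locus, 900-nt genes,
one forced disruption on the galliform stem branch, ρ = 3, seed 11) this
prints:

```
{'detection': {'tp': 58, 'fp': 0, 'fn': 0, 'tn': 2,
               'precision': 1.0, 'recall': 1.0},
 'fate_accuracy': 1.0}
salvaged_vs_outside_locus  test: mannwhitney  p = 1.486e-05
                           means: 0.270 vs 0.164  (n = 6 vs 18)
```

Reading: every truly present gene was detected and every truly lost gene was
not (precision = recall = 1.0); every per-gene fate call matched the
simulator's event log; and the salvaged genes' root-to-tip rates (mean 0.270
substitutions/site) are significantly higher than the flanking intact genes'
(0.164), recovering the planted ρ = 3 rate elevation.

## Command-line interface

`locusdrift` exposes thin verbs over the library: `simulate` (synthetic data
with truth log), `detect` (cascade on real genome tables/FASTA/FASTQ),
`synteny` (fate calls for a target vs a reference order), `substmap`
(ancestral reconstruction and substitution maps), `rates` (branch lengths
and group comparisons), `run` (full synthetic pipeline or `--fixture` mode),
and `config` (print every threshold and simulator default).

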