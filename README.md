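# tractvar

Position-resolved mutation analysis of mononucleotide repeats (A-tracts
and G-tracts) in reference genomes.

Mononucleotide repeats — maximal runs of A:T ("A-tracts") or G:C
("G-tracts") base pairs — are among the most mutable sequences in
vertebrate genomes, yet the base pairs *within* a run are not equally
mutable: single-nucleotide variants and insertions/deletions concentrate
at specific positions (the first and last base pairs of A-tracts, the
second/third of G-tracts), point in the direction of the flanking base,
and vary with tract length, flanking sequence and position along
nucleosomes.  `tractvar` is a library and CLI for quantifying exactly
these patterns from a FASTA reference and a VCF call set, for population
geneticists and mutational-signature analysts who need
census-normalized, strand-aware, position-resolved repeat statistics.

## What it computes

All positions are expressed on the **purine strand** (the strand where
the run reads A^n or G^n), numbered 1..n with the 5' flank at 0 and the
3' flank at n+1. For a stratum of N genomic tracts of class c and
length n:

- **F SNV** = (# tract SNVs) / (N·n) — the normalized fraction of
  polymorphic tracts, per (class, length).
- **Positional spectra** — % SNVs per position and substitution type,
  (#SNVs at p) / N × 100, optionally conditioned on flank bases with
  matching flank-conditioned denominators.
- **Slippage** — single-base indels that change the run length by ±1
  and leave the flanking base composition intact (decided operationally
  by applying the edit and re-scanning): F slip = events/(N·n) and the
  +1/−1 ratio.
- **F Indel** — all other 1–200 bp insertions/deletions touching the
  tract or its flanks: events/(N·n) along the tract, events/N at the
  flanking positions; plus the insertion-junction matrix over
  junctions 0..n+1.
- **Nucleosome phasing** — tract counts versus distance d from the
  nucleosome dyad (d ∈ [−73, 73]), extrema-stratified SNV comparisons
  with paired t-tests, the C-containing/G-containing orientation ratio
  of G-tracts, loess smoothing (span 0.100, degree 3), and the dominant
  rotational period (~10.5 bp helical repeat) with a permutation test.
- **Step flexibility** — from tabulated base-pair-step parameter
  trajectories (shift, slide, rise, tilt, roll, twist):
  V_step = ∏ᵢ√λᵢ = √det Σ of the 6×6 step-parameter covariance, plus
  phosphate-distance groove widths and minor-groove water-bridge
  occupancies.

A synthetic-data generator (`tractvar.simulate`) plants maximal tracts
with controlled composition in run-free backgrounds and draws variants,
nucleosome placements and step-parameter ensembles from known
parameters, with truth tables, so every stage is verifiable without
genome-scale downloads.

## Worked example

```python
from tractvar import (scan_sequence, build_census, map_variants,
                      f_snv_table, slippage_stats)
from tractvar import simulate as sim

# 8,000 planted tracts (200 per class/length/flank stratum) + variants
genome, truth = sim.simulate_genome(sim.default_placements(200), seed=42)
variants, _ = sim.simulate_variants(genome, truth, seed=43)

tracts = sorted(scan_sequence("synth1", genome["synth1"]),
                key=lambda t: (t.chrom, t.start))
census = build_census(tracts)
assignments = map_variants(tracts, variants, genome)

fsnv = f_snv_table(assignments, census)
print(fsnv[fsnv.tract_class == "G"].to_string(index=False))
```

```
tract_class  n  count  denominator    f_snv
          G  4     19          400 0.011875
          G  5     27          400 0.013500
          G  6     47          400 0.019583
          G  7     94          400 0.033571
          G  8    105          400 0.032813
          G  9     84          400 0.023333
          G 10     67          400 0.016750
          G 11     54          400 0.012273
          G 12     46          400 0.009583
          G 13     51          400 0.009808
```

F SNV is bell-shaped over tract length, peaking near n = 7–8 for
G-tracts — the generator's default hotspot bell, recovered by the
pipeline. Slippage shows the same shape on its own scale, with +1
events outnumbering −1:

```python
slip = slippage_stats(assignments, census)
print(slip[slip.tract_class == "A"][["n", "f_slip", "plus_minus_ratio"]]
      .round(4).to_string(index=False))
```

```
 n  f_slip  plus_minus_ratio
 4  0.0006            0.0000
 5  0.0035            2.5000
 6  0.0058            0.7500
 7  0.0154            1.8667
 8  0.0222            1.5357
 9  0.0172            4.1667
10  0.0058            2.8333
11  0.0030            2.2500
12  0.0012            2.0000
13  0.0000               NaN
```

F slip peaks at n = 8 (the configured bell peak) at ~0.02, and the
ratio column shows the +1 excess (missing where no −1 event was seen).

The same analyses run from the shell:

```bash
tractvar simulate --seed 5 --outdir sim/
tractvar spectra --fasta sim/genome.fa --vcf sim/variants.vcf --outdir out/
tractvar ncp --fasta sim/genome.fa --midpoints-bed sim/midpoints.bed --outdir out/
```

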