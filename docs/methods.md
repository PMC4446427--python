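# Methods

## Tract model

A tract is a maximal run of one base, length 4–13 bp, on either strand;
it is classified A (A:T run) or G (G:C run) and annotated with the
strand on which it reads as a purine run. All positional quantities are
expressed on that purine strand: interior positions 1..n from the 5'
end, the flanking bases at 0 and n+1. For a run of T or C on the
forward strand, coordinates and substitutions are reverse-complemented
into purine-strand terms, which makes A- and T-runs (and G- and C-runs)
a single strand-symmetric class.

Scanner conventions, chosen once and applied everywhere:

- Runs longer than 13 bp are excluded entirely, not truncated to 13;
  tract maximality is part of the definition and a truncated 13-mer
  inside a longer run is not a maximal tract.
- Runs abutting a sequence end are excluded: the data model requires
  both flank bases to exist.
- Characters outside {A,C,G,T} are mapped to N; N never extends a run.
  Tracts with an N flank stay in the per-(class, n) census marginals
  but are excluded from flank-conditioned strata and direction-bias
  analyses.
- Coordinates are 0-based half-open internally (BED-style); VCF input
  is 1-based. The purine-strand position of a forward coordinate x is
  p = x − start + 1 on '+' tracts and p = end − x on '−' tracts.

Census comparisons between two sequence sets normalize each census to
per-class proportions over n = 4–13 before differencing, so that sets
covering different total sequence lengths are comparable; raw-count
comparison is available as an option. Census restriction by a region
mask requires whole-tract containment, because the tract — not the base
pair — is the unit of normalization.

## Variant classification

Raw VCF records are split into biallelic records, parsimony-trimmed and
left-aligned (the standard normalization loop: right-trim shared
suffixes, extending left through the reference when an allele empties,
then left-trim to one anchor base). In homopolymers left-alignment
makes the placement of an indel canonical but arbitrary; junction
indices for insertions therefore refer to the leftmost equivalent
placement. Records failing the reference check are dropped with a
warning; duplicates are removed on (chrom, pos, ref, alt). Sites are
counted once each — allele frequencies and genotypes are ignored.

Events are assigned to a tract in three mutually exclusive categories:

- **SNVs** at forward coordinates [start−1, end] become positional
  tract SNVs (p in 1..n) or flank SNVs (p in {0, n+1}), with the
  substitution complemented onto the purine strand. A flank SNV whose
  alternate equals the tract base is flagged `extends_tract`; a G-tract
  SNV at p = 1 with a 5' C flank is flagged `cpg_context`
  (methylation-mediated deamination territory).
- **Slippage**: a 1-bp indel is classified by *apply-and-rescan* — the
  edit is applied to the local reference window and the containing
  maximal run re-measured. If a same-base run of length n±1 remains
  with both flanking base identities unchanged, the event is
  slippage (+1 or −1). This operational definition handles every edge
  case (run splits, run merges, flank replacement) uniformly.
- **Indels**: any other insertion/deletion of 1–200 bp whose span or
  breakpoint touches [start−1, end]. Insertions carry a junction index
  j in 0..n+1 (j = 0 between the 5' flank and the first base);
  deletions carry a location class before_tract / in_tract /
  after_tract on the purine strand, because left-alignment makes a
  within-run deletion position arbitrary. For indel-fraction tables,
  insertions at j = 0 count as before_tract and at j ≥ n as
  after_tract.

A 1-bp tract-base indel is only ever slippage, never double-counted as
an indel; the two analyses are disjoint.

## Normalized statistics

Every statistic is an exact count/denominator ratio (see README for
the formulas). Two conventions matter:

- Flank-conditioned spectra divide by the matching flank-conditioned
  census stratum, never the class total.
- Positional percents count SNV events by default (a tract hit twice
  at one position contributes twice); a per-tract option counts
  distinct tracts instead. Ratios with zero denominators are reported
  as missing, never as infinities.

Dataset equalization rescales one spectrum table so its total percent
at an anchor stratum (class, n = 4 by default) matches another's,
which puts call sets of very different depth on a common scale.

## Nucleosome phasing

Tract centers (left-of-center base for even lengths — deterministic
and documented) are paired with nucleosome midpoints within ±73 bp;
d = center − midpoint. A tract near several midpoints contributes to
each by default (an option keeps only the nearest). Extrema of the
(optionally moving-average-smoothed) dyad profile are strict local
extrema with near-equal values (relative tolerance 1e-9) treated as
plateaus resolved toward the dyad, so analytically flat-topped cosine
peaks resolve deterministically.

Maxima/minima comparisons compute %SNV per tract position separately
at each extremum site, pair the k-th maximum with the k-th minimum
ordered along the particle, and report per-position paired t-tests
(raw and Benjamini–Hochberg-adjusted) plus an overall paired test on
site-mean %SNV. The orientation ratio divides C-forward by G-forward
G-tract counts per d. Loess smoothing is a tricube-weighted local
polynomial fit, default span 0.100 and degree 3, written in-package
because available lowess implementations are first-degree only.

The period estimator evaluates the mean-subtracted periodogram on a
dense period grid in [8, 13] bp, refines the maximum by quadratic
interpolation, and assesses significance by permuting positions
(1,000 shuffles, seedable). The minor-groove-inward/iSAT annotation
shipped under `tractvar/data/` is a synthetic 10.5-bp periodic
stand-in and should be replaced with a crystal-structure-derived table
for real-data work.

## Structure statistics

V_step = ∏√λᵢ over the eigenvalues of the 6×6 unbiased (n−1) sample
covariance of the step parameters, which equals √det Σ exactly; a
rank-deficient covariance (fewer than 7 frames) yields 0 with a
warning. Groove widths are frame-wise phosphate–phosphate distances
under a configurable pairing convention — cross-strand with residue
offset (default 3) or within-strand — with an optional constant
subtraction; the default is cross-strand with no subtraction, the
convention that matches observed ~14 Å G-tract values, and the choice
is recorded in the output. Bridging-water inputs are pre-tabulated
per-frame counts; identifying waters from trajectories is out of
scope, as is running or parsing MD itself.

## Synthetic data: what it emulates and what it does not

The generator plants tracts with exact composition in a background
that contains no same-base run of 4+ and never extends a planted run,
so scan output and truth coincide exactly. Variants are drawn per
tract:

- positional SNV rate = 0.01 × weight, with a 10-fold hotspot at
  positions {1, n} (A) or {2, 3} (G), modulated over length by a
  Gaussian bell (peak 9 for A, 8 for G, σ = 1.5) — mirroring the
  edge/5'-half contrast the statistics are designed to detect;
- A-tract alternates point at the nearer flank with probability
  θ = 0.9, else uniform over the three non-tract bases; G-tract
  alternates follow weights (G→T 0.45, G→C 0.35, G→A 0.20);
- slippage probability = n × h·bell(n) with h = 0.02 and peaks at
  n = 8 (A) and 9 (G), so the configured peak is the argmax of F slip
  (≈0.02 at its peak); the +1:−1 odds are 2:1;
- indel probabilities are zero below n = 7 and constant on the
  F-Indel scale above it (0.003 for A, 0.03 for G in-tract), with
  ≥2-bp run deletions and run-splitting insertions so categories are
  unambiguous by construction; flank-adjacent events that would merge
  runs are rejected.

Nucleosome placements draw dyad offsets from 1 + a·cos(2πd/P)
(defaults P = 10.5 bp, a = 0.5) and can bias which strand orientation
is paired at each offset; the one-midpoint-per-tract mode emulates
uniquely well-positioned nucleosomes. Genomes destined for nucleosome
analyses use 150–250 bp separations so each midpoint pairs with a
single tract; spectra genomes use 5–20 bp.

What the generator does **not** emulate: real base composition and
repeat landscape, linkage and haplotype structure, sequencing error,
mutation-rate heterogeneity beyond the modeled profiles, and selection.
Passing recovery tests therefore demonstrates that the estimators
measure what they claim on data satisfying the model's assumptions —
not that real genomes satisfy them.

## Recovery experiments and problem sizes

Two canonical experiments (`tractvar.recovery`) back the acceptance
checks: (1) 100,000 planted tracts (2,500 per class/length/flank-pair
stratum) through the full spectra pipeline, recovering the positional
profile (Pearson r), θ, and the slippage peak lengths; (2) 20,000
length-5 A-tracts with one midpoint each, cosine amplitude 0.5, and a
20% SNV excess injected at rotational minima, recovering the period
and the minima-vs-maxima paired t-test. These sizes give standard
errors comfortably inside the tolerances tested (e.g. θ's standard
error ≈ 0.005 against a ±0.03 band) while keeping the whole suite
fast.

## Known limitations

- Insertion junctions reflect leftmost placement; call sets normalized
  differently (or unnormalized) will shift junction histograms within
  runs. An as-reported pass-through exists (skip normalization) but
  mixes conventions.
- The paired-extrema t-test assumes site-level %SNV values are
  approximately exchangeable across the particle; strong per-site
  coverage differences would violate this.
- The periodogram assumes an integer-spaced, mostly complete profile;
  profiles with large gaps should be smoothed or masked first.
- Groove-width output depends on the pairing convention; comparisons
  across studies must match conventions (and any radius subtraction),
  which is why both are explicit parameters recorded in the output.
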