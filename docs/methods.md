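# Methods

## The positional model

All analyses rest on one quantity per gene: its distance, in bp, from the
midpoint of its ORF to the nearest transcription initiation site in the
correct orientation. "Correct orientation" means the site could have
launched the polymerase that transcribes the gene: for a forward-strand
gene, the forward-firing site with the largest position ≤ the midpoint;
for a reverse-strand gene, the reverse-firing site with the smallest
position ≥ the midpoint. Bidirectional sites (divergent strand-switch
regions) count for both strands. A site exactly at the midpoint anchors at
distance 0 for either direction it fires — the limiting case of the
upstream rule.

When no correct-orientation site is mapped between the gene and the end of
the assembled sequence, that sequence end is assumed to hold a putative
initiation site: distance = midpoint − 1 for a forward gene (measured from
coordinate 1) and chromosome length − midpoint for a reverse gene. No gene
is ever excluded for lacking a mapped site; the fallback is recorded in the
output (`fallback` column) so downstream users can stratify on it.

Coordinates are kept 1-based inclusive (the GFF3 frame) end to end; the
midpoint is `floor((start + end) / 2)`. Sites strictly downstream of a
forward gene's midpoint are never anchors, even when closer in absolute
terms.

### Gene-class filters

Pseudogenes, variant surface glycoproteins, expression-site-associated
genes and dispersed multi-copy families (e.g. retrotransposon hot spot
protein, GRESAG4) are removed before every positional calculation: the
first three are not RNAP II transcribed or not interpretable positionally,
and for multi-copy families expression measurements cannot be assigned to
an originating locus. Detection is by case-insensitive keyword match
against the product description (shipped defaults in
`polypos/data/gene_class_keywords.yaml`, fully overridable) plus the GFF3
`pseudogene` feature type. This is a reproducible, auditable stand-in for
whatever curated lists the original datasets used; no homology clustering
is attempted.

## Monte Carlo positional tests

A gene group's positional bias is judged against random groups of the same
size drawn without replacement from a universe of genes with distances.
Two statistics are used:

- **Group mean-distance test** (heat-shock up/down sets): both tail
  proportions are reported — trials with mean ≥ the observed mean and
  trials with mean ≤ it, ties counting toward each tail (the conservative
  convention). The headline p is the smaller tail, with the side recorded.
- **Category score** (GO scan): the proportion of trials whose mean is
  *strictly greater* than the category mean, so a score near 1 means
  proximal bias and near 0 distal. Ties do not count toward the score; tie
  probability is negligible for integer bp distances and real group sizes.
  Scores ≥ 0.99 / ≤ 0.01 are flagged — the original decision rule, applied
  without multiple-testing correction, and reported as such.

Default trial count is 10 000 everywhere, seedable. When
C(universe, group) ≤ 100 000 an exact-enumeration mode can replace
sampling (`method="exact"` or `"auto"`); the two routes agree within
binomial sampling error and the exact route doubles as the test oracle.
Sampling is vectorised (per-trial argpartition of a uniform matrix,
chunked to bound memory under ~160 MB).

### Structure-preserving null

GO categories overlap, so naive per-category randomization misstates the
joint null. Instead, one uniformly random bijection of the annotated gene
set is drawn per replicate and every category is mapped through it: a gene
shared between categories maps to the same random gene everywhere, so all
category sizes and all pairwise intersection sizes are preserved exactly
while positional information is destroyed. The expected score histogram
(20 equal bins on [0, 1], right-closed) and its per-bin standard error are
averaged over 100 replicates.

Two universes are involved and deliberately configurable: the resampling
universe for scoring (default: all filtered genes with distances) and the
randomization universe (default: the GO-annotated gene set). For the null
*calibration* the scoring universe must be the annotated set itself —
scores are exactly uniform under the null only when random groups are
drawn from the same pool the bijection permutes. Scoring calibration
replicates against the full gene set instead inherits the annotated
subset's fixed chance positional offset and tilts every replicate the same
way; with matched universes the measured calibration is flat (per-bin
|z| < 2, tails ≈ 1% per flag threshold).

## Heat-shock analysis

Responsive sets use inclusive twofold boundaries (FC ≥ 2 up, FC ≤ 0.5
down). Rank correlation uses midranks for ties with two-sided p-values.
Pearson correlation is computed on log2 fold change (symmetric in up/down;
the raw-scale coefficient is also emitted for transparency). A constant
input makes the correlation undefined and it is reported as NaN, never
as 0. Distance histograms use half-open 20-kbp bins `[k·w, (k+1)·w)` with
the final bin closed at the maximum observed distance.

## Cell-cycle sliding window

Genes are anchored by distance (midpoint-derived, not gene-body overlap)
and pooled across all transcription units. Windows are `[w, w + 20 kbp)`
advanced in 1-kbp steps from 0 to the maximum distance. Per window and
stage, abundances are averaged over member genes on the linear scale, and
the log2 ratio taken against the mean of the four stage means (log of the
ratio of means, not mean of logs). Windows with fewer than `min_genes`
(default 5) genes carry NaN and trailing windows beyond the last
qualifying offset are truncated — tail windows otherwise contain single
genes and dominate the profile. An optional per-gene-normalized mode
divides each gene's four values by their own mean first; the raw mode is
the default and is deliberately not invariant to per-gene scaling.

**Recovering a planted trend.** A per-stage log-linear trend
`2^(slope_s · d)` cannot appear as an exactly linear log2-ratio curve:
every stage's ratio subtracts the same `log2(mean_s 2^(slope_s · d))`
term, which is convex in d and biases a raw straight-line fit of the
late-G1 curve to ~0.83 of the planted slope over the 0–150 kb design
range. The estimator used for recovery is therefore the stage's fitted
slope *minus the across-stage mean of fitted slopes*, which cancels the
shared term exactly and is unbiased for the planted slope contrast
(`recovered_stage_slope`). Fits are restricted to the 0–150 kb range the
planted effect is defined on.

## Run-off model

Parameters: elongation rate v (default 4.3 kb/min, the mammalian
estimate — no trypanosome measurement exists), first-order decay rate k
(default ln 2/30 min⁻¹, an explicit placeholder: no decay rates are
modelled from data), pre-shock production rate p0 (arbitrary units),
pause_factor ≥ 1 multiplying the journey time, and an optional residual
initiation fraction r (default 0 = full stop at onset).

Pre-shock steady state m0 = p0/k defines relative abundance 1. Production
continues until τ = pause_factor · d/v; afterwards
`m(t)/m0 = r + (1 − r)·exp(−k·(t − τ))`. The closed form is validated
against a fixed-step RK4 integrator with the discontinuity at τ inserted
as a step boundary and production held constant within each segment
(agreement ~1e-13 relative at step 0.01 min). k is held constant through
heat shock; per-mRNA turnover changes are out of scope. The model is
validated on ordering and closed-form correctness only — the published
reporter quantifications are not fitted.

## Synthetic data generator

The generator defines the study conditions for every test. It emulates:

- **Genome organization**: chromosomes tiled with alternating-strand
  polycistronic units; unit lengths log-normal with mean 150 kbp
  (σ_log = 0.5, so ~300 kbp units occur in the tail); genes ~1.5 kbp with
  ~1.3 kbp intergenic gaps (dense packing, >50% coding); one 5′ site per
  unit, realised as a forward site at the chromosome start, one
  bidirectional site per divergent strand-switch region and a reverse site
  at a trailing reverse unit's end; internal sites at a fixed count of
  round(f/(1−f) · n_5′) with f = 62/191, placed uniformly inside random
  units and firing in the unit's direction (tagged `iTSS`). ~2% of genes
  carry a removable class flag, with product descriptions that round-trip
  through the keyword classifier.
- **Heat-shock response**: log2 fold changes coupled to distance *ranks*
  through a Gaussian copula with Pearson parameter 2·sin(π·ρ/6), making
  the population Spearman correlation equal the planted ρ (default 0.5)
  exactly regardless of the distance distribution's shape; log2 scale
  sd 1.2, so ~20% of genes pass the twofold threshold in each direction.
- **GO structure**: 30 background terms of 10–40 genes drawn disjoint,
  plus one proximal and one distal planted term (30 genes from the
  nearest/farthest distance decile); overlaps injected by swapping a
  `go_overlap_rate` fraction (default 0.1) of each background term's
  members with its predecessor's, so rate 0 yields exactly disjoint terms
  and planted terms stay positionally pure.
- **Cell cycle**: per-gene stage abundance
  baseline · 2^(slope_s·d) · 2^noise with log-normal baselines (mean 100),
  log2 noise sd 0.25, and default slopes (0, +1/150 kb, −1/150 kb, 0) for
  (early G1, late G1, S, G2/M) — the late-G1 trend spans one log2 unit
  over 0–150 kb, mirroring the effect the window analysis targets.

All generators are bit-reproducible under a seed (independent child
streams per product). What they do **not** emulate: probe-level structure,
sequence content, chromosome-scale heterogeneity of gene density,
correlated noise between stages, GO term hierarchy, or any coupling
between the heat-shock and cell-cycle tables. Passing tests therefore
demonstrate correctness of the computational machinery and recoverability
of planted effects under idealized noise — not that real genomes show
these effects.

## Problem sizes and numerical choices

Tests and the acceptance script run the default generator conditions
(~1 200 genes, ~24 sites, 30 GO terms), null calibration at 100 replicates
× 1 000 trials, planted-category recovery over 50 seeds at 10 000 trials,
and Spearman recovery over 200 seeds at n = 777 — sizes chosen so the full
suite completes in about a minute while keeping Monte Carlo standard
errors well inside the tested tolerances. Flatness of the null calibration
is assessed by chi-square goodness-of-fit plus per-bin z allowances
(≥ 90% of bins within 2×SEM, all within 4×SEM): with 20 approximately
standard-normal per-bin deviations, demanding every bin within 2×SEM
would reject a correct implementation more often than not. Degenerate
inputs are hard errors, not silent defaults: empty member sets, constant
correlations, missing chromosome lengths, duplicate gene ids, unsorted
time grids, infeasible generator geometry.

## Known limitations

- Gene-class detection is keyword-based; curated lists, if available,
  should be supplied as an override.
- The distance model assigns each gene to its nearest upstream site; it
  does not classify strand-switch regions or assign transcription-unit
  identities.
- The run-off model is deterministic and single-rate; polymerase convoys,
  collisions and splicing inhibition are out of scope.
- No GO-graph propagation: memberships are used as given.
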