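# polypos

Positional analysis of genes within polycistronic transcription units.

In trypanosomatids (and several other eukaryote lineages), RNA polymerase II
transcribes tens to hundreds of protein-coding genes from a single
initiation region; individual mRNAs are resolved by trans-splicing and
polyadenylation, so selective regulation at initiation is impossible. Where
a gene sits *within* its transcription unit then becomes a regulatory
variable in its own right: when initiation shuts down under stress,
polymerases already on the template keep elongating, so genes distal to the
initiation site keep being transcribed while proximal genes go silent
within minutes. `polypos` implements the analyses that quantify this
positional layer of gene-expression control, for computational biologists
working on *Trypanosoma brucei*-like genomes or on synthetic models of
them.

## What it computes

- **Distance to initiation** — for every gene, the distance in bp from its
  ORF midpoint to the nearest transcription initiation site in the correct
  orientation (the site that could have launched the transcribing
  polymerase). Where no site is mapped upstream, the end of the assembled
  sequence stands in as a putative site.
- **Heat-shock positional bias** — genes ≥ 2-fold up-/down-regulated after
  heat shock; Spearman/Pearson correlation of fold change with distance;
  20-kbp binned distance distributions against the all-gene background; and
  a Monte Carlo test of each group's mean distance against random same-size
  gene groups drawn without replacement.
- **GO-category positional test** — for every GO category with ≥ 10
  members, the score
  `s(C) = (1/T) · #{ random groups G, |G| = |C| : mean-dist(G) > mean-dist(C) }`
  over T = 10 000 trials; s ≥ 0.99 flags proximal bias, s ≤ 0.01 distal.
  The genome-wide expectation is calibrated by a structure-preserving
  randomization: one random bijection of the annotated gene set per
  replicate, so category sizes and all pairwise overlaps are exactly
  preserved while positions are scrambled (100 replicates).
- **Cell-cycle sliding window** — a 20-kbp window moved in 1-kbp steps
  along the distance axis; per window and cell-cycle stage (early G1, late
  G1, S, G2/M), the log2 ratio of the stage's mean abundance to the mean of
  the four stage means.
- **Run-off model** — initiation stops at t = 0, elongation continues at
  v = 4.3 kb/min; a gene at distance d keeps producing until
  τ = pause_factor · d/v, after which its relative mRNA abundance decays as
  `m(t)/m0 = exp(−k·(t − τ))` (first-order decay, rate k). Distal mRNAs
  persist longer; a ~250 kbp gene keeps being transcribed for ~60 min.
- **Synthetic data** — genomes tiled with alternating-strand polycistronic
  units, initiation sites (5′, internal and bidirectional), fold-change
  tables with a planted distance–response Spearman correlation, four-stage
  cell-cycle tables with planted log-linear trends, and GO annotations with
  planted proximal/distal categories — so the whole pipeline is testable
  without downloads.

## Worked example

```python
import polypos as pp

cfg = pp.SyntheticConfig(seed=1)
genes, sites, chroms = pp.generate_genome(cfg)
kept = pp.apply_gene_filters(genes, {"pseudogene", "vsg", "esag", "multilocus"})
dists = pp.compute_all_distances(kept, sites, chroms)
print(f"{len(kept)} genes, {len(sites)} initiation sites")

expr = pp.generate_heatshock_expression(dists, cfg)
sets = pp.select_responsive(expr, threshold=2.0)
corr = pp.correlate_foldchange_distance(expr, dists, sets.up | sets.down)
print(f"up={len(sets.up)} down={len(sets.down)}  Spearman r={corr.spearman_r:.3f}")

all_h = pp.distance_histogram(dists, bin_width=20_000)
down_h = pp.distance_histogram(dists, sets.down, bin_width=20_000)
print(f"within 20 kbp: all genes {100*all_h.proportions[0]:.1f}%, "
      f"down-regulated {100*down_h.proportions[0]:.1f}%")

test = pp.group_mean_distance_test(sets.down, dists, n_trials=10_000, rng_seed=1)
print(f"down-group mean distance {test.observed_mean/1000:.1f} kbp, "
      f"lower-tail p={test.p_lower:.4f}")

tau = pp.production_time(250_000, pp.RunoffParams(v=4.3))
print(f"run-off journey time for 250 kbp: {tau:.1f} min")
```

prints

```
1161 genes, 24 initiation sites
up=235 down=219  Spearman r=0.672
within 20 kbp: all genes 18.3%, down-regulated 40.6%
down-group mean distance 34.8 kbp, lower-tail p=0.0000
run-off journey time for 250 kbp: 58.1 min
```

The generator planted a positive Spearman correlation between distance and
log2 fold change, so down-regulated genes crowd the first 20 kbp next to
initiation sites (40.6% vs the 18.3% background) and their mean distance is
far below what random gene groups achieve (no lower mean in 10 000 trials).
The journey time says a gene 250 kbp into its unit keeps being transcribed
for roughly an hour after initiation stops.

The same analyses run from the shell on GFF3/TSV inputs:

```sh
polypos synth --out-dir bundle --seed 1
polypos heatshock --gff bundle/genome.gff3 --sites bundle/sites.tsv \
    --expr bundle/heatshock_foldchange.tsv --out-dir results
polypos goscan --gff bundle/genome.gff3 --sites bundle/sites.tsv \
    --go bundle/go_annotations.tsv --out-dir results --calibrate
polypos cellcycle --gff bundle/genome.gff3 --sites bundle/sites.tsv \
    --expr bundle/cellcycle_abundance.tsv --out-dir results
polypos runoff --distance 8000 --distance 284000 --half-life 30 --out-dir results
```

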