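"""Synthetic genomes, initiation sites, expression tables and GO
annotations with known planted structure.

The generator emulates the organization the analysis targets: chromosomes
tiled with alternating-strand polycistronic transcription units, each
served by an initiation site at its 5' end (one bidirectional site per
divergent strand-switch region) plus internal sites at a configurable
fraction of all sites; genes densely packed and non-overlapping.
Expression tables carry planted effects — a target Spearman correlation
between distance and heat-shock fold change, and per-stage log-linear
distance trends for the cell cycle — and the GO annotation carries one
planted proximal and one planted distal category against a disjoint
background, so every downstream test has a known truth. All outputs are
bit-reproducible under a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

from .model import (
    FORWARD,
    REVERSE,
    STAGES,
    ChromosomeInfo,
    ExpressionTable,
    GeneDistance,
    GeneRecord,
    GOAnnotation,
    InitiationSite,
)

#: term_ids of the planted categories (recorded in the truth file too).
PROXIMAL_TERM_ID = "SYNGO:9000001"
DISTAL_TERM_ID = "SYNGO:9000002"

# products that round-trip through the default keyword classifier
_FLAG_PRODUCTS = {
    "vsg": "variant surface glycoprotein (VSG), putative",
    "esag": "expression site-associated gene (ESAG) protein",
    "multilocus": "retrotransposon hot spot protein (RHS), putative",
    "pseudogene": "hypothetical protein pseudogene",
}


@dataclass(frozen=True)
class SyntheticConfig:
    """Generator parameters; defaults describe a compact genome with the
    organization and effect sizes the analyses are designed around.

    Transcription-unit lengths are log-normal with mean ``tu_length_mean``
    (default 150 kbp, so ~300 kbp units occur in the tail); 62/191 of
    initiation sites are internal to units by default; the planted
    heat-shock effect is the target population Spearman correlation between
    distance and log2 fold change; the planted stage slopes are log2 units
    per bp (the default late-G1 slope spans one log2 unit over 150 kbp,
    with an equal and opposite S-phase slope).
    """

    n_chromosomes: int = 4
    units_per_chromosome: int = 6
    tu_length_mean: float = 150_000.0
    tu_length_sigma: float = 0.5  # sigma of log unit length
    gene_length_mean: float = 1_500.0
    gene_length_sigma: float = 0.4
    intergenic_mean: float = 1_300.0
    intergenic_sigma: float = 0.6
    internal_tss_fraction: float = 62.0 / 191.0
    flagged_fraction: float = 0.02
    n_go_terms: int = 30
    go_term_size_range: tuple[int, int] = (10, 40)
    go_overlap_rate: float = 0.1
    planted_term_size: int = 30
    planted_distance_effect: float = 0.5
    log2_fc_sd: float = 1.2
    planted_stage_slopes: tuple[float, float, float, float] = (
        0.0, 1.0 / 150_000.0, -1.0 / 150_000.0, 0.0,
    )
    cellcycle_noise_sd: float = 0.25  # sd of log2 per-value noise
    cellcycle_baseline_mean: float = 100.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.internal_tss_fraction < 1:
            raise ValueError("internal_tss_fraction must be in [0, 1)")
        if not -1 <= self.planted_distance_effect <= 1:
            raise ValueError("planted_distance_effect must be in [-1, 1]")
        if not 0 <= self.go_overlap_rate <= 1:
            raise ValueError("go_overlap_rate must be in [0, 1]")
        for f in ("tu_length_mean", "gene_length_mean", "intergenic_mean"):
            if getattr(self, f) <= 0:
                raise ValueError(f"{f} must be positive")

    def with_(self, **kw) -> "SyntheticConfig":
        return replace(self, **kw)


def _rng(config: SyntheticConfig, stream: int) -> np.random.Generator:
    # one independent stream per generated product
    return np.random.default_rng([config.seed, stream])


def _lognormal(rng: np.random.Generator, mean: float, sigma: float, size=None):
    """Log-normal draws parametrised by their arithmetic mean."""
    if sigma == 0:
        return np.full(size, mean) if size is not None else mean
    mu = math.log(mean) - sigma**2 / 2
    return rng.lognormal(mu, sigma, size)


def generate_genome(
    config: SyntheticConfig,
) -> tuple[list[GeneRecord], list[InitiationSite], list[ChromosomeInfo]]:
    """Generate chromosomes tiled with alternating-strand polycistronic
    units, the initiation sites serving them, and internal sites.

    Units alternate forward/reverse along each chromosome: the first unit's
    5' site sits at its left end, each divergent (reverse->forward) boundary
    carries one bidirectional site, and a trailing reverse unit is served
    from the chromosome's right end. The total number of internal sites is
    fixed at round(f/(1-f) * n_5' sites) so the internal fraction of all
    site records matches ``internal_tss_fraction``; internal sites are
    placed uniformly within randomly chosen units, firing in the unit's
    direction. Raises if a unit cannot fit a single gene.
    """
    rng = _rng(config, 1)
    margin, gap = 2_000, 4_000
    genes: list[GeneRecord] = []
    five_prime_sites: list[tuple[str, int, frozenset[str]]] = []
    units: list[tuple[str, int, int, str]] = []  # chrom, start, end, strand
    chroms: list[ChromosomeInfo] = []

    for ci in range(config.n_chromosomes):
        chrom = f"chr{ci + 1}"
        cursor = margin + 1
        unit_bounds: list[tuple[int, int, str]] = []
        for ui in range(config.units_per_chromosome):
            strand = FORWARD if ui % 2 == 0 else REVERSE
            length = int(
                _lognormal(rng, config.tu_length_mean, config.tu_length_sigma)
            )
            start, end = cursor, cursor + length - 1
            unit_bounds.append((start, end, strand))
            units.append((chrom, start, end, strand))

            # pack genes left to right; coordinates are strand-independent
            g_cursor = start + int(
                _lognormal(rng, config.intergenic_mean, config.intergenic_sigma)
            )
            placed = 0
            while True:
                g_len = max(
                    150,
                    int(_lognormal(rng, config.gene_length_mean, config.gene_length_sigma)),
                )
                if g_cursor + g_len - 1 > end:
                    break
                gene_id = f"SYN{ci + 1:02d}G{len(genes) + 1:05d}"
                flags: frozenset[str] = frozenset()
                product = "hypothetical protein, conserved"
                if rng.random() < config.flagged_fraction:
                    flag = rng.choice(sorted(_FLAG_PRODUCTS))
                    flags = frozenset({flag})
                    product = _FLAG_PRODUCTS[flag]
                genes.append(
                    GeneRecord(
                        gene_id=gene_id, chrom=chrom,
                        start=g_cursor, end=g_cursor + g_len - 1,
                        strand=strand, flags=flags, product=product,
                    )
                )
                placed += 1
                g_cursor += g_len + int(
                    _lognormal(rng, config.intergenic_mean, config.intergenic_sigma)
                )
            if placed == 0:
                raise ValueError(
                    f"infeasible geometry: unit of length {length} on {chrom} "
                    "cannot fit a single gene"
                )
            cursor = end + 1 + gap

        chrom_len = cursor - gap + margin
        chroms.append(ChromosomeInfo(chrom=chrom, length=chrom_len))

        # 5' sites: chromosome start, divergent boundaries, trailing reverse
        five_prime_sites.append((chrom, unit_bounds[0][0], frozenset({FORWARD})))
        for (s1, e1, st1), (s2, e2, st2) in zip(unit_bounds, unit_bounds[1:]):
            if st1 == REVERSE and st2 == FORWARD:
                five_prime_sites.append(
                    (chrom, (e1 + s2) // 2, frozenset({FORWARD, REVERSE}))
                )
        if unit_bounds[-1][2] == REVERSE:
            five_prime_sites.append(
                (chrom, unit_bounds[-1][1], frozenset({REVERSE}))
            )

    f = config.internal_tss_fraction
    n_internal = round(f / (1 - f) * len(five_prime_sites)) if f > 0 else 0
    internal: list[tuple[str, int, frozenset[str]]] = []
    if n_internal:
        chosen = rng.integers(0, len(units), size=n_internal)
        for u in chosen:
            chrom, start, end, strand = units[u]
            length = end - start + 1
            pos = start + int(rng.uniform(0.1, 0.9) * length)
            internal.append((chrom, pos, frozenset({strand})))

    # internal sites are tagged iTSS so downstream checks can tell the two
    # site classes apart without re-deriving unit structure
    sites = sorted(
        [
            InitiationSite(f"TSS{i + 1:04d}", c, p, d)
            for i, (c, p, d) in enumerate(sorted(five_prime_sites))
        ]
        + [
            InitiationSite(f"iTSS{i + 1:04d}", c, p, d)
            for i, (c, p, d) in enumerate(sorted(internal))
        ],
        key=lambda s: (s.chrom, s.position, s.site_id),
    )
    return genes, sites, chroms


def internal_site_fraction(sites: list[InitiationSite]) -> float:
    """Fraction of site records that are internal to a transcription unit
    (generator-tagged ``iTSS`` ids)."""
    return sum(1 for s in sites if s.site_id.startswith("iTSS")) / len(sites)


def _normal_scores(values: np.ndarray) -> np.ndarray:
    ranks = stats.rankdata(values, method="ordinal")
    return stats.norm.ppf((ranks - 0.5) / values.size)


def generate_heatshock_expression(
    distances: list[GeneDistance], config: SyntheticConfig
) -> ExpressionTable:
    """Fold changes with a planted distance correlation.

    Distances act through their ranks: the normal scores of the distance
    ranks are mixed with independent Gaussian noise through a bivariate
    Gaussian copula whose Pearson parameter is chosen (r = 2 sin(pi*rho/6))
    so the population Spearman correlation between distance and log2 fold
    change equals ``planted_distance_effect`` exactly, whatever the distance
    distribution's shape. log2 fold change is scaled by ``log2_fc_sd``.
    """
    rng = _rng(config, 2)
    rho = config.planted_distance_effect
    x = _normal_scores(np.array([d.distance for d in distances], dtype=float))
    if abs(rho) == 1.0:
        y = math.copysign(1.0, rho) * x
    else:
        r = 2.0 * math.sin(math.pi * rho / 6.0)
        y = r * x + math.sqrt(1.0 - r * r) * rng.standard_normal(x.size)
    log2_fc = config.log2_fc_sd * y
    df = pd.DataFrame(
        {"fold_change": np.exp2(log2_fc)},
        index=pd.Index([d.gene_id for d in distances], name="gene_id"),
    )
    return ExpressionTable(mode="foldchange", data=df)


def generate_go_annotations(
    distances: list[GeneDistance],
    config: SyntheticConfig,
    plant_bias: bool = True,
) -> GOAnnotation:
    """GO annotation with uniform background terms and (optionally) one
    planted proximal and one planted distal category.

    Planted categories draw their members from the nearest / farthest
    distance decile (term_ids :data:`PROXIMAL_TERM_ID` /
    :data:`DISTAL_TERM_ID`). Background terms are drawn disjoint from each
    other and from the planted terms, then overlaps are injected by
    replacing a ``go_overlap_rate`` fraction of each background term's
    members with members of the previous term — so at rate 0 all pairwise
    intersections are empty, and planted terms stay positionally pure.
    """
    if config.n_go_terms < 1:
        raise ValueError("n_go_terms must be >= 1")
    rng = _rng(config, 3)
    ids = np.array([d.gene_id for d in distances])
    order = np.argsort([d.distance for d in distances], kind="stable")
    n = ids.size
    decile = max(1, n // 10)

    names: dict[str, str] = {}
    members: dict[str, frozenset[str]] = {}
    used: set[str] = set()
    if plant_bias:
        if config.planted_term_size > decile:
            raise ValueError(
                f"not enough genes: planted term size {config.planted_term_size} "
                f"exceeds decile size {decile}"
            )
        prox = rng.choice(ids[order[:decile]], config.planted_term_size, replace=False)
        dist = rng.choice(ids[order[-decile:]], config.planted_term_size, replace=False)
        names[PROXIMAL_TERM_ID] = "planted proximal set"
        members[PROXIMAL_TERM_ID] = frozenset(prox)
        names[DISTAL_TERM_ID] = "planted distal set"
        members[DISTAL_TERM_ID] = frozenset(dist)
        used = set(prox) | set(dist)

    pool = np.array(sorted(set(ids) - used))
    rng.shuffle(pool)
    lo, hi = config.go_term_size_range
    sizes = rng.integers(lo, hi + 1, size=config.n_go_terms)
    if sizes.sum() > pool.size:
        raise ValueError(
            f"not enough genes: background terms need {sizes.sum()}, "
            f"only {pool.size} unannotated genes available"
        )
    bg_ids: list[str] = []
    at = 0
    for j, size in enumerate(sizes):
        term = f"SYNGO:{j + 1:07d}"
        bg_ids.append(term)
        names[term] = f"synthetic background process {j + 1}"
        members[term] = frozenset(pool[at : at + size])
        at += size

    if config.go_overlap_rate > 0:
        for prev, term in zip(bg_ids, bg_ids[1:]):
            m = set(members[term])
            k = min(
                round(config.go_overlap_rate * len(m)),
                len(members[prev] - m),
                len(m) - 1,
            )
            if k <= 0:
                continue
            drop = rng.choice(sorted(m), k, replace=False)
            add = rng.choice(sorted(members[prev] - m), k, replace=False)
            members[term] = frozenset((m - set(drop)) | set(add))

    return GOAnnotation(names=names, members=members)


def generate_cellcycle_expression(
    distances: list[GeneDistance], config: SyntheticConfig
) -> ExpressionTable:
    """Four-stage abundances with planted log-linear distance trends.

    Per-gene stage abundance = baseline * 2^(slope_stage * distance) *
    2^noise, with a log-normal per-gene baseline and independent Gaussian
    log2 noise per value.
    """
    if len(config.planted_stage_slopes) != len(STAGES):
        raise ValueError("planted_stage_slopes must have four entries")
    rng = _rng(config, 4)
    d = np.array([dd.distance for dd in distances], dtype=float)
    baseline = _lognormal(rng, config.cellcycle_baseline_mean, 0.5, size=d.size)
    cols = {}
    for slope, stage in zip(config.planted_stage_slopes, STAGES):
        noise = config.cellcycle_noise_sd * rng.standard_normal(d.size)
        cols[stage] = baseline * np.exp2(slope * d + noise)
    df = pd.DataFrame(
        cols, index=pd.Index([dd.gene_id for dd in distances], name="gene_id")
    )
    return ExpressionTable(mode="cellcycle", data=df)


def truth_record(config: SyntheticConfig) -> dict:
    """Planted parameters, for the truth JSON emitted with a bundle."""
    return {
        "seed": config.seed,
        "planted_distance_effect": config.planted_distance_effect,
        "planted_stage_slopes": dict(zip(STAGES, config.planted_stage_slopes)),
        "proximal_term_id": PROXIMAL_TERM_ID,
        "distal_term_id": DISTAL_TERM_ID,
        "internal_tss_fraction": config.internal_tss_fraction,
        "go_overlap_rate": config.go_overlap_rate,
    }
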