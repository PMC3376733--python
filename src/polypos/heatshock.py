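"""Positional analysis of the heat-shock response.

Genes whose mRNA rises at least twofold after heat shock ("up") and genes
that fall at least twofold ("down") are selected, and their positions
within transcription units interrogated three ways: the fold-change versus
distance-to-initiation-site correlation, binned distance distributions
against the all-gene background, and a Monte Carlo test on each group's
mean distance against random gene groups of the same size.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from ._sampling import subset_means
from .model import ExpressionTable, GeneDistance


@dataclass(frozen=True)
class ResponsiveSets:
    """Gene sets at least ``threshold``-fold up- or down-regulated
    (boundaries inclusive: FC >= threshold, FC <= 1/threshold)."""

    up: frozenset[str]
    down: frozenset[str]
    threshold: float

    def __post_init__(self) -> None:
        if self.up & self.down:
            raise ValueError("up and down sets overlap")


@dataclass(frozen=True)
class CorrelationResult:
    """Fold-change/distance association. ``pearson_r`` is computed on
    log2 fold change (making up- and down-regulation symmetric);
    ``pearson_r_raw`` on the linear scale for transparency. NaN fields mean
    the correlation was undefined (constant input), which is reported as
    such rather than as zero."""

    spearman_r: float
    pearson_r: float
    pearson_r_raw: float
    n: int
    p_spearman: float
    p_pearson: float

    @property
    def undefined(self) -> bool:
        return math.isnan(self.spearman_r)


@dataclass(frozen=True)
class DistanceHistogram:
    bin_width: int
    edges: tuple[float, ...]
    counts: tuple[int, ...]
    proportions: tuple[float, ...]
    n: int


@dataclass(frozen=True)
class GroupDistanceTest:
    """Monte Carlo test of a gene group's mean distance against random
    same-size groups drawn without replacement from the universe. Both tail
    proportions are reported (trial mean >= / <= observed, ties counting
    toward each tail); ``p`` is the smaller tail and ``side`` records which."""

    observed_mean: float
    p_upper: float
    p_lower: float
    p: float
    side: str
    n_group: int
    n_universe: int
    n_trials: int


def select_responsive(
    expr: ExpressionTable,
    threshold: float = 2.0,
    universe: set[str] | None = None,
) -> ResponsiveSets:
    """Split genes into up- (FC >= threshold) and down- (FC <= 1/threshold)
    regulated sets, both boundaries inclusive.

    ``universe`` restricts selection to genes surviving the class filters,
    so removed genes never appear in either set.
    """
    if threshold <= 1:
        raise ValueError(f"threshold must be > 1, got {threshold}")
    if expr.mode != "foldchange":
        raise ValueError("select_responsive needs a foldchange-mode table")
    fc = expr.data["fold_change"]
    if universe is not None:
        fc = fc[fc.index.isin(universe)]
    up = frozenset(fc.index[fc >= threshold])
    down = frozenset(fc.index[fc <= 1.0 / threshold])
    return ResponsiveSets(up=up, down=down, threshold=threshold)


def correlate_foldchange_distance(
    expr: ExpressionTable,
    distances: list[GeneDistance],
    members: set[str],
) -> CorrelationResult:
    """Spearman (midranks for ties, two-sided p) and Pearson correlation of
    fold change against distance to the initiation site over ``members``."""
    dist = {d.gene_id: d.distance for d in distances}
    genes = sorted(g for g in members if g in dist and g in expr.data.index)
    if len(genes) < 3:
        raise ValueError(f"need >= 3 genes with both values, got {len(genes)}")
    x = np.array([dist[g] for g in genes], dtype=float)
    fc = expr.data.loc[genes, "fold_change"].to_numpy(dtype=float)
    if np.ptp(x) == 0 or np.ptp(fc) == 0:
        nan = float("nan")
        return CorrelationResult(nan, nan, nan, len(genes), nan, nan)
    sp = stats.spearmanr(x, fc)
    pe = stats.pearsonr(x, np.log2(fc))
    pe_raw = stats.pearsonr(x, fc)
    return CorrelationResult(
        spearman_r=float(sp.statistic),
        pearson_r=float(pe.statistic),
        pearson_r_raw=float(pe_raw.statistic),
        n=len(genes),
        p_spearman=float(sp.pvalue),
        p_pearson=float(pe.pvalue),
    )


def distance_histogram(
    distances: list[GeneDistance],
    members: set[str] | None = None,
    bin_width: int = 20_000,
) -> DistanceHistogram:
    """Proportion of genes per distance bin [k*w, (k+1)*w); the final bin is
    closed at the maximum observed distance. Default width 20 kbp."""
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    if members is None:
        vals = np.array([d.distance for d in distances], dtype=float)
    else:
        vals = np.array(
            [d.distance for d in distances if d.gene_id in members], dtype=float
        )
    if vals.size == 0:
        raise ValueError("no member gene has a distance")
    n_bins = max(1, math.ceil(vals.max() / bin_width)) if vals.max() > 0 else 1
    edges = np.arange(0, (n_bins + 1) * bin_width, bin_width, dtype=float)
    counts, _ = np.histogram(vals, bins=edges)
    return DistanceHistogram(
        bin_width=bin_width,
        edges=tuple(edges),
        counts=tuple(int(c) for c in counts),
        proportions=tuple(counts / vals.size),
        n=int(vals.size),
    )


def group_mean_distance_test(
    group: set[str],
    universe: list[GeneDistance],
    n_trials: int = 10_000,
    rng_seed: int = 0,
) -> GroupDistanceTest:
    """Monte Carlo resampling test on the group's mean distance.

    Draws ``n_trials`` random subsets of ``len(group)`` genes without
    replacement from the universe and reports the proportion of trial means
    >= the observed mean (upper tail) and <= it (lower tail)."""
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    uni_vals = np.array([d.distance for d in universe], dtype=float)
    dist = {d.gene_id: d.distance for d in universe}
    missing = [g for g in group if g not in dist]
    if missing:
        raise ValueError(f"group genes absent from universe: {sorted(missing)[:5]}")
    k = len(group)
    if k == 0:
        raise ValueError("empty group")
    if k > uni_vals.size:
        raise ValueError(f"group size {k} exceeds universe size {uni_vals.size}")
    observed = float(np.mean([dist[g] for g in group]))
    rng = np.random.default_rng(rng_seed)
    means = subset_means(uni_vals, k, n_trials, rng)
    p_upper = float(np.mean(means >= observed))
    p_lower = float(np.mean(means <= observed))
    side = "lower" if p_lower <= p_upper else "upper"
    return GroupDistanceTest(
        observed_mean=observed,
        p_upper=p_upper,
        p_lower=p_lower,
        p=min(p_lower, p_upper),
        side=side,
        n_group=k,
        n_universe=int(uni_vals.size),
        n_trials=n_trials,
    )
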