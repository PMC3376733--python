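import pytest

from polypos import (
    ChromosomeInfo,
    GeneRecord,
    InitiationSite,
    SyntheticConfig,
    apply_gene_filters,
    compute_all_distances,
    generate_genome,
)
from polypos.model import FORWARD, REVERSE


def make_gene(gene_id="g1", chrom="chr1", start=100, end=1600,
              strand=FORWARD, flags=(), product=""):
    return GeneRecord(gene_id=gene_id, chrom=chrom, start=start, end=end,
                      strand=strand, flags=frozenset(flags), product=product)


def make_site(site_id="s1", chrom="chr1", position=1000, directions=(FORWARD,)):
    return InitiationSite(site_id=site_id, chrom=chrom, position=position,
                          directions=frozenset(directions))


@pytest.fixture
def chrom100k():
    return ChromosomeInfo(chrom="chr1", length=100_000)


@pytest.fixture(scope="session")
def small_genome():
    """A compact synthetic genome with its filtered distance set, shared by
    the analysis-stage tests."""
    cfg = SyntheticConfig(seed=11, n_chromosomes=2, units_per_chromosome=4)
    genes, sites, chroms = generate_genome(cfg)
    kept = apply_gene_filters(genes, {"pseudogene", "vsg", "esag", "multilocus"})
    distances = compute_all_distances(kept, sites, chroms)
    return cfg, kept, sites, chroms, distances


@pytest.fixture(scope="session")
def default_genome():
    """The generator's default study conditions (~1200 genes)."""
    cfg = SyntheticConfig(seed=7)
    genes, sites, chroms = generate_genome(cfg)
    kept = apply_gene_filters(genes, {"pseudogene", "vsg", "esag", "multilocus"})
    distances = compute_all_distances(kept, sites, chroms)
    return cfg, kept, sites, chroms, distances
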