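"""Core in-memory data model for positional transcription-unit analysis.

All genomic coordinates are 1-based and inclusive, matching the GFF3 frame
they are read from. Distances are reported in base pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

FORWARD = "forward"
REVERSE = "reverse"
STRANDS = (FORWARD, REVERSE)

#: Gene-class flags used by the filtering step. Genes in these classes are
#: removed before any distance calculation: pseudogenes, variant surface
#: glycoproteins (VSG, RNA Pol I transcribed), expression-site-associated
#: genes (ESAG), and dispersed multi-copy families whose originating locus
#: cannot be resolved on an array ("multilocus").
GENE_FLAGS = ("pseudogene", "vsg", "esag", "multilocus")

#: Cell-cycle stage labels, in cycle order.
STAGES = ("earlyG1", "lateG1", "S", "G2M")

#: Sentinel anchor used when no initiation site exists in the correct
#: orientation and the end of the assembled sequence stands in for one.
SEQUENCE_END = "sequence_end"


@dataclass(frozen=True)
class GeneRecord:
    """One annotated protein-coding gene (or pseudogene)."""

    gene_id: str
    chrom: str
    start: int  # 1-based inclusive
    end: int  # 1-based inclusive, end >= start
    strand: str  # FORWARD or REVERSE
    flags: frozenset[str] = frozenset()
    product: str = ""

    def __post_init__(self) -> None:
        if self.start < 1:
            raise ValueError(f"{self.gene_id}: start must be >= 1, got {self.start}")
        if self.end < self.start:
            raise ValueError(
                f"{self.gene_id}: end ({self.end}) < start ({self.start})"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"{self.gene_id}: bad strand {self.strand!r}")
        bad = set(self.flags) - set(GENE_FLAGS)
        if bad:
            raise ValueError(f"{self.gene_id}: unknown flags {sorted(bad)}")


@dataclass(frozen=True)
class InitiationSite:
    """A transcription initiation position and the direction(s) it fires.

    Bidirectional sites (one initiation region launching polymerases both
    ways, as at divergent strand-switch regions) carry both directions.
    """

    site_id: str
    chrom: str
    position: int  # 1-based
    directions: frozenset[str]

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError(f"{self.site_id}: position must be >= 1")
        if not self.directions or not set(self.directions) <= set(STRANDS):
            raise ValueError(
                f"{self.site_id}: directions must be a nonempty subset of {STRANDS}"
            )


@dataclass(frozen=True)
class ChromosomeInfo:
    chrom: str
    length: int

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError(f"{self.chrom}: length must be >= 1")


@dataclass(frozen=True)
class GeneDistance:
    """A gene's distance to its nearest correct-orientation initiation site.

    ``fallback`` is True iff no mapped site existed in the correct direction
    and the sequence end was used as the putative initiation site, in which
    case ``anchor`` is the :data:`SEQUENCE_END` sentinel.
    """

    gene_id: str
    chrom: str
    strand: str
    midpoint: int
    distance: int
    anchor: str
    fallback: bool

    def __post_init__(self) -> None:
        if self.distance < 0:
            raise ValueError(f"{self.gene_id}: negative distance {self.distance}")
        if self.fallback != (self.anchor == SEQUENCE_END):
            raise ValueError(
                f"{self.gene_id}: fallback flag inconsistent with anchor "
                f"{self.anchor!r}"
            )


@dataclass
class ExpressionTable:
    """Per-gene expression values, either heat-shock fold changes or
    four-stage cell-cycle abundances.

    ``data`` is indexed by gene_id; fold-change mode has the single column
    ``fold_change`` (linear scale, post/pre heat shock), cell-cycle mode has
    the four :data:`STAGES` columns (positive abundances). ``unresolved``
    collects gene_ids that could not be matched against a gene set during
    validation — reported, never silently dropped.
    """

    mode: str  # "foldchange" | "cellcycle"
    data: pd.DataFrame
    unresolved: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.mode not in ("foldchange", "cellcycle"):
            raise ValueError(f"unknown expression mode {self.mode!r}")
        want = ["fold_change"] if self.mode == "foldchange" else list(STAGES)
        missing = [c for c in want if c not in self.data.columns]
        if missing:
            raise ValueError(f"expression table missing columns {missing}")
        if self.data.index.has_duplicates:
            dups = self.data.index[self.data.index.duplicated()].tolist()
            raise ValueError(f"duplicate gene_id(s) in expression table: {dups[:5]}")
        vals = self.data[want]
        if not (vals.apply(pd.to_numeric, errors="coerce").notna().all().all()):
            raise ValueError("non-numeric expression value")
        bad = vals[(vals <= 0).any(axis=1)]
        if len(bad):
            raise ValueError(
                f"non-positive expression value for gene_id(s) {bad.index.tolist()[:5]}"
            )

    def __len__(self) -> int:
        return len(self.data)

    def resolve(self, gene_ids: set[str]) -> "ExpressionTable":
        """Record (not drop) ids absent from ``gene_ids``; returns self."""
        self.unresolved = [g for g in self.data.index if g not in gene_ids]
        return self


@dataclass
class GOAnnotation:
    """Gene-ontology memberships: term_id -> (term_name, member gene_ids).

    Membership is many-to-many; a gene may belong to any number of terms.
    """

    names: dict[str, str]
    members: dict[str, frozenset[str]]

    def __post_init__(self) -> None:
        if set(self.names) != set(self.members):
            raise ValueError("names and members must cover the same term_ids")
        empty = [t for t, m in self.members.items() if not m]
        if empty:
            raise ValueError(f"empty member set for term(s) {empty[:5]}")

    def __len__(self) -> int:
        return len(self.members)

    @property
    def annotated_genes(self) -> frozenset[str]:
        out: set[str] = set()
        for m in self.members.values():
            out |= m
        return frozenset(out)


def validate_references(
    genes: list[GeneRecord],
    chroms: list[ChromosomeInfo],
    sites: list[InitiationSite] | None = None,
) -> None:
    """Cross-check referential integrity between genes, sites and chromosomes."""
    lengths = {c.chrom: c.length for c in chroms}
    seen: set[str] = set()
    for g in genes:
        if g.gene_id in seen:
            raise ValueError(f"duplicate gene_id {g.gene_id}")
        seen.add(g.gene_id)
        if g.chrom not in lengths:
            raise ValueError(f"{g.gene_id}: chromosome {g.chrom} has no known length")
        if g.end > lengths[g.chrom]:
            raise ValueError(
                f"{g.gene_id}: end {g.end} exceeds {g.chrom} length {lengths[g.chrom]}"
            )
    for s in sites or []:
        if s.chrom not in lengths:
            raise ValueError(f"{s.site_id}: chromosome {s.chrom} has no known length")
        if s.position > lengths[s.chrom]:
            raise ValueError(
                f"{s.site_id}: position {s.position} exceeds {s.chrom} length "
                f"{lengths[s.chrom]}"
            )
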