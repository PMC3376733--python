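"""Readers, writers and gene-class filters for the pipeline's input formats.

Four inputs drive the analysis: a GFF3 genome annotation (with
``##sequence-region`` pragmas supplying chromosome lengths), a TSV of
transcription initiation sites, TSV expression tables (heat-shock fold
changes or four-stage cell-cycle abundances), and a TSV of GO term
memberships. Everything is validated on the way in; genes are never
silently dropped.
"""

from __future__ import annotations

import logging
from importlib import resources
from pathlib import Path

import gffutils
import pandas as pd
import yaml

from .model import (
    FORWARD,
    GENE_FLAGS,
    REVERSE,
    STAGES,
    ChromosomeInfo,
    ExpressionTable,
    GeneRecord,
    GOAnnotation,
    InitiationSite,
    validate_references,
)

logger = logging.getLogger(__name__)

_GENE_FEATURE_TYPES = ("gene", "protein_coding_gene", "pseudogene")
_STRAND_FROM_GFF = {"+": FORWARD, "-": REVERSE}
_GFF_FROM_STRAND = {FORWARD: "+", REVERSE: "-"}
_DIRECTION_TOKENS = {
    "+": frozenset({FORWARD}),
    "-": frozenset({REVERSE}),
    "−": frozenset({REVERSE}),  # unicode minus
    "both": frozenset({FORWARD, REVERSE}),
}


def default_flag_keywords() -> dict[str, list[str]]:
    """The shipped gene-class keyword map (flag -> description substrings)."""
    text = resources.files("polypos.data").joinpath("gene_class_keywords.yaml")
    return yaml.safe_load(text.read_text())


def _classify(product: str, feature_type: str, keywords: dict[str, list[str]]) -> frozenset[str]:
    low = product.lower()
    flags = {
        flag
        for flag, words in keywords.items()
        if any(w.lower() in low for w in words)
    }
    if feature_type == "pseudogene":
        flags.add("pseudogene")
    return frozenset(flags)


def read_genome_annotation(
    path: str | Path,
    filter_keywords: dict[str, list[str]] | None = None,
) -> tuple[list[GeneRecord], list[ChromosomeInfo]]:
    """Read gene features and chromosome lengths from a GFF3 file.

    One :class:`GeneRecord` is produced per gene-type feature; gene-class
    flags are assigned by case-insensitive substring match of
    ``filter_keywords`` against the product description and by the
    ``pseudogene`` feature type. Pass an empty mapping for no keyword flags;
    ``None`` uses the shipped defaults.

    Raises on a gene whose chromosome has no ``##sequence-region`` length,
    and on a feature with end < start.
    """
    path = Path(path)
    if filter_keywords is None:
        filter_keywords = default_flag_keywords()
    bad = set(filter_keywords) - set(GENE_FLAGS)
    if bad:
        raise ValueError(f"unknown flags in filter_keywords: {sorted(bad)}")

    db = gffutils.create_db(
        str(path), ":memory:", keep_order=True, merge_strategy="create_unique"
    )
    chroms: list[ChromosomeInfo] = []
    for directive in db.directives:
        parts = directive.split()
        if parts and parts[0] == "sequence-region" and len(parts) >= 4:
            chroms.append(ChromosomeInfo(chrom=parts[1], length=int(parts[3])))
    lengths = {c.chrom: c.length for c in chroms}

    genes: list[GeneRecord] = []
    rejects: list[str] = []
    n_features = 0
    for feat in db.all_features():
        if feat.featuretype not in _GENE_FEATURE_TYPES:
            continue
        n_features += 1
        if feat.end < feat.start:
            raise ValueError(
                f"{path.name}: feature {feat.id!r} on {feat.seqid} has "
                f"end < start ({feat.end} < {feat.start})"
            )
        if feat.seqid not in lengths:
            raise ValueError(
                f"{path.name}: feature {feat.id!r} is on {feat.seqid}, which has "
                "no ##sequence-region length"
            )
        if feat.strand not in _STRAND_FROM_GFF:
            rejects.append(feat.id)
            logger.warning("rejecting %s: unstranded feature", feat.id)
            continue
        attrs = feat.attributes
        product = ""
        for key in ("description", "product", "Note", "Name"):
            if key in attrs:
                product = attrs[key][0]
                break
        genes.append(
            GeneRecord(
                gene_id=feat.id,
                chrom=feat.seqid,
                start=feat.start,
                end=feat.end,
                strand=_STRAND_FROM_GFF[feat.strand],
                flags=_classify(product, feat.featuretype, filter_keywords),
                product=product,
            )
        )
    assert n_features == len(genes) + len(rejects)
    validate_references(genes, chroms)
    logger.info(
        "read %d genes on %d chromosomes from %s (%d rejected)",
        len(genes), len(chroms), path.name, len(rejects),
    )
    return genes, chroms


def write_genome_annotation(
    path: str | Path, genes: list[GeneRecord], chroms: list[ChromosomeInfo]
) -> None:
    """Write genes back out as GFF3 (round-trips with the reader)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for c in chroms:
            fh.write(f"##sequence-region {c.chrom} 1 {c.length}\n")
        for g in genes:
            ftype = "pseudogene" if "pseudogene" in g.flags else "gene"
            attrs = f"ID={g.gene_id}"
            if g.product:
                attrs += f";description={g.product}"
            fh.write(
                f"{g.chrom}\tpolypos\t{ftype}\t{g.start}\t{g.end}\t.\t"
                f"{_GFF_FROM_STRAND[g.strand]}\t.\t{attrs}\n"
            )


def apply_gene_filters(
    genes: list[GeneRecord], excluded_flags: set[str]
) -> list[GeneRecord]:
    """Drop genes carrying any of ``excluded_flags``; order preserved.

    The removed classes (pseudogenes, VSG, ESAG, dispersed multi-copy
    families) are excluded from every positional calculation because their
    expression or locus of origin cannot be interpreted positionally.
    """
    bad = set(excluded_flags) - set(GENE_FLAGS)
    if bad:
        raise ValueError(f"unknown excluded flags: {sorted(bad)}")
    excluded = frozenset(excluded_flags)
    kept = [g for g in genes if not (g.flags & excluded)]
    for flag in sorted(excluded):
        n = sum(1 for g in genes if flag in g.flags)
        logger.info("filter %s: %d genes flagged", flag, n)
    logger.info("filters removed %d of %d genes", len(genes) - len(kept), len(genes))
    if genes and not kept:
        logger.warning("gene filters removed every gene")
    return kept


def read_initiation_sites(
    path: str | Path, chroms: list[ChromosomeInfo]
) -> list[InitiationSite]:
    """Read a TSV of initiation sites (columns chrom, position, direction).

    Direction tokens: ``+`` (forward), ``-`` (reverse), ``both``
    (bidirectional). Positions are checked against chromosome lengths.
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    for col in ("chrom", "position", "direction"):
        if col not in df.columns:
            raise ValueError(f"sites table missing column {col!r}")
    lengths = {c.chrom: c.length for c in chroms}
    sites: list[InitiationSite] = []
    for i, row in enumerate(df.itertuples(index=False)):
        token = str(row.direction)
        if token not in _DIRECTION_TOKENS:
            raise ValueError(f"row {i + 2}: unknown direction token {token!r}")
        if row.chrom not in lengths:
            raise ValueError(f"row {i + 2}: unknown chromosome {row.chrom!r}")
        pos = int(row.position)
        if not 1 <= pos <= lengths[row.chrom]:
            raise ValueError(
                f"row {i + 2}: position {pos} outside {row.chrom} "
                f"(length {lengths[row.chrom]})"
            )
        site_id = getattr(row, "site_id", f"site{i + 1:04d}")
        sites.append(
            InitiationSite(
                site_id=str(site_id),
                chrom=row.chrom,
                position=pos,
                directions=_DIRECTION_TOKENS[token],
            )
        )
    return sites


def write_initiation_sites(path: str | Path, sites: list[InitiationSite]) -> None:
    rows = []
    for s in sites:
        if s.directions == frozenset({FORWARD, REVERSE}):
            token = "both"
        elif FORWARD in s.directions:
            token = "+"
        else:
            token = "-"
        rows.append((s.site_id, s.chrom, s.position, token))
    pd.DataFrame(rows, columns=["site_id", "chrom", "position", "direction"]).to_csv(
        path, sep="\t", index=False
    )


def read_expression_table(path: str | Path, mode: str) -> ExpressionTable:
    """Read a per-gene expression TSV.

    ``foldchange`` mode expects columns gene_id, fold_change (linear scale);
    ``cellcycle`` mode expects gene_id plus the four stage columns
    earlyG1, lateG1, S, G2M. Duplicate gene_ids and non-positive or
    non-numeric values are hard errors.
    """
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
    if "gene_id" not in df.columns:
        raise ValueError("expression table missing column 'gene_id'")
    want = ["fold_change"] if mode == "foldchange" else list(STAGES)
    missing = [c for c in want if c not in df.columns]
    if missing:
        raise ValueError(f"{mode} expression table missing columns {missing}")
    df = df.set_index("gene_id")
    return ExpressionTable(mode=mode, data=df[want].astype(float, errors="ignore"))


def write_expression_table(path: str | Path, expr: ExpressionTable) -> None:
    expr.data.rename_axis("gene_id").to_csv(path, sep="\t")


def read_go_annotations(path: str | Path) -> GOAnnotation:
    """Read GO memberships from a long-format TSV (term_id, term_name,
    gene_id — one row per membership)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("term_id", "term_name", "gene_id"):
        if col not in df.columns:
            raise ValueError(f"GO table missing column {col!r}")
    names: dict[str, str] = {}
    members: dict[str, set[str]] = {}
    for row in df.itertuples(index=False):
        prior = names.setdefault(row.term_id, row.term_name)
        if prior != row.term_name:
            raise ValueError(
                f"term {row.term_id} has conflicting names {prior!r} / "
                f"{row.term_name!r}"
            )
        members.setdefault(row.term_id, set()).add(row.gene_id)
    return GOAnnotation(
        names=names, members={t: frozenset(m) for t, m in members.items()}
    )


def write_go_annotations(path: str | Path, go: GOAnnotation) -> None:
    rows = [
        (t, go.names[t], g)
        for t in sorted(go.members)
        for g in sorted(go.members[t])
    ]
    pd.DataFrame(rows, columns=["term_id", "term_name", "gene_id"]).to_csv(
        path, sep="\t", index=False
    )
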