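"""Distance from each gene to its nearest correct-orientation initiation site.

Polycistronic transcription means a gene is transcribed by a polymerase that
initiated upstream of it, in the gene's own direction of transcription. The
distance that matters for positional effects is therefore measured from the
gene's ORF midpoint back to the nearest initiation site that could have
launched that polymerase — not to the nearest site in absolute terms. Where
no such site is mapped before the end of the assembled sequence, the
sequence end stands in as a putative initiation site (``fallback=True``);
no gene is excluded for lacking a mapped site.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .model import (
    FORWARD,
    REVERSE,
    SEQUENCE_END,
    ChromosomeInfo,
    GeneDistance,
    GeneRecord,
    InitiationSite,
    validate_references,
)


def gene_midpoint(gene: GeneRecord) -> int:
    """ORF midpoint, floor((start + end) / 2), in the 1-based frame."""
    return (gene.start + gene.end) // 2


def nearest_upstream_site(
    gene: GeneRecord,
    sites: list[InitiationSite],
    chrom_info: ChromosomeInfo,
) -> GeneDistance:
    """Distance from ``gene`` to its nearest upstream correct-direction site.

    For a forward-strand gene the anchor is the forward-firing site with the
    largest position <= midpoint; for a reverse-strand gene, the
    reverse-firing site with the smallest position >= midpoint. A site
    exactly at the midpoint anchors at distance 0 for either direction it
    fires. With no candidate, the sequence end the polymerase would have
    come from is used: distance midpoint - 1 (forward) or chromosome length
    - midpoint (reverse).
    """
    mid = gene_midpoint(gene)
    best: InitiationSite | None = None
    if gene.strand == FORWARD:
        for s in sites:
            if s.chrom == gene.chrom and FORWARD in s.directions and s.position <= mid:
                if best is None or s.position > best.position:
                    best = s
        if best is None:
            return GeneDistance(
                gene.gene_id, gene.chrom, gene.strand, mid,
                mid - 1, SEQUENCE_END, True,
            )
        return GeneDistance(
            gene.gene_id, gene.chrom, gene.strand, mid,
            mid - best.position, best.site_id, False,
        )
    for s in sites:
        if s.chrom == gene.chrom and REVERSE in s.directions and s.position >= mid:
            if best is None or s.position < best.position:
                best = s
    if best is None:
        return GeneDistance(
            gene.gene_id, gene.chrom, gene.strand, mid,
            chrom_info.length - mid, SEQUENCE_END, True,
        )
    return GeneDistance(
        gene.gene_id, gene.chrom, gene.strand, mid,
        best.position - mid, best.site_id, False,
    )


def compute_all_distances(
    genes: list[GeneRecord],
    sites: list[InitiationSite],
    chroms: list[ChromosomeInfo],
) -> list[GeneDistance]:
    """One :class:`GeneDistance` per gene; deterministic and independent of
    input ordering. A gene on a chromosome absent from ``chroms`` is a hard
    error."""
    validate_references(genes, chroms, sites)
    by_chrom: dict[str, ChromosomeInfo] = {c.chrom: c for c in chroms}
    sites_by_chrom: dict[str, list[InitiationSite]] = {}
    for s in sites:
        sites_by_chrom.setdefault(s.chrom, []).append(s)
    return [
        nearest_upstream_site(g, sites_by_chrom.get(g.chrom, []), by_chrom[g.chrom])
        for g in genes
    ]


def distances_frame(distances: list[GeneDistance]) -> pd.DataFrame:
    """Tabular view of a distance set, indexed by gene_id."""
    return pd.DataFrame(
        {
            "chrom": [d.chrom for d in distances],
            "strand": [d.strand for d in distances],
            "midpoint": [d.midpoint for d in distances],
            "anchor": [d.anchor for d in distances],
            "distance": [d.distance for d in distances],
            "fallback": [d.fallback for d in distances],
        },
        index=pd.Index([d.gene_id for d in distances], name="gene_id"),
    )


def distance_map(distances: list[GeneDistance]) -> dict[str, int]:
    return {d.gene_id: d.distance for d in distances}


def write_distances(path: str | Path, distances: list[GeneDistance]) -> None:
    distances_frame(distances).to_csv(path, sep="\t")


# itemRgb colours for the browser track: up-regulated blue, down red,
# other grey (matches the conventional colouring of this analysis).
_TRACK_COLOURS = {"up": "0,0,255", "down": "255,0,0", "other": "128,128,128"}


def write_gene_track(
    path: str | Path,
    genes: list[GeneRecord],
    groups: dict[str, str] | None = None,
    track_name: str = "polypos_genes",
) -> None:
    """Export a BED9 track of genes coloured by group (up/down/other) for
    genome-browser viewing of positional patterns along each chromosome."""
    groups = groups or {}
    with open(path, "w") as fh:
        fh.write(f'track name="{track_name}" itemRgb="On"\n')
        for g in sorted(genes, key=lambda g: (g.chrom, g.start)):
            grp = groups.get(g.gene_id, "other")
            colour = _TRACK_COLOURS.get(grp, _TRACK_COLOURS["other"])
            strand = "+" if g.strand == FORWARD else "-"
            fh.write(
                f"{g.chrom}\t{g.start - 1}\t{g.end}\t{g.gene_id}\t0\t{strand}\t"
                f"{g.start - 1}\t{g.end}\t{colour}\n"
            )
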