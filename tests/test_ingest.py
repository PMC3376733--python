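"""Input parsing, gene-class flagging, filtering and round-trips."""

import pytest

from polypos import (
    apply_gene_filters,
    read_expression_table,
    read_genome_annotation,
    read_go_annotations,
    read_initiation_sites,
    write_genome_annotation,
    write_go_annotations,
    write_initiation_sites,
)
from polypos.model import FORWARD, REVERSE, ChromosomeInfo

from conftest import make_gene

TOY_GFF = """##gff-version 3
##sequence-region chr1 1 100000
chr1\tsrc\tgene\t100\t1600\t.\t+\t.\tID=g1;description=hypothetical protein
chr1\tsrc\tgene\t2000\t3500\t.\t-\t.\tID=g2;description=variant surface glycoprotein (VSG)
"""


@pytest.fixture
def toy_gff(tmp_path):
    p = tmp_path / "toy.gff3"
    p.write_text(TOY_GFF)
    return p


class TestReadGenomeAnnotation:
    def test_counts_and_lengths(self, toy_gff):
        genes, chroms = read_genome_annotation(toy_gff, filter_keywords={})
        assert len(genes) == 2
        assert chroms == [ChromosomeInfo("chr1", 100_000)]
        assert genes[0].strand == FORWARD and genes[1].strand == REVERSE

    def test_keyword_flagging_is_case_insensitive(self, toy_gff):
        genes, _ = read_genome_annotation(
            toy_gff, filter_keywords={"vsg": ["VARIANT SURFACE GLYCOPROTEIN"]}
        )
        by_id = {g.gene_id: g for g in genes}
        assert by_id["g2"].flags == {"vsg"}
        assert by_id["g1"].flags == frozenset()

    def test_empty_keyword_map_gives_empty_flags(self, toy_gff):
        genes, _ = read_genome_annotation(toy_gff, filter_keywords={})
        assert all(g.flags == frozenset() for g in genes)

    def test_pseudogene_feature_type_sets_flag(self, tmp_path):
        p = tmp_path / "p.gff3"
        p.write_text(
            "##gff-version 3\n##sequence-region chr1 1 10000\n"
            "chr1\tsrc\tpseudogene\t10\t900\t.\t+\t.\tID=pg1\n"
        )
        genes, _ = read_genome_annotation(p, filter_keywords={})
        assert genes[0].flags == {"pseudogene"}

    def test_missing_chromosome_length_is_hard_error(self, tmp_path):
        p = tmp_path / "bad.gff3"
        p.write_text(
            "##gff-version 3\n"
            "chr9\tsrc\tgene\t10\t900\t.\t+\t.\tID=g1\n"
        )
        with pytest.raises(ValueError, match="sequence-region"):
            read_genome_annotation(p, filter_keywords={})

    def test_end_before_start_is_hard_error(self, tmp_path):
        p = tmp_path / "bad.gff3"
        p.write_text(
            "##gff-version 3\n##sequence-region chr1 1 10000\n"
            "chr1\tsrc\tgene\t900\t10\t.\t+\t.\tID=g1\n"
        )
        with pytest.raises(ValueError, match="end < start"):
            read_genome_annotation(p, filter_keywords={})

    def test_gff3_round_trip(self, tmp_path, default_genome):
        _, genes, _, chroms, _ = default_genome
        out = tmp_path / "rt.gff3"
        write_genome_annotation(out, genes, chroms)
        genes2, chroms2 = read_genome_annotation(out)
        assert chroms2 == chroms
        assert genes2 == genes  # field-by-field, incl. flags and products


class TestApplyGeneFilters:
    def test_counts(self):
        genes = [make_gene(gene_id=f"g{i}", flags=({"vsg"} if i < 3 else ()))
                 for i in range(10)]
        kept = apply_gene_filters(genes, {"vsg"})
        assert len(kept) == 7

    def test_empty_exclusion_is_identity(self):
        genes = [make_gene(gene_id=f"g{i}", flags={"vsg"}) for i in range(4)]
        assert apply_gene_filters(genes, set()) == genes

    @pytest.mark.parametrize(
        "flags,excluded,removed",
        [
            (subset, {"pseudogene"}, "pseudogene" in subset)
            for subset in (
                frozenset(), {"vsg"}, {"pseudogene"}, {"vsg", "pseudogene"},
                {"esag", "multilocus"}, {"pseudogene", "esag", "multilocus"},
            )
        ],
    )
    def test_disjointness_over_flag_subsets(self, flags, excluded, removed):
        # a gene is removed iff its flag set intersects the excluded set
        g = make_gene(flags=flags)
        assert (apply_gene_filters([g], excluded) == []) == removed

    def test_idempotent(self):
        genes = [make_gene(gene_id=f"g{i}",
                           flags=({"esag"} if i % 3 == 0 else ()))
                 for i in range(9)]
        once = apply_gene_filters(genes, {"esag"})
        assert apply_gene_filters(once, {"esag"}) == once


class TestReadInitiationSites:
    def write(self, tmp_path, rows):
        p = tmp_path / "sites.tsv"
        p.write_text("chrom\tposition\tdirection\n" +
                     "".join(f"{c}\t{pos}\t{d}\n" for c, pos, d in rows))
        return p

    def test_direction_tokens(self, tmp_path, chrom100k):
        p = self.write(tmp_path, [("chr1", 5000, "+"), ("chr1", 6000, "-"),
                                  ("chr1", 7000, "both")])
        sites = read_initiation_sites(p, [chrom100k])
        assert sites[0].directions == {FORWARD}
        assert sites[1].directions == {REVERSE}
        assert sites[2].directions == {FORWARD, REVERSE}

    def test_unknown_chromosome_is_error(self, tmp_path, chrom100k):
        p = self.write(tmp_path, [("chr9", 10, "+")])
        with pytest.raises(ValueError, match="chr9"):
            read_initiation_sites(p, [chrom100k])

    def test_position_beyond_length_is_error(self, tmp_path, chrom100k):
        p = self.write(tmp_path, [("chr1", 200_000, "+")])
        with pytest.raises(ValueError, match="outside"):
            read_initiation_sites(p, [chrom100k])

    def test_unknown_direction_token_is_error(self, tmp_path, chrom100k):
        p = self.write(tmp_path, [("chr1", 10, "fwd")])
        with pytest.raises(ValueError, match="direction"):
            read_initiation_sites(p, [chrom100k])

    def test_round_trip(self, tmp_path, default_genome):
        _, _, sites, chroms, _ = default_genome
        out = tmp_path / "sites.tsv"
        write_initiation_sites(out, sites)
        assert read_initiation_sites(out, chroms) == sites


class TestReadExpressionTable:
    def test_foldchange_parse(self, tmp_path):
        p = tmp_path / "fc.tsv"
        p.write_text("gene_id\tfold_change\ng1\t2.0\ng2\t0.4\n")
        table = read_expression_table(p, "foldchange")
        assert len(table) == 2
        assert table.data.loc["g2", "fold_change"] == pytest.approx(0.4)

    def test_duplicate_gene_id_is_error(self, tmp_path):
        p = tmp_path / "fc.tsv"
        p.write_text("gene_id\tfold_change\ng1\t2.0\ng1\t0.4\n")
        with pytest.raises(ValueError, match="duplicate"):
            read_expression_table(p, "foldchange")

    def test_missing_stage_column_is_error(self, tmp_path):
        p = tmp_path / "cc.tsv"
        p.write_text("gene_id\tearlyG1\tlateG1\tS\ng1\t1\t2\t3\n")
        with pytest.raises(ValueError, match="G2M"):
            read_expression_table(p, "cellcycle")

    def test_non_positive_value_is_error(self, tmp_path):
        p = tmp_path / "fc.tsv"
        p.write_text("gene_id\tfold_change\ng1\t-2.0\n")
        with pytest.raises(ValueError, match="g1"):
            read_expression_table(p, "foldchange")

    def test_unresolved_ids_reported_not_dropped(self, tmp_path):
        p = tmp_path / "fc.tsv"
        p.write_text("gene_id\tfold_change\ng1\t2.0\ngx\t3.0\n")
        table = read_expression_table(p, "foldchange").resolve({"g1"})
        assert table.unresolved == ["gx"]
        assert len(table) == 2


class TestGOAnnotations:
    def test_round_trip(self, tmp_path):
        p = tmp_path / "go.tsv"
        p.write_text(
            "term_id\tterm_name\tgene_id\n"
            "GO:1\tflagellum\tg1\nGO:1\tflagellum\tg2\nGO:2\tribosome\tg2\n"
        )
        go = read_go_annotations(p)
        assert go.members["GO:1"] == {"g1", "g2"}
        assert go.annotated_genes == {"g1", "g2"}
        out = tmp_path / "go2.tsv"
        write_go_annotations(out, go)
        go2 = read_go_annotations(out)
        assert go2.members == go.members and go2.names == go.names


def test_no_gene_silently_dropped(default_genome, tmp_path):
    """|input gene features| == |records| + |reported rejects| holds through
    a disk round-trip (the writer emits every record)."""
    _, genes, _, chroms, _ = default_genome
    out = tmp_path / "all.gff3"
    write_genome_annotation(out, genes, chroms)
    n_features = sum(
        1 for line in out.read_text().splitlines()
        if not line.startswith("#")
    )
    genes2, _ = read_genome_annotation(out)
    assert n_features == len(genes2)
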