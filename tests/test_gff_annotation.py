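"""GFF3 parsing, gene lengths, and chromosome-name normalization."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ideotrack.gff_annotation import (
    GFF3ParseError,
    GeneModel,
    TranscriptModel,
    classify_gene_type,
    gene_length,
    load_human_alias_map,
    merge_intervals,
    normalize_chromosome_name,
    parse_gff3,
)


class TestParse:
    def test_toy_gene_mature_length(self, toy_gff3):
        genes, layout = parse_gff3(toy_gff3)
        assert len(genes) == 1
        (gene,) = genes
        assert gene.symbol == "ALPHA"
        assert (gene.start, gene.stop) == (1001, 2200)
        assert gene.gene_type == "mRNA"
        assert gene.mature_length == 300  # 100 + 200, introns excluded
        assert layout.chromosomes == [("1", 50000)]

    def test_header_only_file_is_empty(self, tmp_path):
        p = tmp_path / "empty.gff3"
        p.write_text("##gff-version 3\n")
        genes, layout = parse_gff3(p)
        assert genes == [] and layout.chromosomes == []

    def test_malformed_line_names_line_number(self, tmp_path):
        p = tmp_path / "bad.gff3"
        p.write_text("##gff-version 3\n1\tx\tgene\tnotanumber\t5\t.\t+\t.\tID=g\n")
        with pytest.raises(GFF3ParseError, match="line 2"):
            parse_gff3(p)

    def test_orphan_exon_skipped(self, tmp_path, caplog):
        p = tmp_path / "orphan.gff3"
        p.write_text(
            "##gff-version 3\n"
            "1\tx\tgene\t100\t200\t.\t+\t.\tID=g1;gene=G1;gene_biotype=protein_coding\n"
            "1\tx\texon\t100\t200\t.\t+\t.\tID=e1;Parent=rna-missing\n"
        )
        genes, _ = parse_gff3(p)
        assert len(genes) == 1 and genes[0].transcripts == []

    def test_alias_map_whitelists_and_renames(self, tmp_path):
        p = tmp_path / "acc.gff3"
        p.write_text(
            "##gff-version 3\n"
            "##sequence-region chrA 1 9000\n"
            "##sequence-region scaffold_1 1 500\n"
            "chrA\tx\tgene\t10\t90\t.\t+\t.\tID=g1;gene=G1;gene_biotype=lncRNA\n"
            "scaffold_1\tx\tgene\t10\t90\t.\t+\t.\tID=g2;gene=G2;gene_biotype=lncRNA\n"
        )
        genes, layout = parse_gff3(p, alias_map={"chrA": "A"})
        assert [g.symbol for g in genes] == ["G1"]
        assert genes[0].chromosome == "A"
        assert genes[0].gene_type == "ncRNA"
        assert layout.chromosomes == [("A", 9000)]

    def test_duplicate_symbols_kept_with_suffix(self, tmp_path):
        p = tmp_path / "dup.gff3"
        p.write_text(
            "##gff-version 3\n"
            "1\tx\tgene\t100\t200\t.\t+\t.\tID=g1;gene=DUP;gene_biotype=protein_coding\n"
            "1\tx\tgene\t500\t600\t.\t+\t.\tID=g2;gene=DUP;gene_biotype=protein_coding\n"
        )
        genes, _ = parse_gff3(p)
        assert [g.symbol for g in genes] == ["DUP", "DUP_2"]


class TestGeneLength:
    def test_longest_transcript_wins(self):
        gene = GeneModel("G", "1", 1, 1000, transcripts=[
            TranscriptModel("t1", [(1, 300)]),
            TranscriptModel("t2", [(1, 100), (201, 500)]),
        ])
        assert gene_length(gene) == 400

    def test_span_fallback_without_transcripts(self):
        assert gene_length(GeneModel("G", "1", 5001, 5100)) == 100

    def test_single_exon_inclusive_arithmetic(self):
        gene = GeneModel("G", "1", 1, 100,
                         transcripts=[TranscriptModel("t", [(1, 100)])])
        assert gene_length(gene) == 100

    def test_overlapping_exons_merged_before_summing(self):
        tx = TranscriptModel("t", [(1, 100), (50, 150)])
        assert tx.exons == [(1, 150)]
        assert tx.mature_length == 150


class TestChromosomeNames:
    def test_identity_when_absent(self):
        assert normalize_chromosome_name("1", {"chrA": "A"}) == "1"

    def test_table_lookup(self):
        assert normalize_chromosome_name("chrA", {"chrA": "A"}) == "A"

    @pytest.mark.parametrize("seqid,label", [
        ("NC_000001.11", "1"), ("NC_000023.10", "X"),
        ("NC_012920.1", "MT"), ("chr17", "17"),
    ])
    def test_shipped_human_alias_table(self, seqid, label):
        assert normalize_chromosome_name(seqid, load_human_alias_map()) == label


class TestGeneTypes:
    @pytest.mark.parametrize("biotype,expected", [
        ("protein_coding", "mRNA"), ("lncRNA", "ncRNA"), ("miRNA", "ncRNA"),
        ("pseudogene", "pseudogene"), ("transcribed_pseudogene", "pseudogene"),
        ("something_new", "other"),
    ])
    def test_biotype_mapping(self, biotype, expected):
        assert classify_gene_type(biotype) == expected

    def test_child_feature_fallback(self):
        assert classify_gene_type(None, ["mRNA"]) == "mRNA"
        assert classify_gene_type(None, ["lnc_RNA"]) == "ncRNA"
        assert classify_gene_type(None, []) == "other"


@given(st.lists(
    st.tuples(st.integers(1, 10_000), st.integers(1, 500)).map(
        lambda t: (t[0], t[0] + t[1] - 1)),
    min_size=1, max_size=20,
))
@settings(max_examples=200, deadline=None)
def test_exon_sum_property(exons):
    """mature_length equals an independent per-base re-summation."""
    tx = TranscriptModel("t", exons)
    covered = set()
    for s, e in exons:
        covered.update(range(s, e + 1))
    assert tx.mature_length == len(covered)
    assert tx.exons == merge_intervals(exons)
    # merged intervals are sorted and disjoint
    for (s1, e1), (s2, e2) in zip(tx.exons, tx.exons[1:]):
        assert e1 < s2


def test_parsed_gene_invariants(tmp_path, rng):
    """Every parsed gene satisfies start <= stop and gene_length >= 1."""
    from ideotrack.fixtures import make_genome

    _, _, _ = make_genome(2, 30, 5, tmp_path, overlap_fraction=0.2)
    genes, _ = parse_gff3(tmp_path / "annotation.gff3")
    assert len(genes) == 30
    for g in genes:
        assert g.start <= g.stop
        assert gene_length(g) >= 1
        assert g.mature_length <= g.stop - g.start + 1
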