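"""Union-mode counting, TPM normalization, and the count-table TSV."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import count_fragments_oracle
from ideotrack.alignment_io import AlignmentRecord
from ideotrack.gff_annotation import GeneModel, TranscriptModel
from ideotrack.quantify import (
    CountTable,
    count_fragments,
    read_count_table,
    tpm,
    write_count_table,
)


def _gene(symbol, chrom, exons, strand="+"):
    start = min(s for s, _ in exons)
    stop = max(e for _, e in exons)
    return GeneModel(symbol, chrom, start, stop, strand, "mRNA",
                     [TranscriptModel(f"{symbol}.t1", exons)])


def _pair(qname, chrom, p1, p2, read_len=50):
    return [
        AlignmentRecord(qname, 99, chrom, p1, 60, f"{read_len}M"),
        AlignmentRecord(qname, 147, chrom, p2, 60, f"{read_len}M"),
    ]


GENE_A = _gene("A", "1", [(1000, 1999)])
GENE_B = _gene("B", "1", [(1900, 2899)])  # overlaps A in 1900..1999


class TestUnionMode:
    def test_pair_inside_single_gene(self):
        table = count_fragments(_pair("f1", "1", 1100, 1200), [GENE_A, GENE_B])
        assert table.counts == {"A": 1, "B": 0}
        assert table.no_feature == 0 and table.ambiguous == 0

    def test_mates_in_two_genes_is_ambiguous(self):
        # mate1 in A-only sequence, mate2 in B-only sequence
        table = count_fragments(_pair("f1", "1", 1100, 2500), [GENE_A, GENE_B])
        assert table.counts == {"A": 0, "B": 0}
        assert table.ambiguous == 1

    def test_intergenic_pair_is_no_feature(self):
        table = count_fragments(_pair("f1", "1", 5000, 5100), [GENE_A, GENE_B])
        assert table.no_feature == 1 and table.assigned == 0

    def test_block_in_shared_window_is_ambiguous(self):
        table = count_fragments(_pair("f1", "1", 1900, 1920), [GENE_A, GENE_B])
        assert table.ambiguous == 1

    def test_unknown_chromosome_counts_no_feature_with_warning(self):
        table = count_fragments(_pair("f1", "MT", 10, 20), [GENE_A])
        assert table.no_feature == 1
        assert table.unknown_chromosome == 1

    def test_mates_pooled_across_file_order(self):
        # interleave two fragments' mates; pairing is by qname, not order
        records = [
            _pair("f1", "1", 1100, 1200)[0],
            _pair("f2", "1", 2500, 2600)[0],
            _pair("f1", "1", 1100, 1200)[1],
            _pair("f2", "1", 2500, 2600)[1],
        ]
        table = count_fragments(records, [GENE_A, GENE_B])
        assert table.counts == {"A": 1, "B": 1}

    def test_matches_brute_force_on_random_fixture(self, rng, tmp_path):
        from ideotrack.alignment_io import filter_properly_paired, read_sam
        from ideotrack.fixtures import (
            make_alignments, random_genes, random_truth_counts,
        )

        genes, layout = random_genes(rng, 2, 30, overlap_fraction=0.2)
        counts = random_truth_counts(rng, genes)
        sam, _ = make_alignments(genes, layout, counts, n_no_feature=5,
                                 n_ambiguous=5, seed=3,
                                 path=tmp_path / "r.sam")
        _, records = read_sam(sam)
        kept = list(filter_properly_paired(records))
        table = count_fragments(kept, genes)

        pooled: dict[str, tuple[str, list]] = {}
        for rec in kept:
            chrom, blocks = pooled.setdefault(rec.qname, (rec.rname, []))
            blocks.extend(rec.aligned_blocks)
        exp_counts, exp_nf, exp_amb = count_fragments_oracle(
            pooled.values(), genes)
        assert table.counts == exp_counts
        assert (table.no_feature, table.ambiguous) == (exp_nf, exp_amb)


class TestTPM:
    def test_equal_rates_split_evenly(self):
        expr = tpm({"A": 10, "B": 20}, {"A": 1000, "B": 2000})
        assert expr.tpm == {"A": 500000.0, "B": 500000.0}

    def test_all_zero_counts_give_all_zero_tpm(self):
        expr = tpm({"A": 0, "B": 0}, {"A": 100, "B": 100})
        assert expr.tpm == {"A": 0.0, "B": 0.0}

    def test_stated_formula(self):
        expr = tpm({"A": 10, "B": 10}, {"A": 100, "B": 200})
        assert expr.tpm["A"] == pytest.approx(666666.6666667, abs=1e-4)
        assert expr.tpm["B"] == pytest.approx(333333.3333333, abs=1e-4)

    def test_missing_length_lists_symbols(self):
        with pytest.raises(KeyError, match="B"):
            tpm({"A": 1, "B": 1}, {"A": 100})

    @given(st.dictionaries(
        st.text(alphabet="ABCDEFGH", min_size=1, max_size=3),
        st.tuples(st.integers(0, 1000), st.integers(1, 10_000)),
        min_size=1, max_size=20,
    ))
    @settings(max_examples=200, deadline=None)
    def test_sum_and_scaling_invariance(self, table):
        counts = {sym: c for sym, (c, _) in table.items()}
        lengths = {sym: L for sym, (_, L) in table.items()}
        expr = tpm(counts, lengths)
        total = sum(expr.tpm.values())
        if any(counts.values()):
            assert total == pytest.approx(1_000_000, rel=1e-9)
            doubled = tpm({s: 2 * c for s, c in counts.items()}, lengths)
            for sym in counts:
                assert doubled.tpm[sym] == pytest.approx(expr.tpm[sym], rel=1e-12)
        else:
            assert total == 0.0
        assert all(v >= 0 for v in expr.tpm.values())


class TestCountTableIO:
    def test_round_trip(self, tmp_path, rng):
        table = CountTable(
            counts={f"G{i}": int(rng.integers(0, 100)) for i in range(20)},
            no_feature=int(rng.integers(0, 10)),
            ambiguous=int(rng.integers(0, 10)),
        )
        path = tmp_path / "counts.tsv"
        write_count_table(table, path)
        back = read_count_table(path)
        assert back.counts == table.counts
        assert back.no_feature == table.no_feature
        assert back.ambiguous == table.ambiguous

    def test_format_and_ordering(self, tmp_path):
        path = tmp_path / "c.tsv"
        write_count_table(CountTable(counts={"B": 2, "A": 1}), path)
        lines = path.read_text().splitlines()
        assert lines == ["A\t1", "B\t2", "__no_feature\t0", "__ambiguous\t0"]

    def test_non_integer_count_rejected(self, tmp_path):
        path = tmp_path / "c.tsv"
        path.write_text("A\t1.5\n")
        with pytest.raises(ValueError, match="line 1"):
            read_count_table(path)
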