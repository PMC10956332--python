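"""Gene-model assembly and the size formulas under both conventions."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from genarch import annotation_io as aio
from genarch import feature_sizes as fs


def _rec(ftype, start, end, attrs):
    return aio.GffRecord("chr1", "t", ftype, start, end, ".", "+", ".", attrs)


def _tx(exons, tid="t1", gid="g1", strand="+"):
    return fs.TranscriptModel(tid, gid, "chr1", strand, list(exons))


class TestBuildGeneModels:
    def test_simple_hierarchy(self, toy_gff):
        genes, stats = fs.build_gene_models(aio.read_gff3(toy_gff))
        assert len(genes) == 1
        (gene,) = genes
        assert gene.gene_id == "g1" and len(gene.transcripts) == 1
        assert gene.transcripts[0].exons == [(100, 200), (301, 400)]
        assert stats.orphan_transcripts == 0

    def test_cds_fallback_when_no_exons(self):
        records = [
            _rec("gene", 1, 500, {"ID": ["g1"]}),
            _rec("mRNA", 1, 500, {"ID": ["t1"], "Parent": ["g1"]}),
            _rec("CDS", 10, 100, {"Parent": ["t1"]}),
            _rec("CDS", 200, 300, {"Parent": ["t1"]}),
        ]
        genes, _ = fs.build_gene_models(records)
        assert genes[0].transcripts[0].exons == [(10, 100), (200, 300)]

    def test_two_transcripts_one_gene(self):
        records = [
            _rec("gene", 1, 500, {"ID": ["g1"]}),
            _rec("mRNA", 1, 500, {"ID": ["t1"], "Parent": ["g1"]}),
            _rec("mRNA", 1, 400, {"ID": ["t2"], "Parent": ["g1"]}),
            _rec("exon", 1, 100, {"Parent": ["t1"]}),
            _rec("exon", 1, 90, {"Parent": ["t2"]}),
        ]
        genes, _ = fs.build_gene_models(records)
        assert len(genes) == 1 and len(genes[0].transcripts) == 2

    def test_orphan_transcript_gets_synthesized_gene(self):
        records = [
            _rec("mRNA", 1, 100, {"ID": ["t9"], "Parent": ["missing"]}),
            _rec("exon", 1, 100, {"Parent": ["t9"]}),
        ]
        genes, stats = fs.build_gene_models(records)
        assert len(genes) == 1 and genes[0].gene_id == "gene:t9"
        assert stats.orphan_transcripts == 1

    def test_orphan_exons_and_bare_genes_counted_not_fatal(self):
        records = [
            _rec("gene", 1, 100, {"ID": ["g1"]}),
            _rec("exon", 1, 50, {"Parent": ["nobody"]}),
        ]
        genes, stats = fs.build_gene_models(records)
        assert genes == []
        assert stats.orphan_parts == 1
        assert stats.genes_without_transcripts == 1

    def test_multi_parent_exon_contributes_to_each_transcript(self):
        records = [
            _rec("gene", 1, 500, {"ID": ["g1"]}),
            _rec("mRNA", 1, 500, {"ID": ["t1"], "Parent": ["g1"]}),
            _rec("mRNA", 1, 500, {"ID": ["t2"], "Parent": ["g1"]}),
            _rec("exon", 10, 100, {"Parent": ["t1", "t2"]}),
        ]
        genes, _ = fs.build_gene_models(records)
        assert [t.exons for t in genes[0].transcripts] == [[(10, 100)], [(10, 100)]]


class TestSizeFormulas:
    def test_gene_span_both_conventions(self):
        gene = fs.GeneModel("g", "chr1", 100, 400, "+", [_tx([(100, 400)])])
        assert fs.gene_span_size(gene, "paper") == 300
        assert fs.gene_span_size(gene, "biological") == 301

    def test_degenerate_single_base_gene(self):
        gene = fs.GeneModel("g", "chr1", 5, 5, "+", [_tx([(5, 5)])])
        assert fs.gene_span_size(gene, "paper") == 0
        assert fs.gene_span_size(gene, "biological") == 1

    @pytest.mark.parametrize(
        "convention,exp_exons,exp_introns",
        [("paper", [100, 99], [101]), ("biological", [101, 100], [100])],
    )
    def test_exon_and_intron_sizes(self, convention, exp_exons, exp_introns):
        tx = _tx([(100, 200), (301, 400)])
        assert fs.exon_sizes(tx, convention) == exp_exons
        assert fs.intron_sizes(tx, convention) == exp_introns

    def test_single_exon_transcript_has_no_introns(self):
        tx = _tx([(1, 50)])
        assert fs.exon_sizes(tx, "paper") == [49]
        assert fs.intron_sizes(tx, "paper") == []

    def test_sizes_strand_symmetric(self):
        plus = _tx([(100, 200), (301, 400)], strand="+")
        minus = _tx([(301, 400), (100, 200)], strand="-")
        assert fs.exon_sizes(plus, "paper") == fs.exon_sizes(minus, "paper")
        assert fs.intron_sizes(plus, "paper") == fs.intron_sizes(minus, "paper")


@st.composite
def transcripts(draw):
    """Random exon chains: positive exon lengths, positive intron gaps."""
    k = draw(st.integers(1, 12))
    start = draw(st.integers(1, 10_000))
    exons = []
    pos = start
    for _ in range(k):
        e_len = draw(st.integers(1, 2_000))
        exons.append((pos, pos + e_len - 1))
        pos += e_len + draw(st.integers(1, 5_000))
    return _tx(exons)


class TestSpanIdentity:
    @settings(max_examples=200, derandomize=True)
    @given(transcripts())
    def test_exons_plus_introns_equals_span(self, tx):
        for convention in fs.CONVENTIONS:
            total = sum(fs.exon_sizes(tx, convention)) + sum(
                fs.intron_sizes(tx, convention)
            )
            assert total == fs.transcript_span_size(tx, convention)

    @settings(max_examples=200, derandomize=True)
    @given(transcripts())
    def test_intron_count_and_convention_shift(self, tx):
        assert len(fs.intron_sizes(tx, "paper")) == len(tx.exons) - 1
        e_p, e_b = fs.exon_sizes(tx, "paper"), fs.exon_sizes(tx, "biological")
        i_p, i_b = fs.intron_sizes(tx, "paper"), fs.intron_sizes(tx, "biological")
        assert all(b == p + 1 for p, b in zip(e_p, e_b))
        assert all(b == p - 1 for p, b in zip(i_p, i_b))


class TestFeatureSizeTable:
    def test_hand_arithmetic_example(self):
        gene = fs.GeneModel("g", "chr1", 100, 400, "+",
                            [_tx([(100, 200), (301, 400)])])
        tab = fs.feature_size_table([gene], "sp", "paper")
        assert tab.gene_sizes.tolist() == [300]
        assert tab.exon_sizes.tolist() == [100, 99]
        assert tab.intron_sizes.tolist() == [101]
        assert 100 + 99 + 101 == 300
        assert tab.total_exon_bp == 199 and tab.total_intron_bp == 101

    def test_transcripts_pool_with_duplicates(self):
        tx1 = _tx([(100, 200), (301, 400)], tid="t1")
        tx2 = _tx([(100, 200)], tid="t2")
        gene = fs.GeneModel("g", "chr1", 100, 400, "+", [tx1, tx2])
        tab = fs.feature_size_table([gene], "sp", "paper")
        assert sorted(tab.exon_sizes.tolist()) == [99, 100, 100]
        assert tab.intron_sizes.tolist() == [101]

    def test_empty_input_gives_empty_table(self):
        tab = fs.feature_size_table([], "sp", "paper")
        assert tab.gene_count == 0
        assert tab.total_exon_bp == 0 and tab.total_intron_bp == 0

    def test_nonpositive_sizes_dropped_and_counted(self):
        # zero-length gene span under the paper convention; book-ended exons
        gene = fs.GeneModel("g", "chr1", 5, 5, "+", [_tx([(5, 5)])])
        adjacent = fs.GeneModel(
            "g2", "chr1", 1, 200, "+", [_tx([(1, 100), (101, 200)], tid="t2", gid="g2")]
        )
        tab = fs.feature_size_table([gene, adjacent], "sp", "biological")
        assert tab.dropped_nonpositive["intron"] == 1  # 101-100-1 = 0
        assert tab.gene_sizes.tolist() == [1, 200]
        tab_paper = fs.feature_size_table([gene], "sp", "paper")
        assert tab_paper.dropped_nonpositive["gene"] == 1
        assert tab_paper.gene_count == 0

    def test_feature_rows_long_format(self):
        gene = fs.GeneModel("g", "chr1", 100, 400, "+",
                            [_tx([(100, 200), (301, 400)])])
        rows = list(fs.feature_rows([gene], "sp", "paper"))
        features = [(r["feature"], r["ordinal"], r["size_bp"]) for r in rows]
        assert features == [
            ("gene", 1, 300), ("exon", 1, 100), ("exon", 2, 99), ("intron", 1, 101),
        ]
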