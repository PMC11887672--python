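"""I/O and interval-primitive tests: coordinate conventions and round-trips."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from lncscreen import (
    AnnotationError,
    ExpressionTable,
    GenomicInterval,
    Loop,
    LoopSet,
    PeakSet,
    interval_overlap_bp,
    read_expression,
    read_gene_annotation,
    read_loops,
    read_peaks,
    write_expression,
    write_gene_annotation,
    write_loops,
    write_peaks,
)
from helpers import oracle_overlap_count, random_genes

import pandas as pd


GTF_3GENES = "\n".join(
    [
        'chr1\tsrc\tgene\t101\t200\t.\t+\t.\tgene_id "G1"; gene_name "A"; gene_biotype "protein_coding";',
        'chr1\tsrc\tgene\t301\t400\t.\t-\t.\tgene_id "G2"; gene_name "B"; gene_biotype "lncRNA";',
        'chr2\tsrc\tgene\t501\t600\t.\t+\t.\tgene_id "G3"; gene_name "C"; gene_biotype "other";',
    ]
) + "\n"


class TestGeneAnnotation:
    def test_gtf_coordinates_convert_to_zero_based_half_open(self, tmp_path):
        p = tmp_path / "g.gtf"
        p.write_text(GTF_3GENES)
        genes = {g.gene_id: g for g in read_gene_annotation(p)}
        g1 = genes["G1"]
        assert (g1.body.start, g1.body.end) == (100, 200)
        assert g1.tss == 100
        # minus-strand TSS is the body's right edge (last base)
        assert genes["G2"].tss == 399

    def test_biotype_filter(self, tmp_path):
        p = tmp_path / "g.gtf"
        p.write_text(GTF_3GENES)
        lncs = read_gene_annotation(p, biotype_filter={"lncRNA"})
        assert [g.gene_id for g in lncs] == ["G2"]

    def test_duplicate_gene_id_rejected(self, tmp_path):
        p = tmp_path / "dup.gtf"
        line = 'chr1\tsrc\tgene\t101\t200\t.\t+\t.\tgene_id "G1";\n'
        p.write_text(line + line)
        with pytest.raises(AnnotationError, match="duplicate gene_id"):
            read_gene_annotation(p)

    def test_malformed_line_names_line_number(self, tmp_path):
        p = tmp_path / "bad.gtf"
        p.write_text(GTF_3GENES + "chr1\tonly_two_columns\n")
        with pytest.raises(AnnotationError, match="line 4"):
            read_gene_annotation(p)

    def test_round_trip_identity_on_random_annotation(self, tmp_path):
        rng = np.random.default_rng(7)
        genes = random_genes(rng, 50, "RT", biotype="lncRNA")
        path = tmp_path / "rt.gtf"
        write_gene_annotation(genes, path)
        back = read_gene_annotation(path)
        assert sorted(back, key=lambda g: g.gene_id) == sorted(
            genes, key=lambda g: g.gene_id
        )

    def test_exons_are_read_but_body_is_gene_level(self, tmp_path):
        p = tmp_path / "ex.gtf"
        p.write_text(
            'chr1\tsrc\tgene\t101\t500\t.\t+\t.\tgene_id "G1";\n'
            'chr1\tsrc\texon\t101\t150\t.\t+\t.\tgene_id "G1";\n'
            'chr1\tsrc\texon\t401\t500\t.\t+\t.\tgene_id "G1";\n'
        )
        (g,) = read_gene_annotation(p)
        assert (g.body.start, g.body.end) == (100, 500)
        assert [(e.start, e.end) for e in g.exons] == [(100, 150), (400, 500)]


class TestPeaks:
    def test_bed_ingested_verbatim(self, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text("chr1\t100\t200\n")
        ps = read_peaks(p, "H3K27ac")
        assert ps.intervals == [GenomicInterval("chr1", 100, 200)]
        assert ps.scores is None

    def test_zero_length_record_rejected(self, tmp_path):
        p = tmp_path / "z.bed"
        p.write_text("chr1\t100\t100\n")
        with pytest.raises(AnnotationError):
            read_peaks(p, "H3K27ac")

    def test_score_column_used_when_present(self, tmp_path):
        p = tmp_path / "s.bed"
        p.write_text("chr1\t100\t200\tpk\t7.5\t+\n")
        ps = read_peaks(p, "DNase")
        assert ps.scores == [7.5]
        assert ps.intervals[0].strand == "+"

    def test_round_trip_of_1000_random_peaks(self, tmp_path):
        rng = np.random.default_rng(11)
        ivs = []
        for _ in range(1000):
            start = int(rng.integers(0, 10_000_000))
            ivs.append(
                GenomicInterval(f"chr{int(rng.integers(1, 6))}", start,
                                start + int(rng.integers(1, 5_000)))
            )
        ps = PeakSet("CTCF", ivs, scores=[float(i) for i in range(1000)])
        path = tmp_path / "rt.bed"
        write_peaks(ps, path)
        back = read_peaks(path, "CTCF")
        assert back.intervals == ps.intervals
        assert back.scores == ps.scores

    def test_scores_length_mismatch_rejected(self):
        with pytest.raises(AnnotationError, match="scores"):
            PeakSet("H3K27ac", [GenomicInterval("chr1", 0, 10)], scores=[1.0, 2.0])

    def test_overlap_count_agrees_with_pairwise_oracle(self):
        rng = np.random.default_rng(5)
        ivs = []
        for _ in range(1000):
            start = int(rng.integers(0, 1_000_000))
            ivs.append(GenomicInterval(f"chr{int(rng.integers(1, 4))}", start,
                                       start + int(rng.integers(1, 3_000))))
        ps = PeakSet("H3K4me1", ivs)
        for _ in range(50):
            qs = int(rng.integers(0, 1_000_000))
            q = GenomicInterval(f"chr{int(rng.integers(1, 4))}", qs,
                                qs + int(rng.integers(1, 10_000)))
            assert ps.overlap_count(q) == oracle_overlap_count(q, ivs)


class TestLoops:
    def test_bedpe_row_becomes_one_loop(self, tmp_path):
        p = tmp_path / "l.bedpe"
        p.write_text("chr3\t100\t5100\tchr3\t900100\t905100\n")
        ls = read_loops(p)
        assert len(ls) == 1
        assert ls.loops[0].anchor_a == GenomicInterval("chr3", 100, 5100)
        assert ls.loops[0].anchor_b == GenomicInterval("chr3", 900100, 905100)

    def test_empty_file_gives_empty_loopset(self, tmp_path):
        p = tmp_path / "e.bedpe"
        p.write_text("")
        assert len(read_loops(p)) == 0

    def test_short_row_rejected(self, tmp_path):
        p = tmp_path / "short.bedpe"
        p.write_text("chr1\t100\t200\tchr1\t300\n")
        with pytest.raises(AnnotationError, match="6 columns"):
            read_loops(p)

    def test_round_trip_identity(self, tmp_path):
        rng = np.random.default_rng(3)
        loops = []
        for i in range(200):
            a = int(rng.integers(0, 1_000_000))
            b = a + int(rng.integers(50_000, 2_000_000))
            loops.append(
                Loop(GenomicInterval("chr1", a, a + 5000),
                     GenomicInterval("chr1", b, b + 5000), float(i))
            )
        path = tmp_path / "rt.bedpe"
        write_loops(LoopSet(loops), path)
        assert read_loops(path).loops == loops


class TestExpression:
    def test_round_trip_and_metadata(self, tmp_path):
        df = pd.DataFrame(
            {"H1ESC": [3.2, 0.0], "GSC": [0.5, 9.1]}, index=["L1", "L2"]
        )
        table = ExpressionTable(df)
        path = tmp_path / "e.tsv"
        write_expression(table, path)
        back = read_expression(path)
        assert back.cell_lines == ["H1ESC", "GSC"]
        assert np.allclose(back.data.to_numpy(), df.to_numpy())

    def test_negative_values_rejected(self):
        df = pd.DataFrame({"H1ESC": [-1.0]}, index=["L1"])
        with pytest.raises(AnnotationError, match="negative"):
            ExpressionTable(df)


class TestIntervalOverlap:
    @pytest.mark.parametrize(
        "a, b, expected",
        [
            (("chr1", 100, 200), ("chr1", 150, 250), 50),
            (("chr1", 100, 200), ("chr1", 200, 300), 0),  # half-open abutment
            (("chr1", 100, 200), ("chr2", 100, 200), 0),  # different chrom
            (("chr1", 0, 1000), ("chr1", 400, 600), 200),  # containment
        ],
    )
    def test_examples(self, a, b, expected):
        assert interval_overlap_bp(GenomicInterval(*a), GenomicInterval(*b)) == expected

    @given(
        s1=st.integers(0, 10_000), l1=st.integers(1, 500),
        s2=st.integers(0, 10_000), l2=st.integers(1, 500),
        shift=st.integers(0, 1_000),
    )
    def test_symmetric_nonnegative_shift_invariant(self, s1, l1, s2, l2, shift):
        a = GenomicInterval("chr1", s1, s1 + l1)
        b = GenomicInterval("chr1", s2, s2 + l2)
        ov = interval_overlap_bp(a, b)
        assert ov == interval_overlap_bp(b, a)
        assert 0 <= ov <= min(l1, l2)
        assert ov == interval_overlap_bp(a.shift(shift), b.shift(shift))

    def test_invalid_interval_rejected(self):
        with pytest.raises(AnnotationError):
            GenomicInterval("chr1", 200, 100)
        with pytest.raises(AnnotationError):
            GenomicInterval("chr1", 100, 100)
        with pytest.raises(AnnotationError):
            GenomicInterval("", 0, 10)
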