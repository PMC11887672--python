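"""Locus-state calls (criterion d), element classification, expression gate."""

import numpy as np
import pandas as pd
import pytest

from lncscreen import (
    ExpressionTable,
    GenomicInterval,
    PeakSet,
    classify_element,
    classify_locus,
    is_expressed,
)

LOCUS = GenomicInterval("chr1", 10_000, 20_000)


def peakset(mark, *spans):
    return PeakSet(mark, [GenomicInterval("chr1", s, e) for s, e in spans])


class TestClassifyLocus:
    def test_single_active_mark_gives_active_state(self):
        call = classify_locus(LOCUS, [peakset("H3K27ac", (12_000, 13_000))])
        assert call.state == "active"
        assert call.passes_criterion

    def test_repressive_only_locus_still_passes(self):
        call = classify_locus(LOCUS, [peakset("H3K9me3", (12_000, 13_000))])
        assert call.state == "repressed"
        assert call.passes_criterion

    def test_unmarked_locus_fails(self):
        call = classify_locus(LOCUS, [peakset("H3K27ac", (500_000, 501_000))])
        assert call.state == "none"
        assert not call.passes_criterion

    def test_both_mark_families_give_both(self):
        call = classify_locus(
            LOCUS,
            [peakset("H3K36me3", (11_000, 12_000)), peakset("H3K27me3", (15_000, 16_000))],
        )
        assert call.state == "both"
        assert call.passes_criterion

    def test_flank_captures_promoter_marks_past_the_edge(self):
        near = [peakset("H3K27ac", (20_500, 21_000))]
        assert classify_locus(LOCUS, near, flank_bp=0).state == "none"
        assert classify_locus(LOCUS, near, flank_bp=2_000).state == "active"

    def test_abutting_peak_with_zero_flank_is_absent(self):
        # half-open: a peak ending exactly at locus.start does not overlap
        call = classify_locus(LOCUS, [peakset("H3K27ac", (9_000, 10_000))], flank_bp=0)
        assert call.state == "none"

    def test_negative_flank_rejected(self):
        with pytest.raises(ValueError):
            classify_locus(LOCUS, [], flank_bp=-1)


ELEMENT = GenomicInterval("chr1", 10_000, 11_500)


def hub_peaks(flank_left=2_000, flank_right=3_000):
    """H3K4me3+H3K27ac+DNase on the element, H3K4me1 in both flanks."""
    return [
        peakset("H3K4me3", (10_000, 11_500)),
        peakset("H3K27ac", (10_000, 11_500)),
        peakset("DNase", (10_000, 11_500)),
        peakset("H3K4me1",
                (10_000 - flank_left - 500, 10_000 - flank_left),
                (11_500 + flank_right, 11_500 + flank_right + 500)),
    ]


class TestClassifyElement:
    def test_full_active_signature_is_hub_enhancer(self):
        elem = classify_element(ELEMENT, hub_peaks(), h3k4me1_flank_bp=5_000)
        assert elem.element_class == "hub_enhancer"
        assert elem.evidence["H3K4me1_flank"]
        assert elem.evidence["DNase"]

    def test_h3k4me1_beyond_flank_demotes_to_enhancer_or_none(self):
        elem = classify_element(ELEMENT, hub_peaks(8_000, 8_000), h3k4me1_flank_bp=5_000)
        assert elem.element_class != "hub_enhancer"

    def test_one_sided_h3k4me1_is_not_flanked(self):
        peaks = [
            peakset("H3K4me3", (10_000, 11_500)),
            peakset("H3K27ac", (10_000, 11_500)),
            peakset("H3K4me1", (7_000, 8_000)),  # left side only
        ]
        elem = classify_element(ELEMENT, peaks, h3k4me1_flank_bp=5_000)
        assert not elem.evidence["H3K4me1_flank"]
        assert elem.element_class == "enhancer"  # H3K27ac + flanking H3K4me1

    def test_h3k27ac_with_overlapping_h3k4me1_is_plain_enhancer(self):
        peaks = [peakset("H3K27ac", (10_000, 11_500)),
                 peakset("H3K4me1", (9_800, 11_700))]
        assert classify_element(ELEMENT, peaks).element_class == "enhancer"

    def test_dnase_only_is_open_chromatin(self):
        assert (
            classify_element(ELEMENT, [peakset("DNase", (10_200, 10_800))]).element_class
            == "open_chromatin"
        )

    def test_repressive_only_is_repressed(self):
        assert (
            classify_element(ELEMENT, [peakset("H3K27me3", (10_000, 11_500))]).element_class
            == "repressed"
        )

    def test_no_marks_is_none(self):
        assert classify_element(ELEMENT, []).element_class == "none"

    def test_tf_tracks_reported_as_occupancy(self):
        peaks = hub_peaks() + [peakset("NANOG", (10_100, 10_400)),
                               peakset("YY1", (500_000, 500_300))]
        elem = classify_element(ELEMENT, peaks)
        assert elem.tf_occupancy == ("NANOG",)

    def test_peakset_order_is_irrelevant(self):
        peaks = hub_peaks() + [peakset("NANOG", (10_100, 10_400))]
        a = classify_element(ELEMENT, peaks)
        b = classify_element(ELEMENT, list(reversed(peaks)))
        assert (a.element_class, a.evidence, a.tf_occupancy) == (
            b.element_class, b.evidence, b.tf_occupancy
        )

    def test_adding_peaks_never_demotes_a_hub(self):
        rng = np.random.default_rng(13)
        peaks = hub_peaks()
        for mark in ("H3K27ac", "H3K9me3", "H3K4me1", "DNase", "H3K27me3"):
            extra_spans = []
            for _ in range(5):
                s = int(rng.integers(8_000, 13_000))
                extra_spans.append((s, s + int(rng.integers(100, 1_000))))
            peaks = peaks + [peakset(mark, *extra_spans)]
            assert classify_element(ELEMENT, peaks).element_class == "hub_enhancer"

    def test_adding_peaks_never_fails_a_passing_locus(self):
        base = [peakset("H3K27ac", (12_000, 13_000))]
        assert classify_locus(LOCUS, base).passes_criterion
        more = base + [peakset("H3K9me3", (11_000, 18_000)),
                       peakset("H3K36me3", (14_000, 15_000))]
        assert classify_locus(LOCUS, more).passes_criterion


class TestIsExpressed:
    @pytest.fixture()
    def table(self):
        df = pd.DataFrame(
            {"H1ESC": [3.2, 0.0, 0.0], "GSC": [0.0, 0.0, 5.0]},
            index=["L1", "L2", "L3"],
        )
        return ExpressionTable(df)

    def test_expressed_above_threshold(self, table):
        assert is_expressed("L1", table, {"H1ESC"}, 1.0)

    def test_silent_in_all_named_columns(self, table):
        assert not is_expressed("L2", table, {"H1ESC", "GSC"}, 1.0)

    def test_expression_in_unscreened_column_does_not_count(self, table):
        assert not is_expressed("L3", table, {"H1ESC"}, 1.0)
        assert is_expressed("L3", table, {"GSC"}, 1.0)

    def test_missing_gene_counts_as_not_transcribed(self, table):
        assert not is_expressed("UNKNOWN", table, {"H1ESC"}, 1.0)

    def test_unknown_cell_line_is_an_error(self, table):
        with pytest.raises(KeyError):
            is_expressed("L1", table, {"K562"}, 1.0)
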