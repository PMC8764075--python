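"""Regulatory annotation, loop classification, signals, trends."""

import numpy as np
import pandas as pd
import pytest

from hicdyn import (assign_genes, boundary_metaprofile, build_annotation,
                    classify_interaction, engagement_summary, expression_trend,
                    signal_on_regions, tf_engagement)


def peaks(rows):
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


@pytest.fixture
def annotation(genes_frame):
    # genes at TSS 100_000 and 400_000 -> promoter windows +/- 5 kb
    k27 = peaks([
        ("chr1", 200_000, 201_000),   # distal -> enhancer
        ("chr1", 104_999, 106_000),   # straddles promoter edge by 1 bp -> excluded
        ("chr1", 106_000, 107_000),   # starts exactly at promoter end -> enhancer
        ("chr1", 395_500, 396_500),   # inside promoter window -> excluded
    ])
    return build_annotation(genes_frame, k27)


class TestBuildAnnotation:
    def test_promoter_windows(self, annotation):
        p = annotation.promoters
        assert list(p["start"]) == [95_000, 395_000]
        assert list(p["end"]) == [105_000, 405_000]

    def test_whole_peak_exclusion(self, annotation):
        e = annotation.enhancers
        assert list(e["start"]) == [200_000, 106_000]

    def test_one_bp_straddle_excluded(self, genes_frame):
        # peak [104_999, 105_000) overlaps the promoter's last bp
        ann = build_annotation(genes_frame, peaks([("chr1", 104_999, 105_000)]))
        assert len(ann.enhancers) == 0

    def test_touching_peak_kept(self, genes_frame):
        # half-open intervals: [105_000, 106_000) does not intersect
        ann = build_annotation(genes_frame, peaks([("chr1", 105_000, 106_000)]))
        assert len(ann.enhancers) == 1

    def test_overlap_queries(self, annotation):
        assert annotation.overlaps_promoter("chr1", 99_000, 99_500)
        assert not annotation.overlaps_promoter("chr1", 105_000, 110_000)
        assert annotation.overlaps_enhancer("chr1", 200_500, 200_600)
        assert not annotation.overlaps_enhancer("chr2", 200_500, 200_600)


def loop_row(s1, e1, s2, e2, chrom="chr1"):
    return pd.Series({"chrom": chrom, "start1": s1, "end1": e1,
                      "start2": s2, "end2": e2})


class TestClassifyInteraction:
    def test_ep_loop(self, annotation):
        out = classify_interaction(loop_row(99_000, 101_000, 200_000, 202_000),
                                   annotation)
        assert out == {"anchor1_label": "P", "anchor2_label": "E",
                       "class": "E-P"}

    def test_pp_loop(self, annotation):
        out = classify_interaction(loop_row(99_000, 101_000, 399_000, 401_000),
                                   annotation)
        assert out["class"] == "P-P"

    def test_ee_loop(self, annotation):
        out = classify_interaction(loop_row(106_000, 106_500, 200_000, 201_000),
                                   annotation)
        assert out["class"] == "E-E"

    def test_promoter_precedence(self, genes_frame):
        # an anchor touching both a promoter and an enhancer is labelled P
        ann = build_annotation(genes_frame, peaks([("chr1", 110_000, 112_000)]))
        out = classify_interaction(loop_row(104_000, 111_000, 200_000, 201_000),
                                   ann)
        assert out["anchor1_label"] == "P"

    def test_other_class(self, annotation):
        out = classify_interaction(loop_row(150_000, 151_000, 300_000, 301_000),
                                   annotation)
        assert out["class"] == "other"


class TestTfEngagement:
    def _labels(self, annotation, loop):
        return classify_interaction(loop, annotation)

    def test_promoter_only(self, annotation):
        loop = loop_row(99_000, 101_000, 200_000, 202_000)  # P then E
        tf = peaks([("chr1", 100_000, 100_500)])
        out = tf_engagement(loop, self._labels(annotation, loop), tf)
        assert out == {"engaged": True, "subtype": "promoter-only"}

    def test_enhancer_only(self, annotation):
        loop = loop_row(99_000, 101_000, 200_000, 202_000)
        tf = peaks([("chr1", 200_500, 200_900)])
        out = tf_engagement(loop, self._labels(annotation, loop), tf)
        assert out == {"engaged": True, "subtype": "enhancer-only"}

    def test_both_anchors(self, annotation):
        loop = loop_row(99_000, 101_000, 200_000, 202_000)
        tf = peaks([("chr1", 100_000, 100_500), ("chr1", 200_500, 200_900)])
        out = tf_engagement(loop, self._labels(annotation, loop), tf)
        assert out == {"engaged": True, "subtype": "both"}

    def test_not_engaged(self, annotation):
        loop = loop_row(99_000, 101_000, 200_000, 202_000)
        tf = peaks([("chr1", 900_000, 901_000)])
        out = tf_engagement(loop, self._labels(annotation, loop), tf)
        assert out == {"engaged": False, "subtype": "none"}

    def test_non_ep_rejected(self, annotation):
        loop = loop_row(99_000, 101_000, 399_000, 401_000)  # P-P
        with pytest.raises(ValueError):
            tf_engagement(loop, self._labels(annotation, loop), peaks([]))


class TestEngagementSummary:
    def test_counts_and_fractions(self):
        df = pd.DataFrame({
            "class": ["E-P", "E-P", "E-P", "E-P", "P-P", "E-E"],
            "engaged": [True, True, False, False, False, False],
            "subtype": ["both", "enhancer-only", "none", "none", "none", "none"],
        })
        out = engagement_summary(df)
        assert out["class_counts"] == {"E-P": 4, "P-P": 1, "E-E": 1}
        assert out["ep_engaged_fraction"] == pytest.approx(0.5)
        assert out["ep_engaged_count"] == 2
        assert out["ep_subtype_counts"] == {"both": 1, "enhancer-only": 1}

    def test_no_ep_loops_nan_fraction(self):
        df = pd.DataFrame({"class": ["P-P"], "engaged": [False],
                           "subtype": ["none"]})
        out = engagement_summary(df)
        assert np.isnan(out["ep_engaged_fraction"])


class TestAssignGenes:
    def test_within_distance(self, genes_frame):
        # g1 TSS 100_000: 15 kb from anchor1 end -> assigned
        loop = loop_row(110_000, 115_000, 300_000, 305_000)
        loop["start1"], loop["end1"] = 115_000, 120_000
        assert assign_genes(loop, genes_frame) == ["g1"]

    def test_beyond_distance(self, genes_frame):
        loop = loop_row(125_000, 130_000, 300_000, 305_000)
        assert assign_genes(loop, genes_frame) == []  # 25 kb away

    def test_tss_inside_anchor(self, genes_frame):
        loop = loop_row(95_000, 105_000, 395_000, 405_000)
        assert assign_genes(loop, genes_frame) == ["g1", "g2"]

    def test_chromosome_filter(self, genes_frame):
        loop = loop_row(95_000, 105_000, 395_000, 405_000, chrom="chr2")
        assert assign_genes(loop, genes_frame) == []


def coverage(rows):
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "value"])


class TestSignalOnRegions:
    def test_hand_value(self):
        # 0.05 reads/bp over 20 kb inside a peak = 1000 reads -> CPM at 1e6
        cov = coverage([("chr1", 0, 20_000, 0.05)])
        pk = peaks([("chr1", 0, 20_000)])
        regs = pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [20_000]})
        out = signal_on_regions(cov, pk, regs, library_size=1e6)
        assert out["signal"].iloc[0] == pytest.approx(1000.0)

    def test_outside_peaks_zero(self):
        cov = coverage([("chr1", 0, 50_000, 1.0)])
        pk = peaks([("chr1", 100_000, 110_000)])
        regs = pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [50_000]})
        out = signal_on_regions(cov, pk, regs, library_size=1e6)
        assert out["signal"].iloc[0] == 0.0

    def test_library_scaling(self):
        cov = coverage([("chr1", 0, 10_000, 0.2)])
        pk = peaks([("chr1", 0, 10_000)])
        regs = pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [10_000]})
        a = signal_on_regions(cov, pk, regs, library_size=1e6)["signal"].iloc[0]
        b = signal_on_regions(cov, pk, regs, library_size=2e6)["signal"].iloc[0]
        assert a == pytest.approx(2 * b)

    def test_additive_over_disjoint_peaks(self):
        cov = coverage([("chr1", 0, 100_000, 0.1)])
        regs = pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [100_000]})
        s_both = signal_on_regions(
            cov, peaks([("chr1", 0, 10_000), ("chr1", 50_000, 60_000)]),
            regs, library_size=1e6)["signal"].iloc[0]
        s1 = signal_on_regions(cov, peaks([("chr1", 0, 10_000)]),
                               regs, library_size=1e6)["signal"].iloc[0]
        s2 = signal_on_regions(cov, peaks([("chr1", 50_000, 60_000)]),
                               regs, library_size=1e6)["signal"].iloc[0]
        assert s_both == pytest.approx(s1 + s2)

    def test_partial_overlap_clipped(self):
        cov = coverage([("chr1", 0, 100_000, 1.0)])
        pk = peaks([("chr1", 0, 30_000)])
        regs = pd.DataFrame({"chrom": ["chr1"], "start": [20_000],
                             "end": [50_000]})
        out = signal_on_regions(cov, pk, regs, library_size=1e6)
        assert out["signal"].iloc[0] == pytest.approx(10_000.0)

    def test_zero_library_rejected(self):
        with pytest.raises(ValueError):
            signal_on_regions(coverage([]), peaks([]),
                              pd.DataFrame({"chrom": [], "start": [], "end": []}),
                              library_size=0)


class TestBoundaryMetaprofile:
    chrom_lengths = {"chr1": 20_000_000}

    def _boundaries(self, centers):
        return pd.DataFrame({
            "chrom": "chr1",
            "start": [c - 20_000 for c in centers],
            "end": [c + 20_000 for c in centers],
        })

    def test_offsets_and_length(self):
        cov = coverage([("chr1", 0, 20_000_000, 0.01)])
        pk = peaks([("chr1", 0, 20_000_000)])
        out = boundary_metaprofile(cov, pk, self._boundaries([10_000_000]),
                                   self.chrom_lengths)
        assert len(out["offset_bp"]) == 101
        assert out["offset_bp"][0] == -500_000
        assert out["offset_bp"][50] == 0
        assert out["offset_bp"][-1] == 500_000

    def test_flat_coverage_flat_profile(self):
        cov = coverage([("chr1", 0, 20_000_000, 0.01)])
        pk = peaks([("chr1", 0, 20_000_000)])
        out = boundary_metaprofile(cov, pk, self._boundaries([5_000_000,
                                                              10_000_000]),
                                   self.chrom_lengths)
        assert np.allclose(out["signal"], out["signal"][0])
        assert out["n_used"] == 2 and out["n_skipped"] == 0

    def test_peak_at_centre_maximises_zero_offset(self):
        c = 10_000_000
        cov = coverage([("chr1", c - 4_000, c + 4_000, 2.0)])
        pk = peaks([("chr1", c - 4_000, c + 4_000)])
        out = boundary_metaprofile(cov, pk, self._boundaries([c]),
                                   self.chrom_lengths)
        assert np.argmax(out["signal"]) == 50

    def test_edge_boundary_skipped(self):
        cov = coverage([("chr1", 0, 20_000_000, 0.01)])
        pk = peaks([("chr1", 0, 20_000_000)])
        out = boundary_metaprofile(cov, pk,
                                   self._boundaries([100_000, 10_000_000]),
                                   self.chrom_lengths)
        assert out["n_used"] == 1 and out["n_skipped"] == 1

    def test_empty_boundaries_rejected(self):
        with pytest.raises(ValueError):
            boundary_metaprofile(coverage([]), peaks([]),
                                 self._boundaries([]), self.chrom_lengths)

    def test_library_scaling(self):
        cov = coverage([("chr1", 0, 20_000_000, 0.01)])
        pk = peaks([("chr1", 0, 20_000_000)])
        bnd = self._boundaries([10_000_000])
        raw = boundary_metaprofile(cov, pk, bnd, self.chrom_lengths)
        cpm = boundary_metaprofile(cov, pk, bnd, self.chrom_lengths,
                                   library_size=2e6)
        assert np.allclose(cpm["signal"], raw["signal"] / 2)


class TestExpressionTrend:
    def test_up(self):
        assert expression_trend([1, 2, 3, 4]) == "up"

    def test_down(self):
        assert expression_trend([4, 3, 2, 1]) == "down"

    def test_transient(self):
        assert expression_trend([1, 3, 1.5, 4]) == "transient"

    def test_flat_within_dead_band(self):
        assert expression_trend([1.0, 1.2, 1.05, 1.1]) == "flat"

    def test_monotone_but_all_small_deltas_is_flat(self):
        assert expression_trend([1.0, 1.2, 1.4, 1.6]) == "flat"

    def test_one_large_delta_with_small_same_sign_is_up(self):
        assert expression_trend([1.0, 1.1, 1.5, 1.6]) == "up"

    def test_small_opposite_delta_is_transient(self):
        # mixed signs once any delta exceeds the dead band
        assert expression_trend([1.0, 0.9, 1.5, 1.6]) == "transient"

    def test_wrong_length_rejected(self):
        with pytest.raises(ValueError):
            expression_trend([1, 2, 3])

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            expression_trend([1, 2, np.nan, 4])
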