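"""Variant filtering, density segmentation, and candidate selection."""

import itertools

import numpy as np
import pandas as pd
import pytest

import ailqtl as aq
from ailqtl.density import (
    filter_candidates,
    filter_high_quality,
    intersect_intervals,
    merge_intervals,
    total_length,
)


def variant(chrom="chr1", pos=100, depth=30, fdr=0.01, zyg_a="hom_alt",
            zyg_b="hom_ref", feature="exonic", effect="deleterious_missense",
            gene="g1"):
    return dict(chrom=chrom, pos=pos, depth=depth, fdr=fdr, zyg_a=zyg_a,
                zyg_b=zyg_b, feature=feature, effect_class=effect, gene=gene)


class TestQualityFilter:
    def test_depth_below_eight_rejected(self):
        v = pd.DataFrame([variant(depth=7)])
        kept, reasons = filter_high_quality(v)
        assert len(kept) == 0 and reasons["depth"] == 1

    def test_clean_strain_discriminating_variant_kept(self):
        v = pd.DataFrame([variant(depth=30, fdr=0.01)])
        kept, _ = filter_high_quality(v)
        assert len(kept) == 1

    def test_depth_exactly_eight_kept(self):
        kept, _ = filter_high_quality(pd.DataFrame([variant(depth=8)]))
        assert len(kept) == 1

    def test_fdr_boundary_inclusive(self):
        kept, _ = filter_high_quality(pd.DataFrame([variant(fdr=0.10)]))
        assert len(kept) == 1
        kept, reasons = filter_high_quality(pd.DataFrame([variant(fdr=0.11)]))
        assert len(kept) == 0 and reasons["fdr"] == 1

    @pytest.mark.parametrize("za,zb,ok", [
        ("hom_alt", "hom_ref", True),
        ("hom_alt", "het", True),
        ("het", "hom_alt", True),
        ("het", "het", False),
        ("hom_alt", "hom_alt", False),
        ("hom_ref", "hom_ref", False),
    ])
    def test_zygosity_pattern(self, za, zb, ok):
        kept, _ = filter_high_quality(pd.DataFrame([variant(zyg_a=za, zyg_b=zb)]))
        assert (len(kept) == 1) is ok

    def test_malformed_zygosity_rejected_with_reason(self):
        kept, reasons = filter_high_quality(pd.DataFrame([variant(zyg_a="weird")]))
        assert len(kept) == 0 and reasons["malformed"] == 1


class TestBinning:
    GENOME = {"chr1": 2_500_000}

    def test_zero_variants_gives_zero_counts(self):
        empty = pd.DataFrame(columns=["chrom", "pos"])
        prof = aq.bin_density(empty, self.GENOME, 600_000)
        assert (prof.bins["count"] == 0).all()
        assert prof.bins["count"].sum() == 0

    def test_single_variant_lands_in_one_bin(self):
        v = pd.DataFrame([{"chrom": "chr1", "pos": 700_001}])
        prof = aq.bin_density(v, self.GENOME, 600_000)
        assert prof.bins["count"].sum() == 1
        hit = prof.bins[prof.bins["count"] == 1].iloc[0]
        assert hit["start"] == 600_000

    def test_terminal_partial_bin_keeps_true_width(self):
        prof = aq.bin_density(pd.DataFrame(columns=["chrom", "pos"]),
                              self.GENOME, 600_000)
        assert prof.bins.iloc[-1]["width"] == 100_000
        assert prof.bins["width"].sum() == 2_500_000

    def test_counts_are_conserved(self, fixtures):
        hq, _ = filter_high_quality(fixtures.variants)
        prof = aq.bin_density(hq, fixtures.genome, 600_000)
        assert prof.bins["count"].sum() == len(hq)

    def test_bin_size_must_be_positive(self):
        with pytest.raises(ValueError):
            aq.bin_density(pd.DataFrame(columns=["chrom", "pos"]), self.GENOME, 0)

    def test_planted_blocks_make_bimodal_sweep(self, fixtures):
        hq, _ = filter_high_quality(fixtures.variants)
        sweep = aq.sweep_bin_sizes(hq, fixtures.genome,
                                   sizes=[100_000, 600_000, 1_100_000])
        assert sweep.loc[sweep["bin_size"] == 600_000, "bimodality"].iloc[0] > 0.5


class TestSegmentation:
    def test_cutoff_is_inclusive(self):
        bins = pd.DataFrame({"chrom": "chr1", "start": [0, 600_000],
                             "end": [600_000, 1_200_000], "width": 600_000,
                             "count": [1000, 999]})
        prof = aq.DensityProfile(600_000, bins, {"chr1": 1_200_000})
        segs = aq.classify_density(prof, 1000)
        assert len(segs) == 1
        assert segs.iloc[0]["end"] == 600_000

    def test_adjacent_high_bins_merge(self):
        bins = pd.DataFrame({"chrom": "chr1",
                             "start": [0, 600_000, 1_200_000, 1_800_000],
                             "end": [600_000, 1_200_000, 1_800_000, 2_400_000],
                             "width": 600_000,
                             "count": [1500, 1200, 10, 1100]})
        prof = aq.DensityProfile(600_000, bins, {"chr1": 2_400_000})
        segs = aq.classify_density(prof, 1000)
        assert segs.to_dict("records") == [
            {"chrom": "chr1", "start": 0, "end": 1_200_000},
            {"chrom": "chr1", "start": 1_800_000, "end": 2_400_000}]

    def test_all_below_cutoff_gives_empty_set(self, fixtures):
        hq, _ = filter_high_quality(fixtures.variants)
        prof = aq.bin_density(hq, fixtures.genome, 600_000)
        assert len(aq.classify_density(prof, 10**9)) == 0

    def test_planted_blocks_recovered_within_one_bin(self, fixtures):
        hq, _ = filter_high_quality(fixtures.variants)
        prof = aq.bin_density(hq, fixtures.genome, 600_000)
        segs = aq.classify_density(prof, 1000)
        for _, blk in fixtures.high_blocks.iterrows():
            cover = segs[(segs["chrom"] == blk["chrom"])
                         & (segs["start"] <= blk["start"] + 600_000)
                         & (segs["end"] >= blk["end"] - 600_000)]
            assert len(cover) >= 1, f"block {blk.tolist()} not recovered"


class TestIntersectQtl:
    def test_percent_retained_arithmetic(self):
        qtl = pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [264_100_000]})
        segs = pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [109_500_000]})
        _, summary = aq.intersect_qtl(qtl, segs)
        assert summary["total_mb_before"] == pytest.approx(264.1)
        assert summary["total_mb_after"] == pytest.approx(109.5)
        assert round(summary["percent_retained"], 1) == 41.5

    def test_disjoint_sets_retain_nothing(self):
        qtl = pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [100]})
        segs = pd.DataFrame({"chrom": ["chr1"], "start": [200], "end": [300]})
        retained, summary = aq.intersect_qtl(qtl, segs)
        assert len(retained) == 0 and summary["percent_retained"] == 0.0

    def test_full_coverage_retains_everything(self):
        qtl = pd.DataFrame({"chrom": ["chr1"], "start": [100], "end": [200]})
        segs = pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [1000]})
        _, summary = aq.intersect_qtl(qtl, segs)
        assert summary["percent_retained"] == pytest.approx(100.0)

    def test_empty_qtl_set_rejected(self):
        with pytest.raises(ValueError):
            aq.intersect_qtl(pd.DataFrame(columns=["chrom", "start", "end"]),
                             pd.DataFrame(columns=["chrom", "start", "end"]))

    def test_intersection_bounded_by_both_sets(self, fixtures):
        hq, _ = filter_high_quality(fixtures.variants)
        segs = aq.classify_density(aq.bin_density(hq, fixtures.genome, 600_000), 1000)
        qtl = pd.DataFrame({"chrom": ["chr1"], "start": [1_000_000],
                            "end": [20_000_000]})
        retained, _ = aq.intersect_qtl(qtl, segs)
        assert total_length(retained) <= min(total_length(qtl), total_length(segs))


class TestExpressedGenes:
    def test_cpm_rule(self):
        counts = pd.DataFrame({
            "s1": [12, 500, 0], "s2": [12, 0, 0], "s3": [0, 0, 0],
        }, index=["borderline", "one_sample_only", "silent"])
        counts.loc["filler"] = [10_000, 10_000, 10_000]
        got = aq.expressed_genes(counts)
        # 12/10012 * 1e6 ~ 1198 CPM in two samples -> expressed
        assert "borderline" in got
        assert "one_sample_only" not in got   # CPM high but in one sample only
        assert "silent" not in got

    def test_strictly_greater_than_one(self):
        counts = pd.DataFrame({"s1": [1, 999_999], "s2": [1, 999_999]},
                              index=["exactly_one_cpm", "big"])
        # library size 1e6 -> CPM of 1 exactly; strict rule excludes it
        assert "exactly_one_cpm" not in aq.expressed_genes(counts)

    def test_all_zero_matrix_rejected_for_zero_library(self):
        counts = pd.DataFrame({"s1": [0], "s2": [0]}, index=["g"])
        with pytest.raises(ValueError, match="library"):
            aq.expressed_genes(counts)


class TestCandidates:
    def _inputs(self):
        qtl = pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [10_000]})
        segs = pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [5_000]})
        rows = [variant(pos=p, gene=g, effect=e)
                for p, g, e in [(100, "g1", "high_impact"),
                                (4000, "g1", "deleterious_missense"),
                                (6000, "g2", "nonframeshift_deletion"),
                                (7000, "g3", "other"),          # class filtered
                                (8000, "g4", "high_impact"),    # not expressed
                                (20_000, "g1", "high_impact")]]  # outside QTL
        return pd.DataFrame(rows), qtl, {"g1", "g2", "g3"}, segs

    def test_filters_and_summaries(self):
        variants, qtl, expressed, segs = self._inputs()
        cand, summary = filter_candidates(variants, qtl, expressed, segments=segs)
        assert len(cand) == 3
        assert summary["per_gene"] == {"g1": 2, "g2": 1}
        assert summary["n_in_high_density"] == 2
        assert summary["percent_in_high_density"] == pytest.approx(100 * 2 / 3)
        assert summary["candidates_per_qtl"] == pytest.approx(3.0)

    def test_printed_count_arithmetic(self):
        """92 candidates, 84 inside high-density segments, over 37 QTL."""
        qtl = pd.DataFrame({"chrom": "chr1",
                            "start": np.arange(37) * 30_000,
                            "end": np.arange(37) * 30_000 + 30_000})
        segs = pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [840_000]})
        pos = np.arange(92) * 10_000 + 100      # first 84 fall inside segments
        v = pd.DataFrame([variant(pos=int(p)) for p in pos])
        cand, summary = filter_candidates(v, qtl, {"g1"}, segments=segs)
        assert summary["n_candidates"] == 92
        assert round(summary["percent_in_high_density"], 1) == 91.3
        assert round(summary["candidates_per_qtl"], 1) == 2.5

    def test_no_variants_in_qtl_gives_empty_summaries(self):
        variants, _, expressed, segs = self._inputs()
        far = pd.DataFrame({"chrom": ["chr2"], "start": [0], "end": [10]})
        cand, summary = filter_candidates(variants, far, expressed, segments=segs)
        assert len(cand) == 0
        assert summary["percent_in_high_density"] == 0.0

    def test_filter_order_independence(self):
        """Quality, QTL, expression, and class filters commute."""
        variants, qtl, expressed, _ = self._inputs()
        hq, _ = filter_high_quality(variants)

        def in_qtl(v):
            return v[(v["pos"] > qtl.iloc[0]["start"]) & (v["pos"] <= qtl.iloc[0]["end"])]

        def expr(v):
            return v[v["gene"].isin(expressed)]

        def impact(v):
            return v[v["effect_class"].isin(
                {"high_impact", "deleterious_missense", "nonframeshift_deletion"})]

        results = []
        for order in itertools.permutations([in_qtl, expr, impact]):
            v = hq
            for f in order:
                v = f(v)
            results.append(set(v["pos"]))
        assert all(r == results[0] for r in results)


class TestIntervalHelpers:
    def test_merge_and_length(self):
        df = pd.DataFrame({"chrom": ["c", "c", "c"], "start": [0, 50, 200],
                           "end": [100, 150, 300]})
        assert total_length(df) == 250
        assert len(merge_intervals(df)) == 2

    def test_intersection(self):
        a = pd.DataFrame({"chrom": ["c"], "start": [0], "end": [100]})
        b = pd.DataFrame({"chrom": ["c"], "start": [50], "end": [200]})
        got = intersect_intervals(a, b)
        assert got.to_dict("records") == [{"chrom": "c", "start": 50, "end": 100}]

    def test_cm_to_bp_linear(self):
        phys = pd.DataFrame({"marker": ["a", "b"], "chrom": "1",
                             "cm": [0.0, 10.0], "bp": [0, 20_000_000]})
        pk = aq.QtlPeak("1", 5.0, 3.0, 2.5, 7.5)
        out = aq.qtl_cm_to_bp([pk], phys)
        assert out.iloc[0]["start"] == 5_000_000
        assert out.iloc[0]["end"] == 15_000_001
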