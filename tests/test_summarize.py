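"""Region summaries, exclusion filters, Fisher significance, profiles."""

import numpy as np
import pytest
from _oracles import fisher_tail_enumeration

from captor.baits import CaptureRegion
from captor.classify import ClassifiedRead
from captor.reads import ReadPair
from captor.summarize import (
    RegionIndelSummary,
    coverage_stats,
    fisher_significance,
    indel_profiles,
    significance_table,
    summarize_regions,
    tally_regions,
)
from conftest import random_seq


def reads(region, wt=0, snp=0, ins=0, dele=0, disc=0):
    out = []
    out += [ClassifiedRead(region, "WT") for _ in range(wt)]
    out += [ClassifiedRead(region, "SNP", n_mismatches=1) for _ in range(snp)]
    out += [ClassifiedRead(region, "insertion", 1, 0) for _ in range(ins)]
    out += [ClassifiedRead(region, "deletion", -2, 0) for _ in range(dele)]
    out += [ClassifiedRead(region, "discarded") for _ in range(disc)]
    return out


def region(rng, rid="r", seq=None):
    s = seq or random_seq(rng, 200)
    return CaptureRegion(rid, "chr1", 0, 200, s)


class TestSummaries:
    def test_indel_percentage_arithmetic(self, rng):
        summaries = summarize_regions(
            reads("r", wt=80, snp=5, ins=5, dele=10), {"r": region(rng)},
            homopolymer_len=1000,
        )
        s = summaries["r"]
        assert s.n_total == 100
        assert s.indel_pct == 15.0

    def test_counts_conserve_and_discarded_audited(self, rng):
        summaries = summarize_regions(
            reads("r", wt=30, snp=2, ins=1, dele=3, disc=7), {"r": region(rng)},
            min_reads=10, homopolymer_len=1000,
        )
        s = summaries["r"]
        assert s.n_wt + s.n_snp + s.n_ins + s.n_del == s.n_total == 36
        assert s.n_discarded == 7

    def test_low_coverage_flag_at_24_reads(self, rng):
        summaries = summarize_regions(
            reads("r", wt=24), {"r": region(rng)}, homopolymer_len=1000
        )
        assert "low_coverage" in summaries["r"].flags
        summaries = summarize_regions(
            reads("r", wt=25), {"r": region(rng)}, homopolymer_len=1000
        )
        assert "low_coverage" not in summaries["r"].flags

    def test_homopolymer_flag_default_five(self, rng):
        seq = "ACGT" * 25 + "AAAAA" + ("GTCA" * 24)[:95]  # exactly one 5-run
        summaries = summarize_regions(reads("r", wt=30), {"r": region(rng, seq=seq)})
        assert "homopolymer" in summaries["r"].flags
        # the stricter six-base variant leaves a 5-run unflagged
        summaries6 = summarize_regions(
            reads("r", wt=30), {"r": region(rng, seq=seq)}, homopolymer_len=6
        )
        assert "homopolymer" not in summaries6["r"].flags

    def test_high_background_flag_from_untreated(self, rng):
        untreated = summarize_regions(
            reads("r", wt=90, ins=10), {"r": region(rng)}, homopolymer_len=1000
        )
        treated = summarize_regions(
            reads("r", wt=100), {"r": region(rng)}, untreated=untreated,
            homopolymer_len=1000, background_pct=5.0,
        )
        assert "high_background" in treated["r"].flags

    def test_absent_region_empty_low_coverage(self, rng):
        summaries = summarize_regions([], {"r": region(rng)}, homopolymer_len=1000)
        assert summaries["r"].n_total == 0
        assert "low_coverage" in summaries["r"].flags


class TestFisher:
    def test_matches_tail_enumeration_oracle(self):
        t = RegionIndelSummary("r", n_wt=170, n_ins=30)
        c = RegionIndelSummary("r", n_wt=198, n_ins=2)
        res = fisher_significance(t, c)
        expected = fisher_tail_enumeration(30, 170, 2, 198)
        assert res.fisher_p == pytest.approx(expected, rel=1e-9)
        assert res.significant

    def test_identical_tables_not_significant(self):
        t = RegionIndelSummary("r", n_wt=95, n_del=5)
        res = fisher_significance(t, t)
        assert res.fisher_p >= 0.5
        assert not res.significant

    def test_flagged_regions_excluded(self):
        t = RegionIndelSummary("r", n_wt=10, n_del=30)
        t.flags.add("homopolymer")
        c = RegionIndelSummary("r", n_wt=200)
        res = fisher_significance(t, c)
        assert res.excluded and not res.significant

    def test_reverse_direction_mode(self):
        t = RegionIndelSummary("r", n_wt=198, n_ins=2)
        c = RegionIndelSummary("r", n_wt=170, n_ins=30)
        fwd = fisher_significance(t, c, direction="greater")
        rev = fisher_significance(t, c, direction="less")
        assert not fwd.significant
        assert rev.significant

    @pytest.mark.parametrize("correction", ["bonferroni", "bh"])
    def test_corrections_monotone_and_bounded(self, correction):
        treated = {
            f"r{i}": RegionIndelSummary(f"r{i}", n_wt=200 - i * 4, n_del=i * 4)
            for i in range(1, 8)
        }
        control = {f"r{i}": RegionIndelSummary(f"r{i}", n_wt=200) for i in range(1, 8)}
        raw = significance_table(treated, control)
        adj = significance_table(treated, control, correction=correction)
        assert (adj["fisher_p_adj"] >= adj["fisher_p"] - 1e-12).all()
        assert (adj["fisher_p_adj"] <= 1.0).all()
        assert adj["significant"].sum() <= raw["significant"].sum()


class TestProfiles:
    def test_single_size_single_bar(self):
        classified = [ClassifiedRead("r", "deletion", -1, 2) for _ in range(10)]
        sizes, offsets = indel_profiles(classified)
        assert len(sizes) == 1
        assert sizes.iloc[0].tolist() == ["r", -1, 10]

    def test_mixed_sizes_stay_in_signed_range(self, rng):
        classified = []
        for _ in range(100):
            k = int(rng.integers(1, 6))
            if rng.random() < 0.8:
                classified.append(ClassifiedRead("r", "deletion", -k, 0))
            else:
                classified.append(ClassifiedRead("r", "insertion", k, 0))
        sizes, _ = indel_profiles(classified)
        assert set(sizes["net_indel_size"]) <= set(range(-5, 0)) | set(range(1, 6))
        assert 0 not in set(sizes["net_indel_size"])


class TestCoverage:
    def pairs(self, spec):
        out = []
        for rid, n in spec.items():
            for i in range(n):
                out.append(
                    ReadPair(f"{rid}_{i}", "A", "A", "I", "I", assigned_region=rid)
                )
        return out

    def test_uniform_on_target_reported_as_lower_bound(self):
        pairs = self.pairs({"t1": 150, "t2": 150})
        stats = coverage_stats(pairs, ["t1", "t2"], ["r1", "r2"])
        assert stats["mean_targeted"] == 150
        assert stats["mean_random"] == 0
        assert stats["enrichment_is_lower_bound"]
        assert stats["fold_enrichment"] == 150

    def test_equal_density_everywhere_enrichment_one(self):
        pairs = self.pairs({"t1": 10, "r1": 10})
        stats = coverage_stats(pairs, ["t1"], ["r1"])
        assert stats["fold_enrichment"] == 1.0
        assert not stats["enrichment_is_lower_bound"]

    def test_analytic_ratio_for_ontarget_fraction(self):
        # 90% of 1000 pairs on 3 targets, 10% spread over 20 random regions
        spec = {f"t{i}": 300 for i in range(3)}
        spec.update({f"r{i}": 5 for i in range(20)})
        pairs = self.pairs(spec)
        stats = coverage_stats(pairs, [f"t{i}" for i in range(3)], [f"r{i}" for i in range(20)])
        assert stats["fold_enrichment"] == pytest.approx(300 / 5)
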