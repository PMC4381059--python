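"""Read preprocessing, clonal removal, pair merging and region assignment."""

import numpy as np
import pytest

from captor._seq import revcomp
from captor.baits import make_capture_regions, pick_random_controls
from captor.io import make_bed
from captor.reads import (
    ReadPair,
    assign_to_regions,
    merge_pair,
    preprocess_reads,
    read_pairs_from_sam,
    remove_clonal,
)
from captor.simulate import SimConfig, SimTruth, make_genome, simulate_capture_reads
from conftest import random_seq


def pair(seq1, seq2, qual1=None, qual2=None, **kw):
    return ReadPair("p", seq1, seq2, qual1 or "I" * len(seq1), qual2 or "I" * len(seq2), **kw)


class TestPreprocess:
    def test_clean_reads_unchanged(self, rng):
        p = pair(random_seq(rng, 100), random_seq(rng, 100))
        (out,) = preprocess_reads([p])
        assert (out.seq1, out.seq2) == (p.seq1, p.seq2)

    def test_pair_discarded_when_mate_below_35(self, rng):
        p = pair(random_seq(rng, 34), random_seq(rng, 100))
        assert preprocess_reads([p]) == []

    def test_low_quality_tail_trimmed(self, rng):
        seq = random_seq(rng, 100)
        qual = "I" * 90 + "#" * 10
        p = pair(seq, random_seq(rng, 100), qual1=qual)
        (out,) = preprocess_reads([p])
        assert len(out.seq1) == 90
        assert out.seq1 == seq[:90]

    def test_n_bases_stripped(self, rng):
        seq = "NN" + random_seq(rng, 60) + "N"
        p = pair(seq, random_seq(rng, 60))
        (out,) = preprocess_reads([p])
        assert len(out.seq1) == 60
        assert "N" not in out.seq1

    def test_adapter_suffix_removed(self, rng):
        adapter = "AGATCGGAAGAGC"
        seq = random_seq(rng, 70) + adapter + random_seq(rng, 5)
        p = pair(seq, random_seq(rng, 80))
        (out,) = preprocess_reads([p], adapter=adapter)
        assert len(out.seq1) == 70


class TestRemoveClonal:
    def make(self, pid, s1, s2, orient="FR"):
        return ReadPair(pid, "ACGT", "ACGT", "IIII", "IIII",
                        map_chrom="c", map_start1=s1, map_start2=s2, orientation=orient)

    def test_identical_keys_collapse_to_first(self):
        pairs = [self.make(f"p{i}", 100, 250) for i in range(5)]
        kept = remove_clonal(pairs)
        assert [p.pair_id for p in kept] == ["p0"]

    def test_staggered_starts_all_retained(self):
        pairs = [self.make(f"p{i}", 100 + i, 250) for i in range(5)]
        assert len(remove_clonal(pairs)) == 5

    def test_orientation_distinguishes_keys(self):
        pairs = [self.make("a", 100, 250, "FR"), self.make("b", 100, 250, "RF")]
        assert len(remove_clonal(pairs)) == 2

    def test_idempotent(self):
        pairs = [self.make(f"p{i}", 100, 250) for i in range(3)]
        once = remove_clonal(pairs)
        assert remove_clonal(once) == once

    def test_unmapped_pairs_pass_through(self):
        pairs = [pair("ACGTACGT", "ACGTACGT") for _ in range(3)]
        assert len(remove_clonal(pairs)) == 3

    def test_simulated_clonal_rate_count_equals_distinct_keys(self):
        sim = SimConfig(genome_length=20_000, seed=21, clonal_rate=0.5, depth_per_region=200)
        genome = make_genome(sim)
        loci = pick_random_controls(genome, 3, seed=21)
        regions = make_capture_regions(loci, genome)
        truths = [SimTruth(r.region_id, 0.0) for r in regions]
        pairs, _ = simulate_capture_reads(genome, regions, truths, sim)
        distinct = {p.clonal_key() for p in pairs}
        assert len(remove_clonal(pairs)) == len(distinct)
        assert len(pairs) > len(distinct)  # duplicates were actually produced


class TestMergePair:
    def test_fragment_reconstruction_arithmetic(self, rng):
        frag = random_seq(rng, 150)
        r1, r2 = frag[:100], revcomp(frag)[:100]
        merged = merge_pair(r1, r2)
        assert merged == frag
        assert len(merged) == 100 + 100 - 50

    def test_disjoint_halves_not_merged(self, rng):
        frag = random_seq(rng, 300)
        r1, r2 = frag[:100], revcomp(frag)[:100]  # ends 100 bp apart
        assert merge_pair(r1, r2) is None

    def test_identical_reads_full_containment(self, rng):
        r1 = random_seq(rng, 100)
        merged = merge_pair(r1, revcomp(r1))
        assert merged == r1

    def test_overlap_below_minimum_rejected(self, rng):
        frag = random_seq(rng, 100)
        r1, r2 = frag[:52], revcomp(frag[48:])  # exact overlap of 4
        assert merge_pair(r1, r2, min_overlap=5) is None or len(merge_pair(r1, r2, min_overlap=5)) != 100


class TestAssignToRegions:
    def _regions(self, rng, n=5):
        genome = {"chr1": random_seq(rng, 50_000)}
        loci = pick_random_controls(genome, n, seed=31)
        return genome, make_capture_regions(loci, genome)

    def test_verbatim_read_assigned(self, rng):
        genome, regions = self._regions(rng)
        r = regions[2]
        p = pair(r.ref_seq[30:130], revcomp(r.ref_seq[80:180]))
        (out,) = assign_to_regions([p], regions)
        assert out.assigned_region == r.region_id
        assert out.unique

    def test_identical_regions_tie_unassigned(self, rng):
        from captor.baits import CaptureRegion

        seq = random_seq(rng, 200)
        regions = [
            CaptureRegion("dup1", "c", 0, 200, seq),
            CaptureRegion("dup2", "c", 1000, 1200, seq),
        ]
        p = pair(seq[20:120], revcomp(seq[80:180]))
        (out,) = assign_to_regions([p], regions)
        assert out.assigned_region is None
        assert out.unique is False

    def test_foreign_read_unassigned(self, rng):
        genome, regions = self._regions(rng)
        p = pair(random_seq(rng, 100), random_seq(rng, 100))
        (out,) = assign_to_regions([p], regions)
        assert out.assigned_region is None

    def test_simulated_reads_assigned_to_true_region(self, rng):
        sim = SimConfig(genome_length=50_000, seed=32, depth_per_region=100,
                        subst_error_rate=0.001, clonal_rate=0.0)
        genome = make_genome(sim)
        loci = pick_random_controls(genome, 10, seed=32)
        regions = make_capture_regions(loci, genome)
        truths = [SimTruth(r.region_id, 0.0) for r in regions]
        pairs, truth_df = simulate_capture_reads(genome, regions, truths, sim)
        assigned = assign_to_regions(pairs, regions)
        truth_map = dict(zip(truth_df["pair_id"], truth_df["region_id"]))
        bounds = {r.region_id: (r.start, r.end) for r in regions}
        # condition on fragments that actually share a placeable (>=20 bp)
        # stretch with their region; barely-touching fragments carry no signal
        eligible = correct = 0
        for p in assigned:
            rs, re = bounds[truth_map[p.pair_id]]
            if min(p.map_start2, re) - max(p.map_start1, rs) >= 20:
                eligible += 1
                correct += p.assigned_region == truth_map[p.pair_id]
        assert eligible > 800
        assert correct / eligible >= 0.99


class TestSamInput:
    def test_round_trip_through_sam(self, tmp_path, rng):
        import pysam

        header = {"HD": {"VN": "1.6"}, "SQ": [{"LN": 10_000, "SN": "chr1"}]}
        path = tmp_path / "pairs.sam"
        seq1, seq2 = random_seq(rng, 50), random_seq(rng, 50)
        with pysam.AlignmentFile(path, "w", header=header) as out:
            a = pysam.AlignedSegment()
            a.query_name = "p1"
            a.query_sequence = seq1
            a.flag = 0x1 | 0x40  # paired, first in pair
            a.reference_id = 0
            a.reference_start = 100
            a.cigarstring = "50M"
            a.query_qualities = pysam.qualitystring_to_array("I" * 50)
            b = pysam.AlignedSegment()
            b.query_name = "p1"
            b.query_sequence = revcomp(seq2)
            b.flag = 0x1 | 0x80 | 0x10  # paired, second, reverse
            b.reference_id = 0
            b.reference_start = 200
            b.cigarstring = "50M"
            b.query_qualities = pysam.qualitystring_to_array("I" * 50)
            out.write(a)
            out.write(b)
        (p,) = read_pairs_from_sam(path)
        assert p.pair_id == "p1"
        assert p.seq1 == seq1
        assert p.seq2 == seq2  # restored to original read orientation
        assert (p.map_start1, p.map_start2, p.orientation) == (100, 200, "FR")
        assert p.clonal_key() == ("chr1", 100, 200, "FR")
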