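"""Synthetic-data generator: composition, determinism, truth round trips."""

import numpy as np
import pytest

from captor.baits import make_capture_regions, pick_random_controls
from captor.io import make_bed
from captor.peaks import intersect_replicates, split_grna_specific
from captor.simulate import (
    PlantSpec,
    SimConfig,
    SimTruth,
    make_genome,
    pairs_to_fastq,
    plant_sites,
    simulate_capture_reads,
    simulate_peak_sets,
)


class TestSimConfig:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"gc_content": 1.5},
            {"clonal_rate": -0.1},
            {"genome_length": 500},
            {"read_length": 30},
            {"indel_size_range": (0, 5)},
        ],
    )
    def test_invalid_config_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SimConfig(**kwargs)


class TestMakeGenome:
    def test_zero_gc_gives_only_at(self):
        genome = make_genome(SimConfig(genome_length=3000, gc_content=0.0, seed=1))
        assert set(genome["chr1"]) <= {"A", "T"}

    def test_gc_fraction_within_binomial_error(self):
        genome = make_genome(SimConfig(genome_length=1_000_000, gc_content=0.42, seed=2))
        seq = genome["chr1"]
        gc = (seq.count("G") + seq.count("C")) / len(seq)
        assert abs(gc - 0.42) < 0.005  # ~10 binomial SEs at n=1e6

    def test_same_seed_identical(self):
        cfg = SimConfig(genome_length=5000, seed=3)
        assert make_genome(cfg) == make_genome(cfg)


class TestPlantSites:
    def test_mismatch_position_out_of_range(self, s1):
        genome = make_genome(SimConfig(genome_length=5000, seed=4))
        with pytest.raises(ValueError):
            plant_sites(genome, [PlantSpec(s1, 100, "+", (21,), "AGG")])

    def test_overlapping_plants_rejected(self, s1, s2):
        genome = make_genome(SimConfig(genome_length=5000, seed=4))
        with pytest.raises(ValueError):
            plant_sites(genome, [PlantSpec(s1, 100), PlantSpec(s2, 110)])


def _tiny_screen_inputs(seed, n_regions=3, **sim_kwargs):
    sim = SimConfig(genome_length=20_000, seed=seed, depth_per_region=60, **sim_kwargs)
    genome = make_genome(sim)
    loci = pick_random_controls(genome, n_regions, length=200, seed=seed)
    regions = make_capture_regions(loci, genome)
    return sim, genome, regions


class TestSimulateCaptureReads:
    def test_null_simulation_classifies_all_wt(self):
        from captor.classify import classify_pairs
        from captor.reads import assign_to_regions

        sim, genome, regions = _tiny_screen_inputs(
            5, subst_error_rate=0.0, clonal_rate=0.0
        )
        truths = [SimTruth(r.region_id, 0.0) for r in regions]
        pairs, _ = simulate_capture_reads(genome, regions, truths, sim)
        assigned = assign_to_regions(pairs, regions)
        classified = classify_pairs(assigned, regions)
        labels = {c.label for c in classified}
        assert labels <= {"WT", "discarded"}
        assert sum(c.label == "WT" for c in classified) > 0

    def test_region_outside_genome_rejected(self):
        from captor.baits import CaptureRegion

        sim = SimConfig(genome_length=5000, seed=6)
        genome = make_genome(sim)
        bad = CaptureRegion("r", "chr1", 4900, 5100, "A" * 200)
        with pytest.raises(ValueError):
            simulate_capture_reads(genome, [bad], [SimTruth("r", 0.0)], sim)

    def test_truth_must_cover_every_region(self):
        sim, genome, regions = _tiny_screen_inputs(7)
        with pytest.raises(ValueError):
            simulate_capture_reads(genome, regions, [], sim)

    def test_per_pair_truth_matches_mapping_keys(self):
        sim, genome, regions = _tiny_screen_inputs(8)
        truths = [SimTruth(r.region_id, 0.2) for r in regions]
        pairs, truth_df = simulate_capture_reads(genome, regions, truths, sim)
        assert len(pairs) == len(truth_df)
        for p, row in zip(pairs, truth_df.itertuples()):
            assert p.pair_id == row.pair_id
            assert (p.map_start1, p.map_start2) == (row.start1, row.start2)

    def test_clonal_duplicates_share_keys_with_originals(self):
        sim, genome, regions = _tiny_screen_inputs(9, clonal_rate=0.5)
        truths = [SimTruth(r.region_id, 0.0) for r in regions]
        pairs, truth_df = simulate_capture_reads(genome, regions, truths, sim)
        dups = truth_df[truth_df.clone_of != ""]
        assert len(dups) > 0
        originals = truth_df.set_index("pair_id")
        for row in dups.itertuples():
            parent = originals.loc[row.clone_of]
            assert (row.start1, row.start2) == (parent.start1, parent.start2)

    def test_byte_identical_fastq_for_same_config(self):
        outs = []
        for _ in range(2):
            sim, genome, regions = _tiny_screen_inputs(10, clonal_rate=0.3)
            truths = [SimTruth(r.region_id, 0.1) for r in regions]
            pairs, _ = simulate_capture_reads(genome, regions, truths, sim)
            r1, r2 = pairs_to_fastq(pairs)
            outs.append((tuple(r1), tuple(r2)))
        assert outs[0] == outs[1]

    def test_indel_frequency_recovered_within_binomial_error(self):
        from captor.classify import classify_pairs
        from captor.reads import assign_to_regions, preprocess_reads, remove_clonal
        from captor.screen import raw_depth_for_coverage
        from captor.summarize import summarize_regions

        sim = SimConfig(genome_length=20_000, seed=11, clonal_rate=0.0)
        depth = raw_depth_for_coverage(500, sim)
        sim = SimConfig(genome_length=20_000, seed=11, clonal_rate=0.0, depth_per_region=depth)
        genome = make_genome(sim)
        loci = pick_random_controls(genome, 2, length=200, seed=11)
        regions = make_capture_regions(loci, genome)
        truths = [SimTruth(regions[0].region_id, 0.15), SimTruth(regions[1].region_id, 0.0)]
        pairs, _ = simulate_capture_reads(genome, regions, truths, sim)
        assigned = assign_to_regions(remove_clonal(preprocess_reads(pairs)), regions)
        summaries = summarize_regions(
            classify_pairs(assigned, regions), {r.region_id: r for r in regions},
            homopolymer_len=100,
        )
        s = summaries[regions[0].region_id]
        se = np.sqrt(0.15 * 0.85 / s.n_total)
        assert abs(s.indel_pct / 100 - 0.15) < 3 * se


class TestSimulatePeakSets:
    def test_planted_shared_count_recovered(self):
        genome = make_genome(SimConfig(genome_length=120_000, seed=12))
        bed_a, bed_b = simulate_peak_sets(genome, 60, 80, 30, seed=12)
        common, a_spec, b_spec = split_grna_specific(bed_a, bed_b)
        assert (len(common), len(a_spec), len(b_spec)) == (30, 30, 50)

    def test_zero_overlap(self):
        genome = make_genome(SimConfig(genome_length=60_000, seed=13))
        bed_a, bed_b = simulate_peak_sets(genome, 20, 20, 0, seed=13)
        common, _, _ = split_grna_specific(bed_a, bed_b)
        assert len(common) == 0

    def test_identical_sets_intersection_idempotent(self):
        genome = make_genome(SimConfig(genome_length=60_000, seed=14))
        bed_a, _ = simulate_peak_sets(genome, 25, 25, 0, seed=14)
        out = intersect_replicates(bed_a, bed_a)
        assert len(out) == len(bed_a)

    def test_shared_exceeding_set_size_rejected(self):
        genome = make_genome(SimConfig(genome_length=60_000, seed=15))
        with pytest.raises(ValueError):
            simulate_peak_sets(genome, 5, 10, 6, seed=15)
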