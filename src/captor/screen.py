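"""End-to-end screen orchestration: scan -> peaks -> baits -> capture.

Two entry points:

* :func:`run_screen` consumes a :class:`~captor.config.RunConfig` pointing at
  files (genome FASTA, site/peak BEDs, paired FASTQ with mapping coordinates)
  and writes a report bundle of TSV tables plus a JSON provenance block.
* :func:`synthetic_screen` runs the capture stage entirely in memory on
  simulated inputs with known truth — the harness for calibration and
  power/recovery studies.
"""

from __future__ import annotations

import hashlib
import json
import sys
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

import captor
from captor import io
from captor.baits import CaptureRegion, bait_fasta, bait_manifest, make_capture_regions, pick_random_controls
from captor.classify import classify_pairs
from captor.config import RunConfig, validate_config
from captor.peaks import density_summary_table, overlap_fraction, pam_density, split_grna_specific
from captor.reads import assign_to_regions, preprocess_reads, read_pairs_from_fastq, remove_clonal
from captor.scan import TargetSite, hits_to_bed, scan_genome
from captor.simulate import (
    PlantSpec,
    SimConfig,
    SimTruth,
    cut_offset_for_site,
    make_genome,
    pairs_to_fastq,
    plant_sites,
    simulate_capture_reads,
)
from captor.summarize import (
    coverage_stats,
    indel_profiles,
    significance_table,
    summarize_regions,
    summary_table,
)

S1 = TargetSite("S1", "GCTCCCTACGCATGCGTCCC")
S2 = TargetSite("S2", "AATGGCTCAGGTTTGTCGCG")


class ScreenStageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        super().__init__(f"stage {stage!r} failed: {cause}")


def _log(stage: str, msg: str) -> None:
    print(f"[{stage}] {msg}", file=sys.stderr)


def _provenance(cfg: RunConfig) -> dict:
    blob = json.dumps(cfg.to_dict(), sort_keys=True, default=str)
    return {
        "config_sha256": hashlib.sha256(blob.encode()).hexdigest(),
        "captor_version": captor.__version__,
        "seed": cfg.seed,
    }


def _capture_sample(cfg: RunConfig, r1, r2, coords_path, regions) -> tuple[list, list]:
    """FASTQ (+ mapping coords TSV) -> assigned pairs and classified reads."""
    coords = pd.read_csv(coords_path, sep="\t") if coords_path else None
    pairs = read_pairs_from_fastq(r1, r2, truth=coords)
    if not pairs:
        raise ValueError("no read pairs in input FASTQ")
    pairs = preprocess_reads(pairs, min_len=cfg.min_len, qual_threshold=cfg.qual_threshold)
    pairs = remove_clonal(pairs)
    pairs = assign_to_regions(pairs, regions)
    classified = classify_pairs(
        pairs, regions, min_anchor=cfg.min_anchor, min_span=cfg.min_span
    )
    return pairs, classified


def run_screen(cfg: RunConfig | dict) -> dict:
    """Execute every configured stage in order; return the report bundle.

    Any stage failure aborts with the stage name and cause; outputs of prior
    stages remain on disk.
    """
    cfg = validate_config(cfg)
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"provenance": _provenance(cfg)}

    genome = None
    if cfg.genome:
        genome = io.read_fasta(cfg.genome)

    # --- scan -------------------------------------------------------------
    if cfg.targets:
        try:
            if genome is None:
                raise ValueError("scan stage requires a genome")
            scan_counts = {}
            for name, proto in cfg.targets.items():
                target = TargetSite(name, proto)
                hits = scan_genome(genome, target, cfg.max_mm, (cfg.pam,))
                bed = hits_to_bed(hits)
                io.write_bed(bed, out / f"hits_{name}.bed",
                             extra_cols=["matched_seq", "pam", "mismatch_positions"])
                scan_counts[name] = len(hits)
            report["scan_hits"] = scan_counts
            _log("scan", f"hit counts: {scan_counts}")
        except Exception as e:  # noqa: BLE001 - stage boundary
            raise ScreenStageError("scan", e) from e

    # --- peaks ------------------------------------------------------------
    if cfg.peak_files:
        try:
            beds = {label: io.read_bed(p) for label, p in cfg.peak_files.items()}
            labels = list(beds)
            if len(labels) >= 2:
                common, a_spec, b_spec = split_grna_specific(beds[labels[0]], beds[labels[1]])
                report["peaks_common"] = len(common)
                io.write_bed(common, out / "peaks_common.bed")
            if genome is not None:
                results = [
                    pam_density(bed, genome, set_label=label) for label, bed in beds.items()
                ]
                table = density_summary_table(results)
                table.to_csv(out / "pam_density.tsv", sep="\t", index=False)
                report["pam_density"] = table.to_dict("records")
            for flabel, fpath in cfg.feature_files.items():
                features = io.read_bed(fpath)
                for label, bed in beds.items():
                    pct, _ = overlap_fraction(bed, features)
                    report[f"overlap_{label}_{flabel}_pct"] = pct
            _log("peaks", f"processed {len(beds)} peak sets")
        except Exception as e:  # noqa: BLE001
            raise ScreenStageError("peaks", e) from e

    # --- baits ------------------------------------------------------------
    regions: list[CaptureRegion] = []
    if cfg.sites:
        try:
            if genome is None:
                raise ValueError("bait stage requires a genome")
            sites = io.read_bed(cfg.sites)
            regions = make_capture_regions(sites, genome)
            if cfg.n_random_controls:
                controls = pick_random_controls(
                    genome, cfg.n_random_controls, exclusions=sites, seed=cfg.seed
                )
                regions += make_capture_regions(controls, genome, category="random_control")
            manifest = bait_manifest(regions)
            manifest.to_csv(out / "bait_manifest.tsv", sep="\t", index=False)
            io.write_fasta(bait_fasta(regions), out / "baits.fa")
            report["n_capture_regions"] = len(regions)
            _log("baits", f"designed {3 * len(regions)} baits over {len(regions)} regions")
        except Exception as e:  # noqa: BLE001
            raise ScreenStageError("baits", e) from e

    # --- capture ----------------------------------------------------------
    if cfg.treated_r1:
        try:
            if not regions:
                raise ValueError("capture stage requires capture regions (sites BED)")
            region_map = {r.region_id: r for r in regions}
            t_pairs, t_class = _capture_sample(
                cfg, cfg.treated_r1, cfg.treated_r2, cfg.treated_coords, regions
            )
            c_summaries = None
            sig = None
            if cfg.control_r1:
                _, c_class = _capture_sample(
                    cfg, cfg.control_r1, cfg.control_r2, cfg.control_coords, regions
                )
                c_summaries = summarize_regions(
                    c_class, region_map, min_reads=cfg.min_reads,
                    homopolymer_len=cfg.homopolymer_len,
                )
            t_summaries = summarize_regions(
                t_class, region_map, untreated=c_summaries,
                min_reads=cfg.min_reads, homopolymer_len=cfg.homopolymer_len,
                background_pct=cfg.background_pct,
            )
            categories = {r.region_id: r.category for r in regions}
            summary_table(t_summaries, categories).to_csv(
                out / "region_summary.tsv", sep="\t", index=False
            )
            if c_summaries is not None:
                sig = significance_table(
                    t_summaries, c_summaries, alpha=cfg.alpha,
                    direction=cfg.direction, correction=cfg.correction,
                )
                sig.to_csv(out / "significance.tsv", sep="\t", index=False)
                report["significant_regions"] = sorted(
                    sig.loc[sig["significant"], "region_id"]
                )
            sizes, offsets = indel_profiles(t_class)
            sizes.to_csv(out / "indel_sizes.tsv", sep="\t", index=False)
            offsets.to_csv(out / "indel_offsets.tsv", sep="\t", index=False)
            targeted = [r.region_id for r in regions if r.category != "random_control"]
            randoms = [r.region_id for r in regions if r.category == "random_control"]
            if targeted and randoms:
                report["coverage"] = coverage_stats(t_pairs, targeted, randoms)
            _log("capture", f"classified {len(t_class)} reads over {len(regions)} regions")
        except ScreenStageError:
            raise
        except Exception as e:  # noqa: BLE001
            raise ScreenStageError("capture", e) from e

    (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True, default=str))
    return report


# ---------------------------------------------------------------------------
# Synthetic end-to-end harness


@dataclass
class SyntheticScreen:
    """In-memory synthetic screen: regions, truth, reads, tables."""

    regions: list
    truths: list
    treated_pairs: list  # post-dedup, assigned
    raw_treated_pairs: list
    treated_truth: pd.DataFrame
    control_pairs: list  # raw
    treated_summaries: dict
    control_summaries: dict
    significance: pd.DataFrame
    classified: list


def raw_depth_for_coverage(classified_target: int, sim: SimConfig,
                           region_len: int = 200) -> int:
    """Raw read pairs per region needed for a target classifiable coverage.

    With fragment starts uniform over [region_start - fragment_length,
    region_end), a fragment of length f yields a classifiable read (reference
    span >= 100 bp) only when it overlaps the region by >= 100 bp — a
    (f + 1) / (region_len + f) fraction of start positions — and pair merging
    requires the ~2*(2*read_len - f) overlap-copy bases to be error free.
    The unmerged-mate salvage path is ignored, so the estimate is slightly
    conservative.  "Depth" statements about the screen refer to classifiable
    coverage; this converts them to the raw pair count the simulator draws.
    """
    f = sim.fragment_length_mean
    geometric = (f + 1.0) / (region_len + f)
    overlap_bases = max(0.0, 2 * (2 * sim.read_length - f))
    merge_ok = (1.0 - sim.subst_error_rate) ** overlap_bases
    return int(np.ceil(classified_target / (geometric * merge_ok)))


def pick_clean_loci(genome, n: int, homopolymer_len: int, rng) -> pd.DataFrame:
    """Random non-overlapping 200-bp loci free of homopolymer runs.

    The screened target set mirrors a capture design after its homopolymer
    exclusion: candidate loci whose sequence carries a run of
    ``homopolymer_len`` identical bases are rejected and redrawn.
    """
    from captor._seq import max_homopolymer_run

    chrom = next(iter(genome))
    seq = genome[chrom]
    picked = pick_random_controls(genome, 4 * n, length=200, seed=rng)
    clean = [
        row
        for row in picked.itertuples(index=False)
        if max_homopolymer_run(seq[row.start : row.end]) < homopolymer_len
    ]
    if len(clean) < n:
        raise ValueError("could not find enough homopolymer-free loci")
    return pd.DataFrame(clean[:n]).reset_index(drop=True)


def synthetic_screen(
    n_regions: int = 20,
    freqs: dict[int, float] | None = None,
    seed: int = 0,
    sim_config: SimConfig | None = None,
    run_config: RunConfig | None = None,
    plant_targets: bool = True,
) -> SyntheticScreen:
    """Simulate a capture screen and push it through the full pipeline.

    ``freqs`` maps region index -> true indel frequency (missing = 0).  When
    ``plant_targets`` is set, the S1 site (plus strand) is planted at region
    0's center and the S2 site (minus strand) at region 1's, so those regions
    carry a genuine protospacer+PAM and cut offsets follow Cas9 geometry;
    other signal regions use a centered cut.  Loci are drawn free of
    homopolymer runs, emulating a capture design after homopolymer exclusion.
    """
    cfg = run_config or RunConfig()
    # genome sized so that homopolymer-free locus rejection sampling has room
    sim = sim_config or SimConfig(seed=seed, genome_length=max(120_000, 2000 * n_regions))
    freqs = freqs or {}

    genome = make_genome(sim)
    chrom = next(iter(genome))
    loci = pick_clean_loci(
        genome, n_regions, cfg.homopolymer_len, np.random.default_rng([sim.seed, 3])
    )
    loci["name"] = [f"region_{i:04d}" for i in range(n_regions)]

    cut_offsets = {i: 0 for i in range(n_regions)}
    strands = {}
    if plant_targets and n_regions >= 2:
        specs = []
        for i, (target, pam, strand) in enumerate([(S1, "AGG", "+"), (S2, "CGG", "-")]):
            center = (int(loci.at[i, "start"]) + int(loci.at[i, "end"])) // 2
            specs.append(PlantSpec(target, center - 11, strand=strand, pam=pam))
            cut_offsets[i] = cut_offset_for_site(strand)
            strands[i] = strand
        genome, _ = plant_sites(genome, specs, chrom)

    regions = make_capture_regions(loci, genome)
    for i, r in enumerate(regions):
        if i == 0:
            r.category = "chip_S1"
        elif i == 1:
            r.category = "chip_S2"
    truths = [
        SimTruth(
            r.region_id,
            freqs.get(i, 0.0),
            cut_offset=cut_offsets[i],
            pam_strand=strands.get(i, "+"),
        )
        for i, r in enumerate(regions)
    ]
    null_truths = [SimTruth(r.region_id, 0.0) for r in regions]

    treated_pairs, treated_truth = simulate_capture_reads(genome, regions, truths, sim)
    control_sim = SimConfig(**{**sim.__dict__, "seed": sim.seed + 10_007})
    control_pairs, _ = simulate_capture_reads(genome, regions, null_truths, control_sim)

    region_map = {r.region_id: r for r in regions}

    def _run(pairs):
        pairs = preprocess_reads(pairs, min_len=cfg.min_len, qual_threshold=cfg.qual_threshold)
        pairs = remove_clonal(pairs)
        pairs = assign_to_regions(pairs, regions)
        return pairs, classify_pairs(pairs, regions, min_anchor=cfg.min_anchor, min_span=cfg.min_span)

    _, c_class = _run(control_pairs)
    c_summaries = summarize_regions(
        c_class, region_map, min_reads=cfg.min_reads, homopolymer_len=cfg.homopolymer_len
    )
    t_assigned, t_class = _run(treated_pairs)
    t_summaries = summarize_regions(
        t_class, region_map, untreated=c_summaries,
        min_reads=cfg.min_reads, homopolymer_len=cfg.homopolymer_len,
        background_pct=cfg.background_pct,
    )
    sig = significance_table(t_summaries, c_summaries, alpha=cfg.alpha, direction=cfg.direction)
    return SyntheticScreen(
        regions, truths, t_assigned, treated_pairs, treated_truth, control_pairs,
        t_summaries, c_summaries, sig, t_class,
    )


def write_synthetic_inputs(out_dir, screen_cfg: SimConfig, n_regions: int,
                           freqs: dict[int, float], seed: int = 0) -> RunConfig:
    """Materialise a synthetic screen's inputs as files and return a RunConfig.

    Written: genome.fa, sites.bed, peaks_{S1,S2}.bed fixtures, paired FASTQ
    and mapping-coordinate TSVs for treated and control samples.
    """
    from captor.simulate import simulate_peak_sets

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sim = SimConfig(**{**screen_cfg.__dict__, "seed": seed})
    scr = synthetic_screen(n_regions=n_regions, freqs=freqs, seed=seed, sim_config=sim)

    genome = make_genome(sim)
    chrom = next(iter(genome))
    # regenerate the planted genome from the screen's regions (ref sequences)
    seq = list(genome[chrom])
    for r in scr.regions:
        seq[r.start : r.end] = list(r.ref_seq)
    genome[chrom] = "".join(seq)
    io.write_fasta(genome, out / "genome.fa")

    sites = io.make_bed(
        [(r.chrom, r.start, r.end) for r in scr.regions],
        names=[r.region_id for r in scr.regions],
    )
    io.write_bed(sites, out / "sites.bed")

    bed_a, bed_b = simulate_peak_sets(genome, 20, 25, 10, length=100, seed=seed)
    io.write_bed(bed_a, out / "peaks_S1.bed")
    io.write_bed(bed_b, out / "peaks_S2.bed")

    for label, pairs in [
        ("treated", scr.raw_treated_pairs),
        ("control", scr.control_pairs),
    ]:
        r1, r2 = pairs_to_fastq(pairs)
        io.write_fastq(r1, out / f"{label}_R1.fastq")
        io.write_fastq(r2, out / f"{label}_R2.fastq")
        coords = pd.DataFrame(
            {
                "pair_id": [p.pair_id for p in pairs],
                "chrom": [p.map_chrom for p in pairs],
                "start1": [p.map_start1 for p in pairs],
                "start2": [p.map_start2 for p in pairs],
                "orientation": [p.orientation for p in pairs],
            }
        )
        coords.to_csv(out / f"{label}_coords.tsv", sep="\t", index=False)

    return RunConfig(
        genome=str(out / "genome.fa"),
        targets={"S1": S1.protospacer, "S2": S2.protospacer},
        sites=str(out / "sites.bed"),
        peak_files={"S1": str(out / "peaks_S1.bed"), "S2": str(out / "peaks_S2.bed")},
        treated_r1=str(out / "treated_R1.fastq"),
        treated_r2=str(out / "treated_R2.fastq"),
        treated_coords=str(out / "treated_coords.tsv"),
        control_r1=str(out / "control_R1.fastq"),
        control_r2=str(out / "control_R2.fastq"),
        control_coords=str(out / "control_coords.tsv"),
        out_dir=str(out / "report"),
        seed=seed,
    )
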