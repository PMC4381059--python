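"""Synthetic inputs for the capture screen: genome, planted sites, reads, peaks.

The generator emulates the library structure of a capture experiment:
genomic DNA randomly sheared to ~150-bp fragments, paired-end sequenced at
a configurable read length, with a region-specific fraction of fragments
carrying one NHEJ-style indel (1-5 bp, deletions predominating 4:1) whose
left edge sits at the Cas9 cut site — 3 bp upstream of the PAM on the
PAM-bearing strand.  Substitution sequencing errors and PCR-clonal duplicate
pairs are layered on top.  Every random draw flows from the single integer
seed in :class:`SimConfig`, so identical configs produce byte-identical
FASTQ output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from captor._seq import revcomp
from captor.baits import CaptureRegion, REGION_LEN
from captor.io import BED_COLUMNS
from captor.reads import ReadPair
from captor.scan import PAM_LEN, PROTOSPACER_LEN, TargetSite

BASES = np.array(list("ACGT"))
#: Cas9 introduces its blunt double-strand break 3 bp upstream (5') of the PAM.
CUT_UPSTREAM_OF_PAM = 3


@dataclass
class SimConfig:
    """Study conditions for the synthetic capture experiment."""

    genome_length: int = 120_000
    gc_content: float = 0.42  # mouse-like genomic GC
    seed: int = 0
    fragment_length_mean: float = 150.0  # sheared library insert size
    fragment_length_sd: float = 15.0
    read_length: int = 100
    depth_per_region: int = 300  # read pairs per capture region
    clonal_rate: float = 0.1  # fraction of pairs duplicated by PCR
    subst_error_rate: float = 0.001  # per-base substitution error
    indel_size_range: tuple[int, int] = (1, 5)
    deletion_fraction: float = 0.8  # deletions:insertions = 4:1
    lowq_tail: int = 0  # bases of phred-2 tail appended for trimming tests

    def __post_init__(self):
        for name in ("gc_content", "clonal_rate", "subst_error_rate", "deletion_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.genome_length < 10 * REGION_LEN:
            raise ValueError("genome_length must be at least 10x the region length")
        if self.read_length < 35:
            raise ValueError("read_length must be >= 35")
        lo, hi = self.indel_size_range
        if not (1 <= lo <= hi):
            raise ValueError(f"invalid indel_size_range {self.indel_size_range}")


@dataclass
class SimTruth:
    """Ground truth for one capture region."""

    region_id: str
    true_indel_freq: float
    cut_offset: int = -3  # signed bases relative to the region center
    pam_strand: str = "+"

    def __post_init__(self):
        if not 0.0 <= self.true_indel_freq <= 1.0:
            raise ValueError("true_indel_freq must be in [0, 1]")


def make_genome(config: SimConfig, chrom: str = "chr1") -> dict[str, str]:
    """I.i.d. random genome with G and C frequencies gc_content/2 each."""
    rng = np.random.default_rng([config.seed, 0])
    gc = config.gc_content
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    seq = "".join(BASES[rng.choice(4, size=config.genome_length, p=p)])
    return {chrom: seq}


_SUBST = {"A": "C", "C": "G", "G": "T", "T": "A"}


@dataclass
class PlantSpec:
    """A site to write into the genome: target variant + PAM at a locus."""

    target: TargetSite
    position: int  # plus-strand start of the 23-mer written
    strand: str = "+"
    mismatch_positions: tuple[int, ...] = ()
    pam: str = "AGG"


def _mutated_protospacer(target: TargetSite, positions: tuple[int, ...]) -> str:
    proto = list(target.protospacer)
    for pos in positions:
        if not 1 <= pos <= PROTOSPACER_LEN:
            raise ValueError(f"mismatch position {pos} outside 1-{PROTOSPACER_LEN}")
        proto[pos - 1] = _SUBST[proto[pos - 1]]
    return "".join(proto)


def plant_sites(
    genome: dict[str, str], specs: list[PlantSpec], chrom: str | None = None
) -> tuple[dict[str, str], pd.DataFrame]:
    """Write each 23-mer (protospacer+PAM, possibly mismatched) into the genome.

    Planted sites must not overlap each other.  Returns the modified genome
    and a truth BED whose coordinates cover the 20-nt protospacer in scanner
    convention (on the minus strand the written 23-mer is the reverse
    complement, so the protospacer occupies the last 20 plus-strand bases).
    """
    if chrom is None:
        chrom = next(iter(genome))
    seq = genome[chrom]
    site_len = PROTOSPACER_LEN + PAM_LEN
    intervals = sorted((s.position, s.position + site_len) for s in specs)
    for (a0, a1), (b0, b1) in zip(intervals, intervals[1:]):
        if b0 < a1:
            raise ValueError("planted sites overlap")
    rows = []
    for spec in specs:
        proto = _mutated_protospacer(spec.target, spec.mismatch_positions)
        word = proto + spec.pam
        p = spec.position
        if p < 0 or p + site_len > len(seq):
            raise ValueError(f"planted site at {p} outside genome")
        if spec.strand == "-":
            word = revcomp(word)
            proto_start = p + PAM_LEN
        else:
            proto_start = p
        seq = seq[:p] + word + seq[p + site_len :]
        rows.append(
            (
                chrom,
                proto_start,
                proto_start + PROTOSPACER_LEN,
                f"{spec.target.name}_{len(spec.mismatch_positions)}mm",
                len(spec.mismatch_positions),
                spec.strand,
            )
        )
    out = dict(genome)
    out[chrom] = seq
    return out, pd.DataFrame(rows, columns=BED_COLUMNS)


def cut_offset_for_site(site_strand: str = "+") -> int:
    """Cut offset relative to a capture region centered on the 23-mer midpoint.

    For a plus-strand 23-mer at [0, 23) the cut falls at coordinate 17
    (3 bp 5' of the PAM at [20, 23)); for a minus-strand site the PAM sits at
    [0, 3) on the plus strand and the cut at coordinate 6.  Offsets are
    relative to the floor midpoint (11) of the 23-mer.
    """
    mid = (PROTOSPACER_LEN + PAM_LEN) // 2
    if site_strand == "+":
        return PROTOSPACER_LEN - CUT_UPSTREAM_OF_PAM - mid
    return PAM_LEN + CUT_UPSTREAM_OF_PAM - mid


def _apply_errors(read: np.ndarray, rng: np.random.Generator, rate: float) -> np.ndarray:
    if rate <= 0 or read.size == 0:
        return read
    hits = np.flatnonzero(rng.random(read.size) < rate)
    for i in hits:
        choices = [b for b in "ACGT" if b != read[i]]
        read[i] = choices[int(rng.integers(3))]
    return read


def simulate_capture_reads(
    genome: dict[str, str],
    regions: list[CaptureRegion],
    truth: list[SimTruth],
    config: SimConfig,
) -> tuple[list[ReadPair], pd.DataFrame]:
    """Simulate captured paired-end reads with known per-read indel truth.

    Fragment starts are uniform over [region_start - fragment_length,
    region_end) so read pairs are staggered like a randomly sheared library.
    A fraction ``true_indel_freq`` of fragments derives from mutant
    molecules; the indel (left edge at the cut site) appears on the fragment
    only when the fragment interior spans the cut, as in a real library.

    Returns the read pairs and a per-pair truth table (mapping coordinates,
    applied indel size, clonal provenance).
    """
    rng = np.random.default_rng([config.seed, 1])
    truth_by_region = {t.region_id: t for t in truth}
    missing = [r.region_id for r in regions if r.region_id not in truth_by_region]
    if missing:
        raise ValueError(f"truth missing for regions: {missing[:5]}")

    pairs: list[ReadPair] = []
    rows = []
    lo_size, hi_size = config.indel_size_range
    for region in regions:
        seq = genome[region.chrom]
        if region.start < 0 or region.end > len(seq):
            raise ValueError(f"region {region.region_id} outside genome")
        t = truth_by_region[region.region_id]
        cut_abs = region.center + t.cut_offset
        for _ in range(config.depth_per_region):
            flen = int(round(rng.normal(config.fragment_length_mean, config.fragment_length_sd)))
            flen = max(flen, config.read_length)  # floor at one read
            s = int(rng.integers(region.start - flen, region.end))
            s = max(s, 0)
            end = min(s + flen, len(seq))
            is_mutant = bool(rng.random() < t.true_indel_freq)
            indel_size = 0
            if is_mutant and s + 1 <= cut_abs <= end - 1:
                k = int(rng.integers(lo_size, hi_size + 1))
                if rng.random() < config.deletion_fraction:
                    frag = seq[s:cut_abs] + seq[cut_abs + k : min(end + k, len(seq))]
                    indel_size = -k
                else:
                    ins = "".join(BASES[rng.integers(0, 4, size=k)])
                    frag = seq[s:cut_abs] + ins + seq[cut_abs : max(end - k, cut_abs)]
                    indel_size = k
            else:
                frag = seq[s:end]
            r1 = np.array(list(frag[: config.read_length]))
            r2 = np.array(list(revcomp(frag)[: config.read_length]))
            r1 = _apply_errors(r1, rng, config.subst_error_rate)
            r2 = _apply_errors(r2, rng, config.subst_error_rate)
            seq1, seq2 = "".join(r1), "".join(r2)
            q1 = "I" * len(seq1)
            q2 = "I" * len(seq2)
            if config.lowq_tail:
                n = config.lowq_tail
                q1 = q1[:-n] + "#" * min(n, len(q1))
                q2 = q2[:-n] + "#" * min(n, len(q2))
            pid = f"p{len(rows):07d}"
            pair = ReadPair(
                pid, seq1, seq2, q1, q2,
                map_chrom=region.chrom, map_start1=s, map_start2=end, orientation="FR",
            )
            pairs.append(pair)
            rows.append(
                (pid, region.region_id, region.chrom, s, end, "FR",
                 len(frag), indel_size != 0, indel_size, "")
            )
            if rng.random() < config.clonal_rate:
                dup_id = f"{pid}d"
                pairs.append(
                    ReadPair(
                        dup_id, seq1, seq2, q1, q2,
                        map_chrom=region.chrom, map_start1=s, map_start2=end,
                        orientation="FR",
                    )
                )
                rows.append(
                    (dup_id, region.region_id, region.chrom, s, end, "FR",
                     len(frag), indel_size != 0, indel_size, pid)
                )
    truth_df = pd.DataFrame(
        rows,
        columns=[
            "pair_id", "region_id", "chrom", "start1", "start2", "orientation",
            "frag_len", "is_mutant", "indel_size", "clone_of",
        ],
    )
    return pairs, truth_df


def pairs_to_fastq(pairs: list[ReadPair]) -> tuple[list[tuple], list[tuple]]:
    """(title, seq, qual) triples for R1 and R2 FASTQ export."""
    r1 = [(f"{p.pair_id}/1", p.seq1, p.qual1) for p in pairs]
    r2 = [(f"{p.pair_id}/2", p.seq2, p.qual2) for p in pairs]
    return r1, r2


def simulate_peak_sets(
    genome: dict[str, str],
    n_a: int,
    n_b: int,
    n_shared: int,
    length: int = 300,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Two BED peak sets with exactly ``n_shared`` mutually overlapping peaks.

    Shared peaks are written at identical coordinates in both sets; all
    distinct loci are separated by at least 1 bp so set algebra over them has
    a known answer.
    """
    if n_shared > min(n_a, n_b):
        raise ValueError("n_shared cannot exceed either set size")
    from captor.baits import pick_random_controls

    total = n_a + n_b - n_shared
    loci = pick_random_controls(genome, total, length=length, seed=np.random.default_rng([seed, 2]))
    loci = loci.sort_values(["chrom", "start"]).reset_index(drop=True)
    shared = loci.iloc[:n_shared].copy()
    a_only = loci.iloc[n_shared : n_a].copy()
    b_only = loci.iloc[n_a:].copy()
    bed_a = pd.concat([shared, a_only], ignore_index=True)
    bed_a["name"] = [f"A_{i}" for i in range(len(bed_a))]
    bed_b = pd.concat([shared, b_only], ignore_index=True)
    bed_b["name"] = [f"B_{i}" for i in range(len(bed_b))]
    return bed_a, bed_b
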