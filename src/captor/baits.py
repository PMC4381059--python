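"""Capture-region construction and hybridization-bait tiling.

Each candidate site is surveyed through a 200-bp region centered on it,
tiled by three 100-bp baits with a 50-bp walking step so the union of baits
covers the region exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from captor.io import BED_COLUMNS

REGION_LEN = 200
BAIT_LEN = 100
BAIT_STEP = 50

CATEGORIES = (
    "chip_S1",
    "chip_S2",
    "gRNA_independent",
    "predicted_S1",
    "predicted_S2",
    "random_control",
)


@dataclass
class CaptureRegion:
    """A 200-bp reference window centered on a candidate site."""

    region_id: str
    chrom: str
    start: int
    end: int
    ref_seq: str
    category: str = "random_control"
    baits: list[str] = field(default_factory=list)

    def __post_init__(self):
        if self.end - self.start != len(self.ref_seq):
            raise ValueError("reference sequence length must match the interval")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def center(self) -> int:
        return (self.start + self.end) // 2


def tile_baits(region_seq: str, bait_len: int = BAIT_LEN, step: int = BAIT_STEP) -> list[str]:
    """Tile a region with baits at offsets 0, step, 2*step.

    The region length must equal ``bait_len + 2*step`` so the three baits
    cover it exactly with ``bait_len - step`` pairwise overlap.
    """
    if len(region_seq) != bait_len + 2 * step:
        raise ValueError(
            f"region length {len(region_seq)} incompatible with "
            f"bait_len={bait_len}, step={step}"
        )
    return [region_seq[off : off + bait_len] for off in (0, step, 2 * step)]


def make_capture_regions(
    sites: pd.DataFrame,
    genome: dict[str, str],
    category: str | dict[str, str] | None = None,
    region_len: int = REGION_LEN,
) -> list[CaptureRegion]:
    """One 200-bp capture region per site, centered on the site midpoint.

    ``category`` may be a single label for the whole set or a dict keyed by
    site name.  Sites whose region would leave the contig are skipped with a
    warning.  Baits are tiled immediately.
    """
    half = region_len // 2
    regions = []
    skipped = 0
    for _, row in sites.iterrows():
        chrom = row["chrom"]
        seq = genome.get(chrom)
        center = (int(row["start"]) + int(row["end"])) // 2
        lo, hi = center - half, center - half + region_len
        if seq is None or lo < 0 or hi > len(seq):
            skipped += 1
            continue
        name = str(row.get("name", f"{chrom}:{lo}-{hi}"))
        cat = category.get(name, "random_control") if isinstance(category, dict) else (
            category or "random_control"
        )
        ref = seq[lo:hi].upper()
        regions.append(
            CaptureRegion(name, chrom, lo, hi, ref, cat, baits=tile_baits(ref))
        )
    if skipped:
        warnings.warn(f"{skipped} sites skipped: too close to a contig edge")
    return regions


def pick_random_controls(
    genome: dict[str, str],
    n: int,
    length: int = REGION_LEN,
    exclusions: pd.DataFrame | None = None,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Pick ``n`` non-overlapping random regions avoiding ``exclusions``.

    Starts are uniform over eligible positions, reproducible for a seed.
    Raises if the eligible space cannot host ``n`` disjoint regions within a
    bounded number of rejection-sampling attempts.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    from intervaltree import IntervalTree

    occupied: dict[str, IntervalTree] = {c: IntervalTree() for c in genome}
    if exclusions is not None:
        for chrom, s, e in zip(exclusions["chrom"], exclusions["start"], exclusions["end"]):
            if chrom in occupied and e > s:
                occupied[chrom].addi(int(s), int(e))

    chroms = sorted(genome)
    sizes = np.array([max(0, len(genome[c]) - length + 1) for c in chroms], dtype=float)
    if sizes.sum() == 0:
        raise ValueError("no eligible space for random control regions")
    probs = sizes / sizes.sum()

    picked = []
    attempts = 0
    max_attempts = 1000 * n + 1000
    while len(picked) < n:
        attempts += 1
        if attempts > max_attempts:
            raise ValueError(
                f"could not place {n} disjoint regions after {max_attempts} attempts"
            )
        ci = rng.choice(len(chroms), p=probs)
        chrom = chroms[ci]
        s = int(rng.integers(0, len(genome[chrom]) - length + 1))
        if occupied[chrom].overlap(s, s + length):
            continue
        occupied[chrom].addi(s, s + length)
        picked.append((chrom, s, s + length, f"random_{len(picked)}", 0, "."))
    return pd.DataFrame(picked, columns=BED_COLUMNS)


def bait_manifest(regions: list[CaptureRegion]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "region_id": [r.region_id for r in regions],
            "category": [r.category for r in regions],
            "chrom": [r.chrom for r in regions],
            "start": [r.start for r in regions],
            "end": [r.end for r in regions],
        }
    )


def bait_fasta(regions: list[CaptureRegion]) -> dict[str, str]:
    """Bait sequences keyed ``region_id|bait_k|offset`` for FASTA export."""
    out = {}
    for r in regions:
        for k, bait in enumerate(r.baits):
            out[f"{r.region_id}|bait_{k}|{k * BAIT_STEP}"] = bait
    return out
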