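"""Peak-set algebra and PAM-density statistics over ChIP peaks.

All operations use the >=1 shared base overlap criterion (the bedtools
default) and BED DataFrames with 0-based half-open coordinates.  PAM density
of a region is the number of NGG trinucleotide start positions on either
strand within the central 100 bp, expressed as a percentage of the window.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

from captor._seq import pattern_matcher, revcomp


@dataclass(frozen=True)
class GenomicInterval:
    chrom: str
    start: int
    end: int
    name: str = "."
    score: float = 0.0
    strand: str = "."

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError(f"empty interval {self.chrom}:{self.start}-{self.end}")


def _build_trees(bed: pd.DataFrame) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for chrom, grp in bed.groupby("chrom"):
        trees[chrom] = IntervalTree.from_tuples(
            (int(s), int(e)) for s, e in zip(grp["start"], grp["end"]) if e > s
        )
    return trees


def _overlaps_any(bed: pd.DataFrame, trees: dict[str, IntervalTree]) -> np.ndarray:
    out = np.zeros(len(bed), dtype=bool)
    for i, (chrom, s, e) in enumerate(zip(bed["chrom"], bed["start"], bed["end"])):
        t = trees.get(chrom)
        if t is not None and t.overlap(int(s), int(e)):
            out[i] = True
    return out


def split_grna_specific(
    peaks_a: pd.DataFrame, peaks_b: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Split two peak sets into common and set-specific peaks.

    ``common`` holds A peaks that touch (>=1 bp) any B peak — these are the
    gRNA-independent candidates, materialised from set A's coordinates.
    ``a_specific``/``b_specific`` are the remainders; each input set is
    partitioned exactly (no peak lost or duplicated).
    """
    trees_b = _build_trees(peaks_b)
    trees_a = _build_trees(peaks_a)
    in_b = _overlaps_any(peaks_a, trees_b)
    in_a = _overlaps_any(peaks_b, trees_a)
    common = peaks_a[in_b].reset_index(drop=True)
    a_specific = peaks_a[~in_b].reset_index(drop=True)
    b_specific = peaks_b[~in_a].reset_index(drop=True)
    return common, a_specific, b_specific


def intersect_replicates(rep1: pd.DataFrame, rep2: pd.DataFrame) -> pd.DataFrame:
    """High-confidence peaks: rep1 peaks with >= 1-bp overlap in rep2.

    rep1 coordinates are retained, so the operation is idempotent on
    identical replicates.
    """
    keep = _overlaps_any(rep1, _build_trees(rep2))
    return rep1[keep].reset_index(drop=True)


def overlap_fraction(
    peaks: pd.DataFrame, features: pd.DataFrame
) -> tuple[float, np.ndarray]:
    """Percent of peaks overlapping >= 1 feature, plus the per-peak booleans."""
    if len(peaks) == 0:
        return 0.0, np.zeros(0, dtype=bool)
    flags = _overlaps_any(peaks, _build_trees(features))
    return 100.0 * flags.sum() / len(peaks), flags


def subtract_blacklist(
    peaks: pd.DataFrame, blacklist: pd.DataFrame
) -> tuple[pd.DataFrame, int]:
    """Remove peaks with >= 1-bp blacklist overlap; report how many were hit."""
    if len(peaks) == 0:
        return peaks.copy(), 0
    flags = _overlaps_any(peaks, _build_trees(blacklist))
    return peaks[~flags].reset_index(drop=True), int(flags.sum())


@dataclass
class PamDensityResult:
    """Per-region PAM (NGG) density over central windows, as percentages."""

    set_label: str
    densities: np.ndarray  # one value per region, percent
    window: int = 100
    skipped: int = 0
    letter: str | None = None

    @property
    def n(self) -> int:
        return len(self.densities)

    @property
    def median(self) -> float:
        return float(np.median(self.densities))

    @property
    def mean(self) -> float:
        return float(np.mean(self.densities))

    @property
    def sd(self) -> float:
        return float(np.std(self.densities, ddof=1)) if self.n > 1 else 0.0


def count_pam_both_strands(window_seq: str, pam: str = "NGG") -> int:
    """NGG start positions on both strands of a sequence (overlaps allowed).

    Minus-strand NGGs appear as CCN on the plus strand; every trinucleotide
    start position inside the sequence is examined.
    """
    seq = window_seq.upper()
    match = pattern_matcher(pam)
    n = 0
    for s in range(len(seq) - 2):
        tri = seq[s : s + 3]
        if set(tri) - set("ACGT"):
            continue
        if match(tri):
            n += 1
        if match(revcomp(tri)):
            n += 1
    return n


def pam_density(
    regions: pd.DataFrame,
    genome: dict[str, str],
    window: int = 100,
    pam: str = "NGG",
    set_label: str = "regions",
) -> PamDensityResult:
    """PAM density of the central ``window`` bp of each region.

    Density = 100 * (# NGG occurrences, both strands) / window.  The region
    center is floor((start+end)/2); regions whose central window leaves the
    chromosome are skipped with a warning.
    """
    densities = []
    skipped = 0
    half = window // 2
    for chrom, s, e in zip(regions["chrom"], regions["start"], regions["end"]):
        seq = genome.get(chrom)
        center = (int(s) + int(e)) // 2
        lo, hi = center - half, center - half + window
        if seq is None or lo < 0 or hi > len(seq):
            skipped += 1
            continue
        densities.append(100.0 * count_pam_both_strands(seq[lo:hi], pam) / window)
    if skipped:
        warnings.warn(f"{skipped} regions skipped: central window out of bounds")
    return PamDensityResult(set_label, np.asarray(densities, dtype=float), window, skipped)


def compare_density_groups(
    results: list[PamDensityResult], alpha: float = 1e-4
) -> dict[str, str]:
    """Assign compact letters to groups via pairwise two-sample t-tests.

    Groups that are not significantly different at ``alpha`` share a letter;
    each group's letter string is attached to the result objects and returned
    keyed by set label.  Pairs where both samples have zero variance are
    flagged and skipped (treated as not significantly different, except when
    the two constant means differ).
    """
    if len(results) < 2:
        raise ValueError("need at least two groups to compare")
    for r in results:
        if r.n < 2:
            raise ValueError(f"group {r.set_label!r} has fewer than 2 regions")

    k = len(results)
    different = np.zeros((k, k), dtype=bool)
    for i in range(k):
        for j in range(i + 1, k):
            a, b = results[i].densities, results[j].densities
            if np.var(a) == 0 and np.var(b) == 0:
                sig = a.mean() != b.mean()
                if not sig:
                    warnings.warn(
                        f"degenerate variance comparing {results[i].set_label!r} "
                        f"and {results[j].set_label!r}; t-test skipped"
                    )
            else:
                _, p = stats.ttest_ind(a, b, equal_var=True)
                sig = p < alpha
            different[i, j] = different[j, i] = sig

    # Greedy compact-letter assignment in order of decreasing mean: reuse the
    # first letter class whose members are all indistinguishable from the group.
    order = sorted(range(k), key=lambda i: -results[i].mean)
    classes: list[list[int]] = []
    for idx in order:
        placed = False
        for cls in classes:
            if not any(different[idx, member] for member in cls):
                cls.append(idx)
                placed = True
                break
        if not placed:
            classes.append([idx])
    letters = {}
    for letter_i, cls in enumerate(classes):
        for member in cls:
            label = results[member].set_label
            letters[label] = letters.get(label, "") + chr(ord("A") + letter_i)
            results[member].letter = letters[label]
    return letters


def density_summary_table(results: list[PamDensityResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "set_label": [r.set_label for r in results],
            "n": [r.n for r in results],
            "median": [r.median for r in results],
            "mean": [r.mean for r in results],
            "sd": [r.sd for r in results],
            "letter": [r.letter for r in results],
        }
    )
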