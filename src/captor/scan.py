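"""Mismatch+PAM genome scanning and seed/core sequence statistics.

A *S. pyogenes* Cas9 target is a 20-nt protospacer immediately 5' of an NGG
protospacer-adjacent motif (PAM); a weaker NAG PAM is also recognised.  The
scanner enumerates, on both strands, every 23-bp window whose 3-mer suffix
matches a PAM pattern and whose 20-mer has at most ``max_mismatches``
substitutions against the protospacer.  Mismatch positions are numbered 1-20
with 20 PAM-adjacent, the convention used when discussing seed sensitivity.

Coordinates are 0-based half-open over the 20-nt protospacer match, reported
on the plus strand of the reference regardless of hit strand.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from captor._seq import IUPAC, encode, pattern_matcher, revcomp

PROTOSPACER_LEN = 20
PAM_LEN = 3
SEED_LEN = 12
CORE_LEN = 5


@dataclass(frozen=True)
class TargetSite:
    """A 20-nt protospacer plus PAM pattern.

    The PAM-proximal 12 nt are the *seed*; the data in this kind of screen
    support an even shorter 5-nt PAM-proximal *core* that dominates binding.
    """

    name: str
    protospacer: str
    pam_pattern: str = "NGG"
    chrom: str | None = None
    start: int | None = None
    end: int | None = None
    strand: str | None = None

    def __post_init__(self):
        proto = self.protospacer.upper()
        if len(proto) != PROTOSPACER_LEN or set(proto) - set("ACGT"):
            raise ValueError(
                f"protospacer must be 20 nt of A/C/G/T, got {self.protospacer!r}"
            )
        object.__setattr__(self, "protospacer", proto)
        pam = self.pam_pattern.upper()
        if len(pam) != PAM_LEN or set(pam) - set(IUPAC):
            raise ValueError(f"PAM pattern must be a 3-mer IUPAC string, got {pam!r}")
        object.__setattr__(self, "pam_pattern", pam)

    @property
    def seed12(self) -> str:
        """PAM-proximal 12 nt of the protospacer."""
        return self.protospacer[-SEED_LEN:]

    @property
    def core5(self) -> str:
        """PAM-proximal 5 nt (suffix of the seed)."""
        return self.protospacer[-CORE_LEN:]


@dataclass
class OffTargetHit:
    """A genomic locus matching a target with <= k mismatches next to a PAM."""

    chrom: str
    start: int  # 0-based start of the 20-nt protospacer match
    end: int  # half-open end (start + 20)
    strand: str
    matched_seq: str  # protospacer-oriented 20-mer
    pam: str  # observed 3-mer
    mismatch_count: int
    mismatch_positions: list[int] = field(default_factory=list)  # 1..20, 20 PAM-adjacent

    def as_bed_row(self) -> tuple:
        return (
            self.chrom,
            self.start,
            self.end,
            f"{self.mismatch_count}mm",
            self.mismatch_count,
            self.strand,
            self.matched_seq,
            self.pam,
            ",".join(map(str, self.mismatch_positions)) or ".",
        )


def _pam_mask(codes: np.ndarray, pattern: str, n_windows: int) -> np.ndarray:
    """Boolean mask over window starts whose PAM 3-mer matches ``pattern``.

    ``codes`` are ASCII codes; the PAM occupies positions [s+20, s+23).
    Ambiguous (non-ACGT) bases never match.
    """
    mask = np.ones(n_windows, dtype=bool)
    for k, sym in enumerate(pattern):
        allowed = np.frombuffer("".join(IUPAC[sym]).encode(), dtype=np.uint8)
        col = codes[PROTOSPACER_LEN + k : PROTOSPACER_LEN + k + n_windows]
        mask &= np.isin(col, allowed)
    return mask


def _scan_strand(seq: str, protospacer: str, max_mismatches: int, pam_patterns):
    """Yield (window_start, mismatch_positions, pam_str) for one strand."""
    codes = encode(seq)
    n_windows = len(seq) - PROTOSPACER_LEN - PAM_LEN + 1
    if n_windows <= 0:
        return
    target = encode(protospacer)
    acgt = np.frombuffer(b"ACGT", dtype=np.uint8)
    valid = np.isin(codes, acgt)

    mism = np.zeros(n_windows, dtype=np.int16)
    ok = np.ones(n_windows, dtype=bool)
    for p in range(PROTOSPACER_LEN):
        col = codes[p : p + n_windows]
        mism += col != target[p]
        ok &= valid[p : p + n_windows]

    pam_ok = np.zeros(n_windows, dtype=bool)
    for pat in pam_patterns:
        pam_ok |= _pam_mask(codes, pat, n_windows)

    hits = np.flatnonzero(ok & pam_ok & (mism <= max_mismatches))
    for s in hits:
        window = seq[s : s + PROTOSPACER_LEN]
        positions = [i + 1 for i in range(PROTOSPACER_LEN) if window[i] != protospacer[i]]
        yield int(s), positions, seq[s + PROTOSPACER_LEN : s + PROTOSPACER_LEN + PAM_LEN]


def scan_genome(
    genome: dict[str, str],
    target: TargetSite,
    max_mismatches: int = 4,
    pam_patterns: tuple[str, ...] = ("NGG",),
    mask: pd.DataFrame | None = None,
) -> list[OffTargetHit]:
    """Scan a genome for protospacer matches adjacent to a PAM, both strands.

    Parameters
    ----------
    genome : dict of chrom -> sequence (see :func:`captor.io.read_fasta`).
    target : the protospacer to search for.
    max_mismatches : maximum substitutions tolerated over the 20-mer.
    pam_patterns : IUPAC 3-mers; a window's PAM must match at least one.
    mask : optional BED DataFrame; hits whose protospacer interval overlaps
        any masked interval are dropped (off by default).

    Returns
    -------
    Hits sorted by (chrom, start); windows containing non-ACGT bases are
    skipped rather than matched through ambiguity codes.
    """
    if max_mismatches > PROTOSPACER_LEN:
        raise ValueError("max_mismatches cannot exceed the protospacer length")
    hits: list[OffTargetHit] = []
    for chrom in sorted(genome):
        seq = genome[chrom].upper()
        L = len(seq)
        for s, positions, pam in _scan_strand(
            seq, target.protospacer, max_mismatches, pam_patterns
        ):
            hits.append(
                OffTargetHit(
                    chrom, s, s + PROTOSPACER_LEN, "+",
                    seq[s : s + PROTOSPACER_LEN], pam, len(positions), positions,
                )
            )
        rc = revcomp(seq)
        for s, positions, pam in _scan_strand(
            rc, target.protospacer, max_mismatches, pam_patterns
        ):
            start = L - s - PROTOSPACER_LEN
            hits.append(
                OffTargetHit(
                    chrom, start, start + PROTOSPACER_LEN, "-",
                    rc[s : s + PROTOSPACER_LEN], pam, len(positions), positions,
                )
            )
    if mask is not None and len(mask):
        from captor.peaks import _build_trees

        trees = _build_trees(mask)
        hits = [
            h
            for h in hits
            if h.chrom not in trees or not trees[h.chrom].overlap(h.start, h.end)
        ]
    hits.sort(key=lambda h: (h.chrom, h.start, h.strand))
    return hits


def hits_to_bed(hits: list[OffTargetHit]) -> pd.DataFrame:
    cols = [
        "chrom", "start", "end", "name", "score", "strand",
        "matched_seq", "pam", "mismatch_positions",
    ]
    return pd.DataFrame([h.as_bed_row() for h in hits], columns=cols)


def _kmer_pam_matches(region_seq, kmer, max_mm, pam_pattern):
    """Placements of ``kmer`` with <= max_mm mismatches 5' of a PAM, one strand."""
    k = len(kmer)
    pam_match = pattern_matcher(pam_pattern)
    out = []
    for s in range(len(region_seq) - k - PAM_LEN + 1):
        window = region_seq[s : s + k]
        pam = region_seq[s + k : s + k + PAM_LEN]
        if set(window + pam) - set("ACGT"):
            continue
        if not pam_match(pam):
            continue
        mm = sum(a != b for a, b in zip(window, kmer))
        if mm <= max_mm:
            out.append((s, mm))
    return out


def seed_match(
    region_seq: str,
    target: TargetSite,
    seed_len: int = SEED_LEN,
    max_mm: int = 4,
    pam: str = "NGG",
) -> list[tuple[int, str, int]]:
    """Placements of the PAM-proximal seed (<= max_mm mismatches) next to a PAM.

    Both strands are searched; positions are plus-strand starts of the seed
    match.  A region "has a seed match" iff the result is non-empty.
    """
    region_seq = region_seq.upper()
    seed = target.protospacer[-seed_len:]
    out = [(s, "+", mm) for s, mm in _kmer_pam_matches(region_seq, seed, max_mm, pam)]
    rc = revcomp(region_seq)
    L = len(region_seq)
    for s, mm in _kmer_pam_matches(rc, seed, max_mm, pam):
        out.append((L - s - seed_len, "-", mm))
    out.sort()
    return out


def core_match(region_seq: str, target: TargetSite, pam: str = "NGG") -> int:
    """Count exact core5+PAM placements on both strands of a region."""
    region_seq = region_seq.upper()
    n = len(_kmer_pam_matches(region_seq, target.core5, 0, pam))
    n += len(_kmer_pam_matches(revcomp(region_seq), target.core5, 0, pam))
    return n


def rank_hits_vs_peaks(hits: list[OffTargetHit], peaks: pd.DataFrame):
    """For each hit, whether any peak interval overlaps it by >= 1 bp.

    Returns (per-hit boolean list, number of overlapping hits).  Hits on
    chromosomes absent from the peak set raise a warning once and count as
    non-overlapping.
    """
    from captor.peaks import _build_trees

    trees = _build_trees(peaks)
    warned: set[str] = set()
    flags = []
    for h in hits:
        if h.chrom not in trees:
            if h.chrom not in warned and len(peaks):
                warnings.warn(f"chromosome {h.chrom!r} absent from peak set")
                warned.add(h.chrom)
            flags.append(False)
            continue
        flags.append(bool(trees[h.chrom].overlap(h.start, h.end)))
    return flags, sum(flags)
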