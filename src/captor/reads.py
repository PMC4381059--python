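"""Capture read handling: filtering, clonal removal, merging, region assignment.

Reads arrive as paired FASTQ plus mapping coordinates (from an external
aligner via SAM, or from the simulator's truth).  Clonal (PCR-duplicate)
pairs share both mates' mapped start positions and orientation; exactly one
representative of each clonal family is retained.  Pair merging joins mates
whose 3'/5' ends share an exact overlap of at least 5 bp, reconstructing the
sequenced fragment.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

from captor._lcs import longest_common_substring
from captor._seq import encode, revcomp

MIN_READ_LEN = 35
MIN_MERGE_OVERLAP = 5


@dataclass
class ReadPair:
    """One capture read pair with optional mapping/assignment metadata."""

    pair_id: str
    seq1: str
    seq2: str
    qual1: str = ""
    qual2: str = ""
    map_chrom: str | None = None
    map_start1: int | None = None
    map_start2: int | None = None
    orientation: str = "FR"
    assigned_region: str | None = None
    unique: bool | None = None

    def clonal_key(self):
        if self.map_start1 is None or self.map_start2 is None:
            return None
        return (self.map_chrom, self.map_start1, self.map_start2, self.orientation)


def _trim_quality_3prime(seq: str, qual: str, threshold: int) -> tuple[str, str]:
    """Strip 3' bases whose phred score is below threshold (Illumina 1.8+)."""
    cut = len(seq)
    while cut > 0 and ord(qual[cut - 1]) - 33 < threshold:
        cut -= 1
    return seq[:cut], qual[:cut]


def _trim_n(seq: str, qual: str) -> tuple[str, str]:
    start = 0
    while start < len(seq) and seq[start] == "N":
        start += 1
    end = len(seq)
    while end > start and seq[end - 1] == "N":
        end -= 1
    return seq[start:end], qual[start:end]


def _trim_adapter(seq: str, qual: str, adapter: str) -> tuple[str, str]:
    idx = seq.find(adapter)
    if idx >= 0:
        return seq[:idx], qual[:idx]
    return seq, qual


def preprocess_reads(
    pairs: Iterable[ReadPair],
    min_len: int = MIN_READ_LEN,
    qual_threshold: int = 20,
    adapter: str | None = None,
) -> list[ReadPair]:
    """Quality/adapter/N trimming; discard pairs with a mate under ``min_len``.

    3' bases below the quality threshold are stripped, then leading/trailing
    N bases, then any adapter suffix.  Both mates are discarded if either one
    ends up shorter than ``min_len``.
    """
    kept = []
    for p in pairs:
        s1, q1 = _trim_quality_3prime(p.seq1, p.qual1 or "I" * len(p.seq1), qual_threshold)
        s2, q2 = _trim_quality_3prime(p.seq2, p.qual2 or "I" * len(p.seq2), qual_threshold)
        s1, q1 = _trim_n(s1, q1)
        s2, q2 = _trim_n(s2, q2)
        if adapter:
            s1, q1 = _trim_adapter(s1, q1, adapter)
            s2, q2 = _trim_adapter(s2, q2, adapter)
        if len(s1) < min_len or len(s2) < min_len:
            continue
        kept.append(replace(p, seq1=s1, qual1=q1, seq2=s2, qual2=q2))
    return kept


def remove_clonal(pairs: Sequence[ReadPair]) -> list[ReadPair]:
    """Keep one pair per (chrom, start1, start2, orientation) clonal key.

    The first-encountered pair of each family is retained (stable order);
    pairs without mapping coordinates cannot be keyed and pass through.
    The operation is idempotent.
    """
    seen = set()
    kept = []
    for p in pairs:
        key = p.clonal_key()
        if key is None:
            kept.append(p)
            continue
        if key not in seen:
            seen.add(key)
            kept.append(p)
    return kept


def merge_pair(seq1: str, seq2: str, min_overlap: int = MIN_MERGE_OVERLAP) -> str | None:
    """Merge mates through the longest exact 3'/5' overlap of >= 5 bp.

    Mate 2 is reverse complemented before the search.  Overlap lengths are
    tried from the longest down, so the longest exact overlap wins (full
    containment merges to the longer read).  Returns the merged sequence or
    None when no adequate overlap exists.
    """
    rc2 = revcomp(seq2)
    for olen in range(min(len(seq1), len(rc2)), min_overlap - 1, -1):
        if seq1[-olen:] == rc2[:olen]:
            return seq1 + rc2[olen:]
    return None


def merged_sequences(pair: ReadPair) -> list[str]:
    """Sequences a pair contributes to classification: merged, or both mates.

    Unmerged mates are emitted separately, mate 2 reverse complemented so all
    sequences are in reference orientation of mate 1's strand.
    """
    merged = merge_pair(pair.seq1, pair.seq2)
    if merged is not None:
        return [merged]
    return [pair.seq1, revcomp(pair.seq2)]


class RegionAssigner:
    """Assign read pairs to capture regions by their best exact anchor.

    Candidate regions are short-listed through a k-mer index of the region
    references (both strands); among candidates the score is the longest
    common substring between either mate (either orientation) and the region
    reference.  A pair is assigned iff one region's score is strictly best —
    ties leave the pair unassigned.  Regions sharing no indexed k-mer with a
    read have anchors shorter than k and cannot beat an indexed candidate.
    """

    def __init__(self, regions, k: int = 12):
        self.k = k
        self.regions = {r.region_id: r for r in regions}
        self._encoded = {
            rid: (encode(r.ref_seq), encode(revcomp(r.ref_seq)))
            for rid, r in self.regions.items()
        }
        self.index: dict[str, set[str]] = {}
        for rid, r in self.regions.items():
            for seq in (r.ref_seq, revcomp(r.ref_seq)):
                for i in range(len(seq) - k + 1):
                    self.index.setdefault(seq[i : i + k], set()).add(rid)

    def _candidates(self, pair: ReadPair) -> set[str]:
        cands: set[str] = set()
        for seq in (pair.seq1, pair.seq2):
            for i in range(0, len(seq) - self.k + 1):
                hit = self.index.get(seq[i : i + self.k])
                if hit:
                    cands |= hit
        return cands

    def _score(self, pair: ReadPair, rid: str) -> int:
        fwd, rc = self._encoded[rid]
        best = 0
        for seq in (pair.seq1, pair.seq2):
            q = encode(seq)
            for ref in (fwd, rc):
                length, _, _ = longest_common_substring(q, ref)
                if length > best:
                    best = length
        return best

    def assign(self, pair: ReadPair) -> ReadPair:
        cands = self._candidates(pair)
        if not cands:
            return replace(pair, assigned_region=None, unique=False)
        if len(cands) == 1:
            return replace(pair, assigned_region=next(iter(cands)), unique=True)
        scores = {rid: self._score(pair, rid) for rid in cands}
        ranked = sorted(scores.items(), key=lambda kv: (-kv[1], kv[0]))
        if len(ranked) > 1 and ranked[0][1] == ranked[1][1]:
            return replace(pair, assigned_region=None, unique=False)
        return replace(pair, assigned_region=ranked[0][0], unique=True)


def assign_to_regions(pairs: Iterable[ReadPair], regions, k: int = 12) -> list[ReadPair]:
    """Assign each pair to its unique best-anchor region (see RegionAssigner)."""
    assigner = RegionAssigner(regions, k=k)
    return [assigner.assign(p) for p in pairs]


def read_pairs_from_fastq(r1_path, r2_path, truth=None) -> list[ReadPair]:
    """Load paired FASTQ into ReadPair objects.

    ``truth`` may be a DataFrame indexed by pair id carrying mapping
    coordinates (chrom, start1, start2, orientation) — the synthetic stand-in
    for an external aligner's SAM.
    """
    from captor.io import read_fastq

    coords = {}
    if truth is not None:
        for row in truth.itertuples():
            coords[str(row.pair_id)] = (
                row.chrom, int(row.start1), int(row.start2), row.orientation
            )
    pairs = []
    for (t1, s1, q1), (t2, s2, q2) in zip(read_fastq(r1_path), read_fastq(r2_path)):
        pid = t1.split()[0].removesuffix("/1")
        pid2 = t2.split()[0].removesuffix("/2")
        if pid != pid2:
            raise ValueError(f"unpaired FASTQ records: {t1!r} vs {t2!r}")
        chrom = st1 = st2 = None
        orient = "FR"
        if pid in coords:
            chrom, st1, st2, orient = coords[pid]
        pairs.append(ReadPair(pid, s1, s2, q1, q2, chrom, st1, st2, orient))
    return pairs


def read_pairs_from_sam(path) -> list[ReadPair]:
    """Build ReadPairs from a (name-grouped or unsorted) SAM via pysam.

    Mate sequences are restored to original read orientation; mapped start
    positions of both mates feed the clonal key.
    """
    import pysam

    mates: dict[str, dict[int, tuple]] = {}
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for aln in sam:
            if aln.is_secondary or aln.is_supplementary:
                continue
            seq = aln.query_sequence or ""
            qual = (
                "".join(chr(q + 33) for q in aln.query_qualities)
                if aln.query_qualities is not None
                else "I" * len(seq)
            )
            if aln.is_reverse:
                seq, qual = revcomp(seq), qual[::-1]
            which = 2 if aln.is_read2 else 1
            rec = (
                seq,
                qual,
                aln.reference_name,
                None if aln.is_unmapped else int(aln.reference_start),
                aln.is_reverse,
            )
            mates.setdefault(aln.query_name, {})[which] = rec
    pairs = []
    for name, d in mates.items():
        if 1 not in d or 2 not in d:
            continue
        s1, q1, chrom, st1, rev1 = d[1]
        s2, q2, _, st2, rev2 = d[2]
        orient = ("R" if rev1 else "F") + ("R" if rev2 else "F")
        pairs.append(ReadPair(name, s1, s2, q1, q2, chrom, st1, st2, orient))
    pairs.sort(key=lambda p: p.pair_id)
    return pairs
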