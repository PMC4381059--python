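"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive (python loops, exhaustive enumeration,
off-the-shelf global alignment) and shares no code path with the package
implementation it checks.
"""

from __future__ import annotations

import math

import edlib

COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}

IUPAC_SETS = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "N": "ACGT", "R": "AG", "Y": "CT",
}


def rc(seq: str) -> str:
    return "".join(COMP[c] for c in reversed(seq))


def pam_ok(kmer: str, pattern: str) -> bool:
    return len(kmer) == len(pattern) and all(
        b in IUPAC_SETS[p] for b, p in zip(kmer, pattern)
    )


def brute_force_scan(genome: dict[str, str], protospacer: str, max_mm: int,
                     pam: str) -> set[tuple]:
    """Enumerate every 23-mer window on both strands; no shared code with scan.

    Returns {(chrom, plus_strand_start_of_protospacer, strand, mismatches)}.
    """
    hits = set()
    L = len(protospacer)
    for chrom, seq in genome.items():
        n = len(seq)
        for s in range(n - L - 2):
            window = seq[s : s + L + 3]
            if any(c not in "ACGT" for c in window):
                continue
            # plus strand: protospacer then PAM
            if pam_ok(window[L:], pam):
                mm = sum(a != b for a, b in zip(window[:L], protospacer))
                if mm <= max_mm:
                    hits.add((chrom, s, "+", mm))
            # minus strand: reverse complement reads protospacer+PAM
            w = rc(window)
            if pam_ok(w[L:], pam):
                mm = sum(a != b for a, b in zip(w[:L], protospacer))
                if mm <= max_mm:
                    hits.add((chrom, s + 3, "-", mm))
    return hits


def align_classify(read: str, ref: str) -> tuple[str, int]:
    """Unit-cost global(infix)-alignment classification of a read.

    Aligns the read (better orientation) into the reference with edlib and
    reads the class off the extended cigar: net inserted-minus-deleted bases
    decides insertion/deletion; otherwise any mismatch means SNP, else WT.
    """
    best = None
    for seq in (read, rc(read)):
        res = edlib.align(seq, ref, mode="HW", task="path")
        if best is None or res["editDistance"] < best["editDistance"]:
            best = res
    ins = dels = subs = 0
    num = ""
    for c in best["cigar"]:
        if c.isdigit():
            num += c
            continue
        n = int(num)
        num = ""
        if c == "I":
            ins += n
        elif c == "D":
            dels += n
        elif c == "X":
            subs += n
    net = ins - dels
    if net < 0:
        return "deletion", net
    if net > 0:
        return "insertion", net
    if subs:
        return "SNP", 0
    return "WT", 0


def fisher_tail_enumeration(a: int, b: int, c: int, d: int) -> float:
    """One-sided Fisher p by explicit hypergeometric tail summation.

    Table [[a, b], [c, d]]; tests enrichment of the first cell (greater).
    """
    row1, col1, n = a + b, a + c, a + b + c + d

    def log_choose(n_, k_):
        return math.lgamma(n_ + 1) - math.lgamma(k_ + 1) - math.lgamma(n_ - k_ + 1)

    denom = log_choose(n, col1)
    p = 0.0
    for k in range(a, min(row1, col1) + 1):
        if col1 - k > n - row1:
            continue
        p += math.exp(log_choose(row1, k) + log_choose(n - row1, col1 - k) - denom)
    return min(p, 1.0)


def sliding_pam_count(window: str) -> int:
    """NGG-on-either-strand count via direct character tests (no IUPAC code)."""
    n = 0
    for i in range(len(window) - 2):
        if window[i + 1] == "G" and window[i + 2] == "G":
            n += 1
        if window[i] == "C" and window[i + 1] == "C":
            n += 1
    return n


def quadratic_overlaps(set_a, set_b) -> list[bool]:
    """All-pairs >=1 bp overlap check for (chrom, start, end) tuples."""
    out = []
    for ca, sa, ea in set_a:
        out.append(
            any(cb == ca and sb < ea and sa < eb for cb, sb, eb in set_b)
        )
    return out
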