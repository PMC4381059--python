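"""Small sequence helpers shared across modules."""

from __future__ import annotations

import numpy as np

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

#: IUPAC degenerate nucleotide codes (unambiguous bases only on the right).
IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (IUPAC N preserved)."""
    return seq.translate(_COMPLEMENT)[::-1]


def encode(seq: str) -> np.ndarray:
    """Encode a DNA string as a uint8 array of ASCII codes."""
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def pattern_matcher(pattern: str):
    """Return a predicate testing an unambiguous k-mer against an IUPAC pattern.

    Ambiguity codes in the *query* never match: the N of a PAM pattern stands
    for any real base, not for an undetermined one.
    """
    sets = [frozenset(IUPAC[c]) for c in pattern.upper()]

    def match(kmer: str) -> bool:
        if len(kmer) != len(sets):
            return False
        return all(b in s for b, s in zip(kmer.upper(), sets))

    return match


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("hamming distance requires equal lengths")
    return sum(x != y for x, y in zip(a, b))


def max_homopolymer_run(seq: str) -> int:
    """Length of the longest run of identical consecutive bases."""
    best = run = 0
    prev = ""
    for c in seq:
        run = run + 1 if c == prev else 1
        prev = c
        if run > best:
            best = run
    return best
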