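"""Longest-common-substring kernel.

The anchor classifier and the region assigner both need exact longest common
substrings between a read and a 200-bp reference.  The dynamic program is
O(n*m) per pair; it is compiled with numba so that screens with 10^5 reads
stay in seconds.  Ties are broken toward the earliest end position in the
first sequence, then in the second — a fixed, documented convention so runs
are reproducible.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def _lcs_kernel(a: np.ndarray, b: np.ndarray):  # pragma: no cover - compiled
    n = a.shape[0]
    m = b.shape[0]
    prev = np.zeros(m + 1, dtype=np.int32)
    cur = np.zeros(m + 1, dtype=np.int32)
    best = 0
    end_a = 0
    end_b = 0
    for i in range(1, n + 1):
        ai = a[i - 1]
        for j in range(1, m + 1):
            if ai == b[j - 1]:
                v = prev[j - 1] + 1
                cur[j] = v
                if v > best:
                    best = v
                    end_a = i
                    end_b = j
            else:
                cur[j] = 0
        prev, cur = cur, prev
    return best, end_a, end_b


def longest_common_substring(a: np.ndarray, b: np.ndarray) -> tuple[int, int, int]:
    """Longest exact common substring of two encoded sequences.

    Parameters
    ----------
    a, b : uint8 arrays (ASCII codes, see :func:`captor._seq.encode`).

    Returns
    -------
    (length, end_a, end_b) : the match is ``a[end_a-length:end_a]`` ==
        ``b[end_b-length:end_b]``; ``(0, 0, 0)`` if the sequences share no base.
    """
    if a.shape[0] == 0 or b.shape[0] == 0:
        return 0, 0, 0
    best, ea, eb = _lcs_kernel(a, b)
    return int(best), int(ea), int(eb)
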