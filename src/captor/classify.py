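"""Anchor-based WT/SNP/indel classification of capture reads.

A read (merged pair or single mate) is compared to its region's 200-nt
reference through exact anchors:

1. the longest common substring (primary anchor) between read and reference,
   in either orientation; reads whose best anchor is shorter than
   ``min_anchor`` (20 bp) are discarded;
2. on each unanchored read flank, further anchors — repeatedly, the longest
   common substring of the remainder against the corresponding side of the
   reference — until the leftover is shorter than ``min_second_anchor``;
   short leftovers (stray tail bases from sequencing errors or beyond the
   region boundary) are ignored so they cannot fabricate indels;
3. the implied reference span between the outer anchor endpoints must reach
   ``min_span`` (100 bp) or the read is discarded;
4. the net length difference between the read span and the reference span
   decides the class: negative = deletion, positive = insertion, zero with
   all bases equal = WT, zero with mismatches = SNP.

The indel's position is summarised as the midpoint of the inter-anchor gap
on the reference, expressed relative to the region center (offset 0 = center
of the 200-bp region); Cas9 cuts ~3 bp upstream of the PAM, so true indels
cluster near the center by construction of the capture regions.
"""

from __future__ import annotations

from dataclasses import dataclass

from captor._lcs import longest_common_substring
from captor._seq import encode, revcomp

MIN_ANCHOR = 20
MIN_SPAN = 100
MIN_SECOND_ANCHOR = 10

WT = "WT"
SNP = "SNP"
INSERTION = "insertion"
DELETION = "deletion"
DISCARDED = "discarded"


@dataclass
class ClassifiedRead:
    region_id: str
    label: str
    net_indel_size: int = 0  # signed; deletions negative
    indel_center_offset: int | None = None  # bases relative to region center
    n_mismatches: int = 0
    read_id: str | None = None


def _classify_oriented(seq: str, ref: str, min_anchor: int, min_span: int,
                       min_second_anchor: int):
    """Classify one orientation; returns (anchor_len, result or None)."""
    q = encode(seq)
    r = encode(ref)
    alen, qa_end, ra_end = longest_common_substring(q, r)
    if alen < min_anchor:
        return alen, None
    qa0, qa1 = qa_end - alen, qa_end
    ra0, ra1 = ra_end - alen, ra_end

    # Outer endpoints start at the primary anchor and are pushed outward by
    # chains of flank anchors: each unanchored remainder is matched against
    # the corresponding side of the reference, and the process repeats on
    # what is still left, so an indel and a sequencing error on the same
    # flank are both resolved.
    gaps = []  # (ref_gap_start, ref_gap_end, read_gap_len)

    q_hi, r_hi = qa1, ra1
    while len(seq) - q_hi >= min_second_anchor:
        rlen, rq_end, rr_end = longest_common_substring(q[q_hi:], r[r_hi:])
        if rlen < min_second_anchor:
            break
        gaps.append((r_hi, r_hi + rr_end - rlen, rq_end - rlen))
        q_hi += rq_end
        r_hi += rr_end

    q_lo, r_lo = qa0, ra0
    while q_lo >= min_second_anchor:
        llen, lq_end, lr_end = longest_common_substring(q[:q_lo], r[:r_lo])
        if llen < min_second_anchor:
            break
        gaps.append((lr_end, r_lo, q_lo - lq_end))
        q_lo = lq_end - llen
        r_lo = lr_end - llen

    span = r_hi - r_lo
    if span < min_span:
        return alen, (DISCARDED, 0, None, 0)

    net = (q_hi - q_lo) - span
    if net == 0:
        # length-preserving read: compare the whole read at the implied
        # placement so substitutions in short unanchored tails still count
        off = r_lo - q_lo
        i0 = max(0, -off)
        i1 = min(len(seq), len(ref) - off)
        mism = sum(seq[i] != ref[i + off] for i in range(i0, i1))
        label = WT if mism == 0 else SNP
        return alen, (label, 0, None, mism)

    # Indel: locate it at the midpoint of the widest inter-anchor gap.
    center = len(ref) // 2
    if gaps:
        g0, g1, qg = max(gaps, key=lambda g: abs(g[2] - (g[1] - g[0])))
        offset = (g0 + g1) // 2 - center
    else:
        offset = None
    label = DELETION if net < 0 else INSERTION
    return alen, (label, net, offset, 0)


def classify_read(
    seq: str,
    region_ref: str,
    region_id: str = "",
    min_anchor: int = MIN_ANCHOR,
    min_span: int = MIN_SPAN,
    min_second_anchor: int = MIN_SECOND_ANCHOR,
    read_id: str | None = None,
) -> ClassifiedRead:
    """Classify a read against a region reference (both orientations tried).

    The orientation with the longer primary anchor wins (forward on ties).
    """
    best = None
    best_alen = -1
    for oriented in (seq, revcomp(seq)):
        alen, result = _classify_oriented(
            oriented, region_ref, min_anchor, min_span, min_second_anchor
        )
        if alen > best_alen:
            best_alen = alen
            best = result
    if best is None:
        return ClassifiedRead(region_id, DISCARDED, read_id=read_id)
    label, net, offset, mism = best
    return ClassifiedRead(region_id, label, net, offset, mism, read_id=read_id)


def classify_pairs(pairs, regions, **kwargs) -> list[ClassifiedRead]:
    """Classify every merged sequence of every assigned pair.

    ``regions`` maps region_id -> CaptureRegion (or any object with
    ``ref_seq``).  Unassigned pairs are skipped.
    """
    from captor.reads import merged_sequences

    region_map = regions if isinstance(regions, dict) else {r.region_id: r for r in regions}
    out = []
    for p in pairs:
        if not p.assigned_region:
            continue
        region = region_map[p.assigned_region]
        for i, seq in enumerate(merged_sequences(p)):
            out.append(
                classify_read(
                    seq,
                    region.ref_seq,
                    region_id=p.assigned_region,
                    read_id=f"{p.pair_id}.{i}",
                    **kwargs,
                )
            )
    return out
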