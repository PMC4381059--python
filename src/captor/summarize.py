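"""Per-region indel summaries, exclusion filters and Fisher significance.

The indel percentage of a region is 100 * (insertions + deletions) / all
classified reads (WT and SNP reads stay in the denominator).  Regions are
excluded from significance testing when coverage is below ``min_reads``
(default 25), when the reference carries a homopolymer run of
``homopolymer_len`` or more (indel calling is unreliable next to
homopolymers), or when the untreated control already shows more than
``background_pct`` indels (strain/reference mismatch rather than nuclease
activity).  Enrichment of indels in the treated sample over the untreated
control is assessed with a one-sided Fisher's exact test on the 2x2 table
(indel, non-indel) x (treated, control).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from captor._seq import max_homopolymer_run
from captor.classify import DELETION, DISCARDED, INSERTION, SNP, WT

MIN_READS = 25
HOMOPOLYMER_LEN = 5
BACKGROUND_PCT = 5.0
ALPHA = 0.01


@dataclass
class RegionIndelSummary:
    region_id: str
    n_wt: int = 0
    n_snp: int = 0
    n_ins: int = 0
    n_del: int = 0
    n_discarded: int = 0  # audit only; not part of n_total
    flags: set[str] = field(default_factory=set)

    @property
    def n_total(self) -> int:
        return self.n_wt + self.n_snp + self.n_ins + self.n_del

    @property
    def n_indel(self) -> int:
        return self.n_ins + self.n_del

    @property
    def indel_pct(self) -> float:
        return 100.0 * self.n_indel / self.n_total if self.n_total else 0.0


@dataclass
class SignificanceResult:
    region_id: str
    treated: tuple[int, int]  # (indel, non-indel)
    control: tuple[int, int]
    fisher_p: float
    significant: bool
    excluded: bool = False


def tally_regions(classified) -> dict[str, RegionIndelSummary]:
    """Count classified reads per region (audit-counting discarded reads)."""
    out: dict[str, RegionIndelSummary] = {}
    for c in classified:
        s = out.setdefault(c.region_id, RegionIndelSummary(c.region_id))
        if c.label == WT:
            s.n_wt += 1
        elif c.label == SNP:
            s.n_snp += 1
        elif c.label == INSERTION:
            s.n_ins += 1
        elif c.label == DELETION:
            s.n_del += 1
        elif c.label == DISCARDED:
            s.n_discarded += 1
    return out


def summarize_regions(
    classified,
    regions,
    untreated: dict[str, RegionIndelSummary] | None = None,
    min_reads: int = MIN_READS,
    homopolymer_len: int = HOMOPOLYMER_LEN,
    background_pct: float = BACKGROUND_PCT,
) -> dict[str, RegionIndelSummary]:
    """Per-region summaries with exclusion flags for every capture region.

    ``regions`` provides the universe of region_ids and reference sequences
    (for the homopolymer filter); regions absent from the classification get
    an empty, low-coverage summary.  ``untreated`` supplies the background
    indel percentages for the high-background flag.
    """
    region_map = regions if isinstance(regions, dict) else {r.region_id: r for r in regions}
    tallies = tally_regions(classified)
    out = {}
    for rid, region in region_map.items():
        s = tallies.get(rid, RegionIndelSummary(rid))
        if s.n_total < min_reads:
            s.flags.add("low_coverage")
        if max_homopolymer_run(region.ref_seq) >= homopolymer_len:
            s.flags.add("homopolymer")
        if untreated is not None:
            u = untreated.get(rid)
            if u is not None and u.indel_pct > background_pct:
                s.flags.add("high_background")
        out[rid] = s
    return out


def fisher_significance(
    treated: RegionIndelSummary,
    control: RegionIndelSummary,
    alpha: float = ALPHA,
    direction: str = "greater",
) -> SignificanceResult:
    """One-sided Fisher's exact test for indel enrichment in the treated sample.

    ``direction='greater'`` tests enrichment in treated (the screen's call);
    ``'less'`` runs the reverse analysis.  Flagged or empty regions are
    excluded (p = 1, not significant).
    """
    t = (treated.n_indel, treated.n_total - treated.n_indel)
    c = (control.n_indel, control.n_total - control.n_indel)
    rid = treated.region_id
    if treated.flags or control.flags or treated.n_total == 0 or control.n_total == 0:
        return SignificanceResult(rid, t, c, 1.0, False, excluded=True)
    _, p = stats.fisher_exact([[t[0], t[1]], [c[0], c[1]]], alternative=direction)
    return SignificanceResult(rid, t, c, float(p), bool(p < alpha))


def significance_table(
    treated: dict[str, RegionIndelSummary],
    control: dict[str, RegionIndelSummary],
    alpha: float = ALPHA,
    direction: str = "greater",
    correction: str | None = None,
) -> pd.DataFrame:
    """Fisher tests across all regions; optional multiple-testing correction.

    ``correction`` may be None (raw p, the default), 'bonferroni' or 'bh'
    (Benjamini-Hochberg); the significance column always honours ``alpha``
    on the (possibly adjusted) p-values.
    """
    rows = []
    for rid in sorted(treated):
        res = fisher_significance(
            treated[rid], control.get(rid, RegionIndelSummary(rid)), alpha, direction
        )
        rows.append(
            {
                "region_id": rid,
                "treated_indel": res.treated[0],
                "treated_other": res.treated[1],
                "control_indel": res.control[0],
                "control_other": res.control[1],
                "indel_pct": treated[rid].indel_pct,
                "control_indel_pct": control.get(rid, RegionIndelSummary(rid)).indel_pct,
                "flags": ",".join(sorted(treated[rid].flags)) or ".",
                "fisher_p": res.fisher_p,
                "excluded": res.excluded,
                "significant": res.significant,
            }
        )
    df = pd.DataFrame(rows)
    if correction and len(df):
        tested = ~df["excluded"]
        m = int(tested.sum())
        p = df.loc[tested, "fisher_p"].to_numpy()
        if correction == "bonferroni":
            adj = np.minimum(p * m, 1.0)
        elif correction == "bh":
            order = np.argsort(p)
            ranked = p[order] * m / (np.arange(m) + 1)
            ranked = np.minimum.accumulate(ranked[::-1])[::-1]
            adj = np.empty(m)
            adj[order] = np.minimum(ranked, 1.0)
        else:
            raise ValueError(f"unknown correction {correction!r}")
        df["fisher_p_adj"] = np.nan
        df.loc[tested, "fisher_p_adj"] = adj
        df["significant"] = tested & (df["fisher_p_adj"] < alpha)
    return df


def indel_profiles(classified) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Signed indel-size and center-offset histograms, per region.

    Returns (size_df, offset_df) with columns region_id/value/count; deletion
    sizes are negative.
    """
    sizes: dict[tuple[str, int], int] = {}
    offsets: dict[tuple[str, int], int] = {}
    for c in classified:
        if c.label not in (INSERTION, DELETION):
            continue
        key = (c.region_id, c.net_indel_size)
        sizes[key] = sizes.get(key, 0) + 1
        if c.indel_center_offset is not None:
            okey = (c.region_id, c.indel_center_offset)
            offsets[okey] = offsets.get(okey, 0) + 1
    size_df = pd.DataFrame(
        [(r, v, n) for (r, v), n in sorted(sizes.items())],
        columns=["region_id", "net_indel_size", "count"],
    )
    offset_df = pd.DataFrame(
        [(r, v, n) for (r, v), n in sorted(offsets.items())],
        columns=["region_id", "center_offset", "count"],
    )
    return size_df, offset_df


def coverage_stats(
    assigned_pairs,
    targeted_ids,
    random_ids,
    random_floor: float = 1.0,
) -> dict:
    """Mean reads per targeted region and fold enrichment over random regions.

    When the random regions attract fewer than ``random_floor`` reads each on
    average, enrichment is reported as a lower bound at the floor (the true
    ratio divides by nearly zero); the raw random mean is reported alongside.
    """
    counts: dict[str, int] = {}
    for p in assigned_pairs:
        if p.assigned_region:
            counts[p.assigned_region] = counts.get(p.assigned_region, 0) + 1
    targeted = np.array([counts.get(r, 0) for r in targeted_ids], dtype=float)
    random_ = np.array([counts.get(r, 0) for r in random_ids], dtype=float)
    mean_t = float(targeted.mean()) if len(targeted) else 0.0
    mean_r = float(random_.mean()) if len(random_) else 0.0
    floored = mean_r < random_floor
    denom = max(mean_r, random_floor)
    return {
        "mean_targeted": mean_t,
        "mean_random": mean_r,
        "fold_enrichment": mean_t / denom if denom else float("nan"),
        "enrichment_is_lower_bound": floored,
    }


def summary_table(summaries: dict[str, RegionIndelSummary], categories=None) -> pd.DataFrame:
    rows = []
    for rid in sorted(summaries):
        s = summaries[rid]
        rows.append(
            {
                "region_id": rid,
                "category": (categories or {}).get(rid, "."),
                "n_total": s.n_total,
                "n_wt": s.n_wt,
                "n_snp": s.n_snp,
                "n_ins": s.n_ins,
                "n_del": s.n_del,
                "n_discarded": s.n_discarded,
                "indel_pct": s.indel_pct,
                "flags": ",".join(sorted(s.flags)) or ".",
            }
        )
    return pd.DataFrame(rows)
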