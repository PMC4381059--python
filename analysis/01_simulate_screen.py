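#!/usr/bin/env python
"""Generate the synthetic capture screen this analysis runs on.

Writes, under scratch/screen_inputs/: a random 42%-GC genome with the S1 and
S2 protospacers planted at two capture-region centers, a BED of 20 candidate
200-bp regions (three with true indel signal: 15% at the S1 site, 35% at the
S2 site, 5% at one unplanted region), ChIP-peak BED fixtures, and paired-end
capture FASTQs (treated + untreated control) with per-pair mapping
coordinates standing in for an external aligner.  Raw pair depth is chosen
so each region ends up with ~300 classifiable reads.
"""

import argparse
from pathlib import Path

from captor.config import save_config
from captor.screen import raw_depth_for_coverage, write_synthetic_inputs
from captor.simulate import SimConfig

OUT = Path("scratch/screen_inputs")
FREQS = {0: 0.15, 1: 0.35, 5: 0.05}


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--n-regions", type=int, default=20)
    args = ap.parse_args()

    sim = SimConfig(seed=args.seed, genome_length=120_000)
    sim = SimConfig(seed=args.seed, genome_length=120_000,
                    depth_per_region=raw_depth_for_coverage(300, sim))
    cfg = write_synthetic_inputs(OUT, sim, args.n_regions, FREQS, seed=args.seed)
    save_config(cfg, OUT / "screen_config.yaml")
    print(f"inputs written to {OUT}")
    print(f"  {args.n_regions} regions, raw depth {sim.depth_per_region} pairs/region")
    print(f"  true indel frequencies: {FREQS} (region index -> fraction)")


if __name__ == "__main__":
    main()
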