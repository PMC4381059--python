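#!/usr/bin/env python
"""Design capture baits over the candidate regions.

Each 200-bp region centered on a candidate site is tiled by three 100-bp
hybridization baits with a 50-bp walking step, covering the region exactly.
Writes results/bait_manifest.tsv and results/baits.fa.
"""

from pathlib import Path

from captor import io
from captor.baits import bait_fasta, bait_manifest, make_capture_regions

IN = Path("scratch/screen_inputs")
RESULTS = Path("results")


def main():
    genome = io.read_fasta(IN / "genome.fa")
    sites = io.read_bed(IN / "sites.bed")
    regions = make_capture_regions(sites, genome)
    RESULTS.mkdir(exist_ok=True)
    bait_manifest(regions).to_csv(RESULTS / "bait_manifest.tsv", sep="\t", index=False)
    io.write_fasta(bait_fasta(regions), RESULTS / "baits.fa")
    n = len(regions)
    print(f"{n} capture regions -> {3 * n} baits "
          f"(100 bp, offsets 0/50/100 within each region)")


if __name__ == "__main__":
    main()
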