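# Methods

`captor` implements a capture-based screen for CRISPR/Cas9 off-target
activity: candidate sites are found by sequence (a mismatch+PAM genome scan)
or taken from dCas9 ChIP peaks, 200-bp capture regions around them are tiled
with hybridization baits, and indels — the NHEJ signature of Cas9 cleavage —
are quantified per region from paired-end capture reads and tested for
enrichment over an untreated control. This note records the models,
conventions and numerical choices behind each stage, and what the synthetic
data do and do not establish.

## Off-target scanning

A target is a 20-nt protospacer followed by a 3-nt PAM (NGG for
*S. pyogenes* Cas9; NAG is supported as the weaker alternative). The scanner
enumerates every 23-bp window on both strands whose PAM 3-mer matches the
IUPAC pattern and whose 20-mer is within `max_mm` substitutions (default 4)
of the protospacer. Conventions:

* Coordinates are 0-based half-open over the 20-nt protospacer match,
  reported on the plus strand for both hit orientations (BED convention).
* Mismatch positions are numbered 1–20 with 20 PAM-adjacent, matching the
  seed-proximity vocabulary ("a mismatch 2 bp from the PAM" = position 19).
* Windows containing non-ACGT bases are skipped; the PAM N position must be
  a real base. Ambiguity codes never match, so assemblies with N-runs do
  not generate hits.
* No repeat masking is applied by default; a mask BED can be supplied and is
  subtracted from the hit set.
* Overlapping placements are all reported; region-level statistics use
  presence/absence.

The seed of a target is its PAM-proximal 12 nt, the core its PAM-proximal
5 nt (`seed_match` and `core_match` analyse peak sequences for degenerate
and exact matches respectively). On desk-scale genomes (≤50 kb) the scanner
is verified hit-for-hit against exhaustive window enumeration for all
`max_mm ≤ 6` and both PAM patterns.

## Peak statistics

Peak-set operations use the ≥1-shared-base overlap criterion throughout
(the bedtools default). "Common" peaks between two gRNA datasets are
materialized from the first set's coordinates; replicate intersection keeps
the first replicate's coordinates, so it is idempotent. PAM density of a
region is the count of NGG start positions on both strands (CCN on the plus
strand for the minus-strand count, overlaps allowed) within the central
100 bp, expressed as a percent of the window; the region center is
`floor((start+end)/2)`. For a random sequence with GC fraction g the
expected density is `~2·(g/2)²·100·(98/100)` percent — about 8.6% at mouse-like
g = 0.42, which the synthetic random-region median reproduces. Group
comparisons use Student's t-tests (equal variance) at alpha 1e-4 with a
greedy compact-letter assignment in order of decreasing mean: groups sharing
a letter are pairwise indistinguishable at alpha. Pairs where both samples
are constant are flagged and skipped.

## Bait design

Each candidate site becomes one 200-bp capture region centered on the site
midpoint (for a predicted site, the midpoint of the 23-bp protospacer+PAM;
for a peak, the peak midpoint — the two conventions can differ by tens of
bp for the same locus and are recorded per region). Regions are tiled by
three 100-bp baits at offsets 0/50/100, covering the region exactly with
50-bp pairwise overlap; baits are reported on the plus strand. Random
control regions are drawn uniformly over the eligible genome, disjoint and
avoiding an exclusion BED, by seeded rejection sampling.

## Capture read pipeline

1. **Filtering** — 3' bases below the quality threshold (default Q20) are
   trimmed, then leading/trailing Ns, then a configurable adapter suffix;
   a pair is dropped if either mate falls under 35 bp.
2. **Clonal removal** — library fragments are staggered by random shearing,
   so pairs with identical (chrom, start1, start2, orientation) keys are PCR
   duplicates; exactly one (the first encountered, stable order) is kept.
   Coordinates come from an external aligner (SAM) or, for synthetic runs,
   from the simulator's truth table.
3. **Assignment** — a pair is assigned to the capture region with the
   strictly longest exact anchor (longest common substring, either mate,
   either orientation); candidate regions are short-listed through a 12-mer
   index of the region references, which cannot change the winner because a
   region sharing no 12-mer has anchors shorter than 12. Ties leave the
   pair unassigned.
4. **Merging** — mate 2 is reverse complemented and the longest exact 3'/5'
   overlap ≥5 bp joins the pair into one fragment-length sequence; pairs
   without an exact overlap are classified as two separate reads. With
   100-bp reads and ~150-bp fragments, a 0.1% substitution rate fails the
   exact overlap in roughly 10% of pairs; those mates usually miss the
   100-bp span requirement below, which shrinks the denominator but does not
   bias the indel fraction.
5. **Classification** — the read's longest common substring against the
   200-nt region reference is the primary anchor (minimum 20 bp, both
   orientations tried, longer anchor wins). Each unanchored flank is then
   resolved by chained secondary anchors (repeated longest-common-substring
   of the remainder against the corresponding side of the reference) until
   the leftover is shorter than 10 bp; short leftovers are ignored so stray
   tail bases cannot fabricate indels. The implied reference span between
   the outer anchor endpoints must reach 100 bp. The net difference between
   read span and reference span sets the class: negative = deletion,
   positive = insertion; at net zero the whole read is compared at the
   implied placement and any mismatch makes it a SNP, else WT. The indel
   position is the midpoint of the widest inter-anchor gap, reported
   relative to the region center. The classifier is validated against a
   unit-cost dynamic-programming alignment oracle rather than trusted:
   error-free reads with indels ≥10 bp from the read ends agree 100%, reads
   with 0.1% substitution errors ≥99%.
6. **Summaries and significance** — per region,
   `indel% = 100·(insertions+deletions)/classified reads` (SNP reads stay in
   the denominator). Regions are excluded when classified coverage is below
   25 reads, when the reference contains a homopolymer run ≥5 nt (the
   stricter ≥6 variant is a flag away), or when the untreated control
   already shows >5% indels (strain/reference mismatch, a property of the
   cell line rather than treatment). Remaining regions get a one-sided
   Fisher's exact test (enrichment of indels in treated vs untreated) at
   alpha 0.01 on the 2×2 (indel, non-indel) × (treated, control) table; the
   reverse direction and Bonferroni/Benjamini–Hochberg corrections are
   available by flag but off by default (raw P values are reported with n
   noted).

### Known biases

The anchor classifier ignores unanchored read tails shorter than 10 bp, so
a mutant read whose indel sits within ~10 bp of a read end is scored WT.
With fragment starts uniform over the capture support this loses ~12% of
mutant reads, giving a systematic relative undercount of the true indel
fraction (e.g. ~13% observed for a 15% region). The recovery checks
therefore compare estimates to truth within 3 binomial standard errors, and
capture-based percentages should be read as conservative — consistent with
capture assays reporting lower indel frequencies than amplicon sequencing
of the same sites. Unmerged mates contribute two classified reads from one
fragment (≤5% of reads at default error rates), a mild pseudo-replication
in the Fisher counts.

## Synthetic data generator

The generator emulates the structure of a capture experiment so every stage
runs with known truth:

* **Genome** — i.i.d. bases at GC 0.42 (mouse-like); planted 23-mers
  (protospacer variants + concrete PAM, either strand) with recorded loci.
* **Fragments** — lengths Normal(150, 15) (sonication to ~150 bp); starts
  uniform over [region_start − fragment_length, region_end), emulating
  random shearing, so read pairs are staggered and clonal keys are
  informative.
* **Indels** — each fragment is mutant with the region's true frequency; a
  mutant fragment carries one indel whose left edge sits at the cut site,
  3 bp upstream (5', protospacer side) of the PAM on the PAM-bearing
  strand. Sizes are uniform on 1–5 bp with deletions:insertions 4:1
  (deletions predominate in NHEJ spectra; the exact ratio is configurable).
  Mutant fragments not covering the cut show no indel, as in a real
  library.
* **Reads** — paired-end (default 100+100) with per-base substitution
  errors (default 0.1%), constant Q40 qualities (an optional low-quality
  tail exercises trimming), and a `clonal_rate` fraction of pairs emitted
  as exact duplicates.
* **Determinism** — every draw flows from the single integer seed;
  identical configs give byte-identical FASTQ.

"Depth 300" for screen-level statements means ~300 *classifiable* reads per
region; `screen.raw_depth_for_coverage` converts that to raw pairs with an
analytic retention formula (geometric span fraction × merge survival, no
fitting) — about 770 raw pairs per region at the defaults. Screen loci are
sampled free of ≥5-nt homopolymer runs, mirroring an analysis set after
homopolymer exclusion; the homopolymer flag itself is unit-tested on
constructed references.

What the synthetic data do not model: capture-hybridization dropout of
large indels (capture favors small mismatches, another reason its
percentages are conservative), PCR chimeras, position-dependent quality
decay, real repeat structure and chromatin context. Passing tests therefore
establish the pipeline's correctness and calibration on idealized
libraries, not performance on real genomes.

## Statistical calibration

With 197 null regions at alpha 0.01 and error-only reads, substitution
errors cannot create indels, so false positives arise only from rare
classifier edge cases; the null screen calls zero to a handful of regions,
within the Binomial(197, 0.01) upper 99% bound of 7. Power for a 5% region
at ~300 classified reads per arm against a zero-indel control exceeds 0.99
(the exact-test threshold is ~7 indel reads against a mean of ~15).

## Problem sizes

The shipped analyses and checks use: 20-region screens for the worked
example, a 200-region screen (500-kb genome, ~770 raw pairs/region,
treated + control) for recovery/calibration, ten 50-kb genomes for scanner
oracle equivalence, and 1000 simulated reads per class for the classifier
oracle — sizes chosen to exercise every code path at full statistical
strength while keeping a complete run in minutes on one CPU.
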