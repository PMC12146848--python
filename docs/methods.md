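# Methods

`axispeaks` analyzes where meiotic chromosome-axis proteins — the
synaptonemal-complex lateral-element protein SYCP3 and the transverse-filament
protein SYCP1 — sit on chromatin, starting from called CUT&Tag peaks and
normalized signal tracks. This note records the models, conventions and
numerical choices behind each stage, what the synthetic scenarios emulate,
and what the tests do and do not establish about real data.

## Coordinates and interval algebra

All coordinates are 0-based, half-open (BED convention) everywhere inside the
package; readers convert dialects (e.g. the 1-based cytosine report) at the
boundary and reject out-of-bounds records instead of clamping. Peak width is
`end − start`; the peak center is the floor midpoint, with narrowPeak summit
offsets honored as a documented option where a profile needs an anchor.

Peaks closer than a threshold are combined: `merge_within(peaks, max_gap)`
bridges inter-peak gaps strictly below `max_gap` (default 1000 bp, the
"< 1 kb" convention) and always coalesces touching or overlapping intervals,
so the output equals painting covered bases on an array, bridging sub-threshold
gaps and reading off runs. The operation is idempotent, and the test suite
holds it (plus covered-base intersection and nearest-peak distances) to exact
agreement with per-base and all-pairs brute-force oracles, and to `bedtools
merge` as an external cross-check.

Nearest-peak distance defaults to the edge-to-edge gap (0 for overlapping or
book-ended peaks; undefined for a peak alone on its chromosome). Reported
inter-peak distances do not distinguish gap from center-to-center in all
published figures, so both are provided (`mode="gap"` default,
`mode="center"` optional).

Venn-style overlap partitioning is per-set: each peak is labeled with the
subset of other sets it overlaps by at least `min_overlap` bp (default 1).
Because overlaps can be many-to-many, counts from the two perspectives need
not be symmetric; the result object states this convention.

## Signal tracks

Coverage is built from fragment intervals at a fixed bin size (default
50 bp): a fragment spanning k bins increments all k bins, matching the
piecewise-coverage semantics of bedGraph rather than midpoint counting. RPKM
normalization divides each bin by (bin size / 1000) and (total fragments /
10⁶); it is invariant under uniform duplication of the library. Tracks read
from bedGraph are treated as already-normalized densities; the track records
which path produced it.

Region density is the length-weighted mean of bin values, with partial bins
weighted by the covered fraction; constant spans short-circuit to the
constant so ratios of uniform signal are exactly 1. Meta-profiles sample
center ± flank (default 2 kb) in profile bins (default 50 bp); columns
reaching past a chromosome edge are missing, and column means use finite
entries only, avoiding edge artifacts. Heatmap row order is descending row
mean with genomic position breaking ties. Genome-wide track correlation
(Spearman default, Pearson optional) rebins all tracks to a common bin
(default 10 kb, a standard genome-wide summary bin); bins at which every
track is zero can be dropped (`drop_all_zero`) — with sparse peak tracks the
common zero background otherwise dominates the rank correlation — and the
choice is recorded in output metadata.

## Occupancy statistics

**Occupancy ratio (OR).** For each gene, the promoter is TSS ± 1 kb and the
gene body runs from 1 kb downstream of the TSS (in the transcription
direction) to the TES; genes of span ≤ 1 kb have no body. OR is the mean
normalized density over the promoter divided by the mean over the body —
mean density, not summed counts, consistent with a read-density definition —
so it is invariant to positive rescaling of the track. OR is defined only
when both densities are positive (it is strictly positive by construction);
zero-density genes are reported ineligible with a reason, and an optional
pseudocount flag exists for sparse tracks rather than a silent default.
Condition comparisons pair genes eligible in both conditions and use the
Wilcoxon rank-sum test on the two OR distributions, with the median log2
shift as the effect summary.

**TE enrichment.** Per repeat family (or class):
`(bp of family inside peaks / total merged peak width) ÷ (bp of family
genome-wide / genome size)`, with 1 the no-enrichment reference. Family
intervals are merged before overlap so nested or overlapping annotation
records are not double-counted; genome size is the summed length of the
supplied chromosomes (restriction to peak-bearing chromosomes is an option).
The four raw quantities are retained for audit. Family-level signal is the
length-weighted mean density: Σ(transcript mean density × transcript length)
/ Σ(transcript length), each annotated repeat record counting as one
transcript.

**Methylome tiling.** CpG counts are destranded (symmetric strand pairs
summed at the plus-strand position; the operation is idempotent), sites with
coverage below `mincov` (default 3) are excluded, and remaining counts are
pooled into non-overlapping 1 kb windows (window = step, the only tiling
supported). Window level = pooled methylated / pooled total; classes are
hypo (< 25%), hyper (> 75%), intermediate otherwise — both thresholds are
strict, so levels of exactly 0.25 or 0.75 are intermediate. Occupancy per
class is log2(mean density + 1) per tile, compared hypo vs hyper by Wilcoxon
rank-sum.

**GC profile.** Mean GC in a 100 bp rolling window at every 10 bp offset
within ±2 kb of each peak center, averaged over peaks. N bases are excluded
from numerator and denominator; edge-truncated windows use the bases
available; an all-N window is missing. Implemented with cumulative base
counts, and tested against direct per-window counting.

**Spacing and periodicity.** Peak centers are binned (default 100 bp) per
chromosome; the observed statistic is the maximum excess, over lags up to
10 kb, of the pairwise center-distance histogram above its null mean, with a
permutation P value (seed mandatory). Two nulls are provided because they
answer different questions:

- `uniform` (default): interior centers re-placed uniformly between the first
  and last center — the distribution of a homogeneous Poisson process
  conditioned on count and extent. Exactly calibrated against random
  placement and sensitive to any regular lattice of centers.
- `shuffle_gaps`: re-orders consecutive inter-center gaps, conditioning on
  the spacing distribution and testing phase-locking only. A perfect lattice
  is invariant under this null (all gaps equal, P = 1), which is why it is
  not the default; but for called peak sets — which are non-overlapping by
  construction and therefore a hard-core point process — the uniform null
  correctly reports non-randomness even without any phase structure, so the
  gap-shuffling null is the right scenario-level question ("periodic beyond
  the spacing distribution?").

A period estimate (lag of maximal excess) is reported only when P < alpha.
Type-I error of the uniform null is held, in tests, to alpha + 2 binomial
standard errors over 100 seeded Poisson-placement replicates.

**Intensity groups.** Peaks scored by mean track density are split into
near-equal ordered groups (high/intermediate/low for 3); group sizes differ
by at most one with the remainder assigned to the strongest group, and ties
break by genomic position — any deterministic rule would do; this one is
documented and tested.

**Sex chromosomes.** Peaks are partitioned by compartment; the exact fraction
on sex chromosomes is reported (no rounding conventions), with per-peak mean
densities and a Wilcoxon rank-sum comparison when both compartments are
occupied.

## Site classification

Feature annotation is center-based with a fixed priority ladder — promoter
(TSS ± 1 kb) > 5'UTR > 3'UTR > exon > intron > downstream (≤ 3 kb past the
TES) > distal intergenic — the behavior of common annotators, made explicit
and testable. UTR calls require exon blocks plus a CDS span in the gene
model; without them exonic positions are labeled exon. Within a priority
level the gene with the nearest TSS wins. Gene models are ingested from a
documented TSV (gene id, chromosome, strand, span, optional exon blocks and
CDS) rather than full GTF parsing, since only TSS/TES/strand and optional
block structure are consumed.

Stage retention labels each peak of two stages specific or overlapping
(≥ `min_overlap` bp with ≥ 1 peak of the other stage); the headline retained
fraction is directional — overlapping early-stage peaks over early-stage
total — with the reverse direction reported alongside. The perturbation
split labels control peaks core (overlapping ≥ 1 post-perturbation peak) or
non-core; core and non-core partition the control set exactly. Genes whose
non-distal features carry at least one peak are exported for external
GO tooling.

## Synthetic scenarios

The generator emulates the statistical structure the analyses assume, with
every planted property recorded as ground truth; recovering those plants
within pre-registered tolerances is the module's reason to exist. All
randomness flows from one seed through named `SeedSequence` children, so a
given config is bit-reproducible and the stages are statistically
independent.

Default study conditions (chosen once, as the conditions the analyses
target): a 5.25 Mb genome (three 1.5 Mb autosomes plus a 0.75 Mb X) at
background GC 0.42 with GC boosted by +0.15 within 300 bp of peak centers;
400 non-overlapping genes of 2–10 kb with exon/CDS structure; four repeat
families (SINE-like families at 6% and 4% of the genome with planted peak
enrichment folds 5 and 3, LINE- and LTR-like families at folds 1); 1000
peaks with lognormal widths (median ≈ 400 bp); 40% of peaks placed in
promoters; stage-2 retention 0.70 and perturbation-core fraction 0.67
(the ~67% of occupied regions retained after 1,6-hexanediol treatment of
spermatocytes motivates both the statistic and the default); a mostly
methylated background (Beta(8,2)) with hypomethylated promoters
(probability 0.9, Beta(1,12)); per-CpG coverage Poisson(10) per strand so
the mincov filter is exercised; fragment sampling with a triangular offset
kernel (analytically checkable meta-profiles; Gaussian optional), ~40
fragments per peak over a uniform background, and a ×2 intensity multiplier
on the sex chromosome.

Placement details that make the plants recoverable rather than merely
planted:

- Peaks are mutually disjoint with a quarter-width safety margin. Stage-2
  and perturbed copies are jittered by ≤ 25% of width — guaranteed still to
  overlap their original but never an unrelated peak — so retention and core
  fractions are recovered to binomial accuracy instead of being inflated by
  chance collisions. De-novo stage-2 peaks are placed clear of every stage-1
  peak for the same reason. Widths in overfull regions shrink stepwise
  (to ≥ 200 bp) before the generator declares the genome full.
- A planted TE fold f for a family occupying genome fraction q is realized by
  placing each (non-promoter) peak fully inside that family's footprint with
  probability f·q, and background peaks fully outside all footprints. The
  bp-level enrichment statistic then equals f in expectation and exactly 1
  for unenriched families; a center-weighted scheme would be diluted by
  partial overlaps. Feasibility requires Σ f·q ≤ 1, validated up front.
  Planted folds are folds among non-promoter peaks; recovery tests use a
  promoter fraction of 0.
- The elongation-block condition multiplies gene-body fragment intensity by a
  configured factor (default 0.5) while preserving promoter intensity, so the
  expected OR doubles and the Wilcoxon comparison has a known direction.

What the scenarios do **not** emulate: sequence-realistic repeats (no actual
consensus sequences), read-level artifacts (no FASTQ, PCR duplicates,
mappability), irregular chromatin domains, or genome-scale sizes. Passing
tests therefore establishes that the statistics recover what they claim from
data with this covariance structure at desk scale — not that any biological
conclusion holds in a real genome.

## Problem sizes

The test and acceptance workloads use desk-scale problems chosen to make the
statistical checks sharp: 200 random instances for the exact interval-algebra
oracles; 20 replicates of 1000 peaks on a 10 Mb genome for TE calibration
(null within [0.9, 1.1], fold-5 recovery within 15%); 2000 peaks for
retention/core recovery within the binomial 95% CI; 200 genes for the OR
shift; 100 Poisson replicates for periodicity type-I calibration. The full
suite runs in well under a minute of CPU apart from the calibration loops.

## Known limitations

- Sorted-sweep algorithms are correctness-first; no interval trees, so
  whole-genome peak sets (10⁵–10⁶ intervals) are workable but not fast.
- Only non-overlapping methylome tiling (window = step) is implemented.
- The scale-regions (gene-body-stretched) profile mode is not provided; only
  reference-point profiles around centers.
- `overlap_classify` supports 2- or 3-way partitions, matching its use;
  larger Venn partitions are out of scope.
- Printed fractions in published reports sometimes disagree with their own
  count parentheticals; this package always reports exact fractions and does
  not attempt to reproduce rounding conventions.
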