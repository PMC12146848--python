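# axispeaks

Downstream occupancy analysis for CUT&Tag data of meiotic chromosome-axis
proteins — the synaptonemal-complex lateral-element protein SYCP3 and the
transverse-filament protein SYCP1 — in mouse spermatocytes, rebuilt as a
tested, reusable pipeline with a seeded synthetic-data generator so every
stage is verifiable without downloading the original sequencing data.

It is written for genomicists asking where an axis protein sits on meiotic
chromatin and how that occupancy responds to stage progression (leptotene →
pachytene), transcription inhibition (α-amanitin-like), or dissolution of
protein assemblies (1,6-hexanediol-like): which peaks survive, how promoter
versus gene-body signal shifts, which repeat families are enriched, and how
occupancy tracks DNA methylation, GC content and the sex chromosomes.

## Statistics implemented

- **Interval algebra** (0-based, half-open): validation, gap-bridging merge
  (peaks < 1 kb apart combined), covered-base intersection, 2/3-way Venn
  partitioning, nearest-peak distances, width summaries — all held to exact
  agreement with per-base brute-force oracles.
- **Occupancy ratio (OR)** per gene: mean normalized read density at the
  promoter (TSS ± 1 kb) over the gene body (TSS + 1 kb → TES), with paired
  condition comparison by Wilcoxon rank-sum:

  OR = density(TSS ± 1 kb) / density(TSS + 1 kb … TES)

- **TE enrichment** per repeat family/class:
  (family bp in peaks / total peak bp) ÷ (family bp genome-wide / genome
  size), 1 = no enrichment; plus length-weighted family signal.
- **Methylome tiling** (1 kb windows, mincov 3, destranded): hypo (< 25%),
  intermediate, hyper (> 75%) classes and the occupancy contrast between
  them.
- **Profiles**: RPKM coverage from fragments, meta-profiles around peak
  centers (± 2 kb), rolling-window GC profiles, genome-wide Spearman/Pearson
  track correlation.
- **Peak taxonomies**: center-based feature annotation (promoter > 5'UTR >
  3'UTR > exon > intron > downstream > distal), stage retention, core /
  non-core classification under a perturbation, intensity tertiles,
  sex-chromosome versus autosome comparison.
- **Spacing periodicity**: permutation test on the binned peak-center
  pair-distance spectrum, with an exactly calibrated uniform null and a
  gap-shuffling null (see `docs/methods.md`).
- **Synthetic scenarios** (`axispeaks.simulate`): seeded generator of a
  GC-heterogeneous genome, gene models, repeat families with planted
  enrichment folds, promoter-hypomethylated methylomes, two-stage peak
  retention, a perturbation core split and fragment-sampled coverage — with
  ground truth recorded for every plant.

## Worked example

Generate a scenario and run the analyses (numbered drivers under
`analysis/`, all computation in the library):

```bash
python analysis/01_simulate_scenario.py --seed 1
python analysis/02_peak_landscape.py   --seed 1
python analysis/03_occupancy_ratio.py  --seed 1
python analysis/04_te_and_methylation.py
python analysis/05_site_classes.py
```

which prints (seed 1):

```
GC at peak centers 0.568 vs flanks 0.435 (uplift +0.133)
intensity tertiles: {'high': 334, 'intermediate': 333, 'low': 333}
median width 406 bp, median nearest gap 1222 bp
periodicity [uniform null]: p=0.066, period=None
periodicity [shuffle_gaps null]: p=0.447, period=None
median OR before 1.96, after 3.91 (body signal x0.5)
median log2 OR shift +0.994 (up), Wilcoxon rank-sum P = 7.93e-62 over 200 genes
TE enrichment (1 = none): {'AluY': 3.27, 'DeuX': 2.45, 'ERVK': 1.07, 'L1Md': 0.85}
methylation tiles: {'hypo': 540, 'intermediate': 593, 'hyper': 4117}
occupancy log2 medians hypo 11.54 vs hyper 0.00, Wilcoxon P = 1.95e-128
stage retention: 68.9% of 1000 stage-1 peaks persist at stage 2
core/non-core: 65.6% core (656/1000); median widths 406 vs 400 bp
sex chromosomes: 149/1000 peaks (14.90%), median intensity ratio 2.01, Wilcoxon P = 1.49e-58
```

Reading these numbers: peak centers show elevated GC over flanking sequence;
halving gene-body signal while preserving promoters doubles the median OR
(log2 shift ≈ +1) with an overwhelming rank-sum P, the expected signature of
an elongation block; the planted SINE-family biases surface as enrichment
folds diluted by the 40% of peaks placed in promoters (fold-recovery tests
use a promoter fraction of 0 and recover 5×); hypomethylated tiles carry far
higher occupancy than hypermethylated ones; the planted 70% retention and
67% core fractions are recovered to binomial accuracy; and the planted ×2
sex-chromosome intensity boost appears as a median intensity ratio ≈ 2.

The same stages are available as a CLI over files
(`axispeaks simulate|analyze|report`), e.g.:

```bash
axispeaks simulate --seed 1 --outdir scenario/
axispeaks analyze --stages retention,core \
    --peaks scenario/peaks_control.bed --peaks2 scenario/peaks_stage2.bed \
    --perturbed scenario/peaks_perturbed.bed \
    --sizes scenario/chrom.sizes --outdir analysis/
axispeaks report analysis/
```

All outputs are plain TSV/BED/JSON with a manifest (config, seeds, digests)
for reproducibility; seeds are required, never defaulted silently.

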