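"""Occupancy statistics for axis-protein CUT&Tag data.

Implements the study's bespoke measures: the promoter/gene-body occupancy
ratio (OR), transposable-element enrichment and family-level signal,
methylome tiling with hypo/intermediate/hyper classification, GC
meta-profiles around peak centers, inter-peak spacing with a permutation
test for periodicity, intensity tertiles, and the sex-chromosome versus
autosome comparison.  Group comparisons use the Wilcoxon rank-sum test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .genome_io import (
    CpGSiteTable,
    GeneModel,
    GenomeSequence,
    RepeatAnnotation,
)
from .intervals import (
    ChromSizes,
    GenomicInterval,
    PeakSet,
    closest_distance,
    intersect_length,
    merge_within,
)
from .tracks import CoverageTrack, region_mean_density

__all__ = [
    "ORResult",
    "TEEnrichment",
    "MethylationTile",
    "SpacingAnalysis",
    "occupancy_ratio",
    "compare_or",
    "te_enrichment",
    "te_family_signal",
    "tile_methylome",
    "occupancy_by_methylation",
    "gc_profile",
    "spacing_periodicity",
    "group_by_intensity",
    "sex_autosome_comparison",
]

HYPO_THRESHOLD = 0.25   # methylation level strictly below -> hypomethylated
HYPER_THRESHOLD = 0.75  # strictly above -> hypermethylated


# ---------------------------------------------------------------------------
# occupancy ratio (OR)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ORResult:
    """Promoter/gene-body occupancy ratio for one gene.

    OR = mean normalized density over the promoter (TSS +/- 1 kb) divided by
    mean density over the gene body (1 kb downstream of the TSS to the TES).
    Ineligible genes (body absent, or either density 0 without pseudocount —
    OR is strictly positive when defined) carry ``or_value`` None and a reason.
    """

    gene_id: str
    promoter_density: float
    body_density: float | None
    or_value: float | None
    eligible: bool
    reason: str | None = None


def occupancy_ratio(track: CoverageTrack, genes: Sequence[GeneModel],
                    pseudocount: float = 0.0) -> list[ORResult]:
    """Per-gene OR from a normalized track.

    ``pseudocount`` (off by default) is added to both densities for sparse
    tracks; with it, zero-body genes become eligible.
    """
    if not genes:
        raise ValueError("occupancy_ratio needs at least one gene")
    results = []
    for g in genes:
        if g.chrom not in track.sizes:
            results.append(ORResult(g.gene_id, np.nan, None, None, False, "unknown chromosome"))
            continue
        prom = g.promoter(track.sizes)
        body = g.body()
        p = region_mean_density(track, prom) + pseudocount
        if body is None:
            results.append(ORResult(g.gene_id, p, None, None, False, "gene length <= 1 kb"))
            continue
        b = region_mean_density(track, body) + pseudocount
        if b <= 0:
            results.append(ORResult(g.gene_id, p, b, None, False, "zero body density"))
            continue
        if p <= 0:  # OR is strictly positive when defined
            results.append(ORResult(g.gene_id, p, b, None, False,
                                    "zero promoter density"))
            continue
        results.append(ORResult(g.gene_id, p, b, p / b, True))
    return results


def or_table(results: Sequence[ORResult]) -> pd.DataFrame:
    return pd.DataFrame([{
        "gene_id": r.gene_id, "promoter_density": r.promoter_density,
        "body_density": r.body_density, "or_value": r.or_value,
        "eligible": r.eligible, "reason": r.reason,
    } for r in results])


def median_or(results: Sequence[ORResult]) -> float:
    vals = [r.or_value for r in results if r.eligible]
    if not vals:
        raise ValueError("no eligible genes")
    return float(np.median(vals))


def compare_or(before: Sequence[ORResult], after: Sequence[ORResult]) -> dict:
    """Shift of OR between two conditions, paired on gene_id.

    Returns per-gene pairs, the median log2 shift, and the Wilcoxon rank-sum
    P value comparing the two OR distributions (genes eligible in both).
    """
    b = {r.gene_id: r.or_value for r in before if r.eligible}
    a = {r.gene_id: r.or_value for r in after if r.eligible}
    shared = sorted(set(b) & set(a))
    if len(shared) < 2:
        raise ValueError("fewer than 2 genes eligible in both conditions")
    ors_b = np.array([b[g] for g in shared])
    ors_a = np.array([a[g] for g in shared])
    stat, p = stats.ranksums(ors_a, ors_b)
    log2_shift = np.log2(ors_a) - np.log2(ors_b)
    return {
        "genes": shared,
        "or_before": ors_b,
        "or_after": ors_a,
        "median_log2_shift": float(np.median(np.log2(ors_a)) - np.median(np.log2(ors_b))),
        "median_paired_log2_shift": float(np.median(log2_shift)),
        "direction": "up" if np.median(log2_shift) > 0 else
                     ("down" if np.median(log2_shift) < 0 else "none"),
        "statistic": float(stat),
        "p_value": float(p),
        "n": len(shared),
    }


# ---------------------------------------------------------------------------
# transposable elements
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TEEnrichment:
    """Peak enrichment of one repeat group.

    enrichment = (bp_in_peaks / total_peak_width) / (bp_in_genome / genome_size);
    1 is the no-enrichment reference.  Undefined (None) when the group is
    absent from the genome.
    """

    group: str
    bp_in_peaks: int
    total_peak_width: int
    bp_in_genome: int
    genome_size: int
    enrichment: float | None


def te_enrichment(peaks: PeakSet, repeats: RepeatAnnotation, sizes: ChromSizes,
                  level: str = "family") -> dict[str, TEEnrichment]:
    """TE enrichment per family or class.

    Within-group repeat intervals are merged before overlap so nested or
    overlapping annotation records are not double counted; peaks are merged
    the same way and total peak width is the merged width.  Genome size is
    the summed length of the supplied chromosomes.
    """
    if level not in ("family", "class"):
        raise ValueError(f"unknown level {level!r}")
    if len(peaks) == 0:
        raise ValueError("te_enrichment of an empty PeakSet")
    merged_peaks = merge_within(peaks.sorted(), 0)
    total_peak_width = merged_peaks.total_width()
    genome_size = sizes.genome_size
    groups = repeats.families if level == "family" else repeats.classes
    out: dict[str, TEEnrichment] = {}
    for group in groups:
        footprint = (repeats.family_footprint(group) if level == "family"
                     else repeats.class_footprint(group))
        bp_in_genome = footprint.total_width()
        bp_in_peaks = intersect_length(merged_peaks, footprint)
        if bp_in_genome == 0 or total_peak_width == 0:
            enr = None
        else:
            enr = (bp_in_peaks / total_peak_width) / (bp_in_genome / genome_size)
        out[group] = TEEnrichment(group, bp_in_peaks, total_peak_width,
                                  bp_in_genome, genome_size, enr)
    return out


def te_family_signal(track: CoverageTrack, repeats: RepeatAnnotation) -> dict[str, float]:
    """Length-weighted mean density per TE family.

    Per annotated transcript: mean track density times transcript length;
    summed within a family and divided by the family's total transcript
    length.  Families of total length 0 are excluded.
    """
    if len(repeats) == 0:
        raise ValueError("te_family_signal needs a non-empty repeat annotation")
    out: dict[str, float] = {}
    for family in repeats.families:
        ivs = repeats.intervals(family=family)
        total_len = 0
        total_counts = 0.0
        for iv in ivs:
            if iv.chrom not in track.sizes:
                continue
            d = region_mean_density(track, iv)
            total_counts += d * iv.width
            total_len += iv.width
        if total_len > 0:
            out[family] = total_counts / total_len
    return out


# ---------------------------------------------------------------------------
# methylome tiling
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MethylationTile:
    """A fixed genomic window with pooled CpG counts and a methylation class.

    level = summed methylated / summed total over qualifying sites;
    class: hypo if level < 0.25, hyper if level > 0.75, else intermediate
    (both boundaries fall in intermediate).
    """

    window: GenomicInterval
    n_sites: int
    meth_count: int
    total_count: int

    @property
    def level(self) -> float:
        return self.meth_count / self.total_count

    @property
    def klass(self) -> str:
        if self.level < HYPO_THRESHOLD:
            return "hypo"
        if self.level > HYPER_THRESHOLD:
            return "hyper"
        return "intermediate"


def tile_methylome(cpgs: CpGSiteTable, sizes: ChromSizes, win: int = 1000,
                   step: int = 1000, mincov: int = 3) -> list[MethylationTile]:
    """Tile pooled CpG methylation into fixed windows (methylKit-style).

    Sites with total coverage below ``mincov`` are excluded before pooling;
    windows with no qualifying site are omitted.  Only non-overlapping tiling
    (win == step) is supported.
    """
    if win != step:
        raise ValueError("only non-overlapping tiling (win == step) is supported")
    if not cpgs.destranded:
        warnings.warn("tiling a non-destranded CpG table; symmetric CpGs count twice")
    t = cpgs.table
    t = t[t["total"] >= mincov]
    tiles: list[MethylationTile] = []
    if len(t) == 0:
        return tiles
    t = t.assign(window=t["pos"] // win)
    grouped = t.groupby(["chrom", "window"], sort=True).agg(
        n_sites=("pos", "size"), meth=("meth", "sum"), total=("total", "sum"))
    for (chrom, widx), row in grouped.iterrows():
        if chrom not in sizes:
            raise ValueError(f"CpG site on unknown chromosome {chrom!r}")
        lo = int(widx) * win
        hi = min(lo + win, sizes[chrom])
        tiles.append(MethylationTile(
            GenomicInterval(str(chrom), lo, hi),
            n_sites=int(row["n_sites"]), meth_count=int(row["meth"]),
            total_count=int(row["total"])))
    return tiles


def methylation_tile_table(tiles: Sequence[MethylationTile]) -> pd.DataFrame:
    return pd.DataFrame([{
        "chrom": t.window.chrom, "start": t.window.start, "end": t.window.end,
        "n_sites": t.n_sites, "meth": t.meth_count, "total": t.total_count,
        "level": t.level, "class": t.klass,
    } for t in tiles])


def occupancy_by_methylation(track: CoverageTrack, tiles: Sequence[MethylationTile],
                             classes: tuple[str, str] = ("hypo", "hyper")) -> dict:
    """Track occupancy across methylation classes.

    Per tile: log2(mean normalized density + 1).  The two ``classes``
    (hypo vs hyper by default) are compared by the Wilcoxon rank-sum test.
    """
    values: dict[str, list[float]] = {"hypo": [], "intermediate": [], "hyper": []}
    for t in tiles:
        if t.window.chrom not in track.sizes:
            continue
        d = region_mean_density(track, t.window)
        values[t.klass].append(float(np.log2(d + 1.0)))
    a, b = classes
    if not values[a] or not values[b]:
        raise ValueError(f"no tiles in class {a if not values[a] else b!r}")
    stat, p = stats.ranksums(values[a], values[b])
    return {
        "log2_density": {k: np.array(v) for k, v in values.items()},
        "medians": {k: (float(np.median(v)) if v else np.nan) for k, v in values.items()},
        "compared": classes,
        "statistic": float(stat),
        "p_value": float(p),
    }


# ---------------------------------------------------------------------------
# GC meta-profile
# ---------------------------------------------------------------------------

def gc_profile(genome: GenomeSequence, peaks: PeakSet, flank: int = 2000,
               window: int = 100, step: int = 10) -> pd.DataFrame:
    """Mean GC around peak centers with a rolling window.

    For each offset in [-flank, +flank] (every ``step`` bp) the GC fraction
    of the ``window``-bp window centered there is computed per peak over
    non-N bases and averaged over peaks.  Edge-truncated windows use the
    available bases; windows with no informative base are missing.
    Returns a frame with columns offset, mean_gc, n_peaks.
    """
    if len(peaks) == 0:
        raise ValueError("gc_profile of an empty PeakSet")
    if window <= 0 or step <= 0 or flank <= 0:
        raise ValueError("flank, window and step must be positive")
    gc_arrays = genome.gc_arrays()
    cums: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom, (is_gc, is_known) in gc_arrays.items():
        cums[chrom] = (np.concatenate([[0], np.cumsum(is_gc, dtype=np.int64)]),
                       np.concatenate([[0], np.cumsum(is_known, dtype=np.int64)]))
    offsets = np.arange(-flank, flank + 1, step)
    half = window // 2
    gc_sum = np.zeros(len(offsets))
    n_obs = np.zeros(len(offsets), dtype=int)
    sizes = genome.sizes
    for iv in peaks.intervals:
        if iv.chrom not in cums:
            raise ValueError(f"peak on chromosome {iv.chrom!r} absent from the genome")
        if iv.end > sizes[iv.chrom]:
            raise ValueError(f"peak {iv.chrom}:{iv.start}-{iv.end} out of sequence bounds")
        gc_cum, known_cum = cums[iv.chrom]
        length = sizes[iv.chrom]
        centers = iv.center + offsets
        lo = np.clip(centers - half, 0, length)
        hi = np.clip(centers - half + window, 0, length)
        gc = gc_cum[hi] - gc_cum[lo]
        known = known_cum[hi] - known_cum[lo]
        ok = known > 0
        gc_sum[ok] += gc[ok] / known[ok]
        n_obs[ok] += 1
    with np.errstate(invalid="ignore"):
        mean_gc = np.where(n_obs > 0, gc_sum / np.maximum(n_obs, 1), np.nan)
    return pd.DataFrame({"offset": offsets, "mean_gc": mean_gc, "n_peaks": n_obs})


# ---------------------------------------------------------------------------
# spacing and periodicity
# ---------------------------------------------------------------------------

@dataclass
class SpacingAnalysis:
    """Inter-peak spacing distribution and a permutation test for periodicity.

    The test statistic is the maximal excess, over lags 1..max_lag, of the
    pair-distance histogram of binned peak centers above its permutation-null
    mean; the null shuffles the order of consecutive center-to-center gaps on
    each chromosome (preserving the gap multiset).  A period estimate is
    reported only when the permutation P value is below alpha.
    """

    distances: np.ndarray          # nearest-neighbor gaps (bp), NaN where undefined
    bin: int
    lags: np.ndarray               # lag centers in bp (1..max_lag)
    autocorr: np.ndarray           # observed pair-count per lag
    null_mean: np.ndarray          # permutation mean per lag
    periodicity_stat: float
    p_value: float
    period_estimate: int | None
    n_perm: int
    alpha: float

    def histogram(self, bins: int = 50) -> tuple[np.ndarray, np.ndarray]:
        d = self.distances[np.isfinite(self.distances)]
        return np.histogram(d, bins=bins)


def _pair_lag_counts(center_bins: np.ndarray, max_lag_bins: int) -> np.ndarray:
    """Counts of pairwise bin differences in 1..max_lag_bins (sorted input)."""
    counts = np.zeros(max_lag_bins, dtype=np.int64)
    if len(center_bins) < 2:
        return counts
    d = center_bins[None, :] - center_bins[:, None]
    d = d[d > 0]
    d = d[d <= max_lag_bins]
    if len(d):
        counts += np.bincount(d, minlength=max_lag_bins + 1)[1:]
    return counts


def spacing_periodicity(peaks: PeakSet, bin: int = 100, max_lag: int = 10_000,
                        n_perm: int = 1000, alpha: float = 0.05,
                        seed: int | None = None, min_peaks: int = 10,
                        null: str = "uniform") -> SpacingAnalysis:
    """Nearest-neighbor spacing plus an autocorrelation periodicity test.

    Peak centers are binned at ``bin`` bp per chromosome; the observed
    statistic is max over lags of (pair count - null mean).  Two nulls:

    ``uniform`` (default): interior centers are re-placed uniformly between
    the first and last center of each chromosome — the distribution of a
    homogeneous Poisson process conditioned on peak count and extent, so the
    test is exactly calibrated against random placement and any regular
    lattice of centers is detected.

    ``shuffle_gaps``: re-orders the consecutive inter-center gaps.  This
    preserves the gap multiset, but a lattice whose gaps are all equal is
    invariant under it and therefore undetectable; it is kept as a
    sensitivity check for phase-locking beyond the gap distribution.
    """
    if seed is None:
        raise ValueError("spacing_periodicity requires an explicit seed")
    if max_lag % bin:
        raise ValueError("max_lag must be a multiple of bin")
    if null not in ("uniform", "shuffle_gaps"):
        raise ValueError(f"unknown null {null!r}")
    by_chrom = peaks.sorted().by_chrom()
    analyzed = {c: ivs for c, ivs in by_chrom.items() if len(ivs) >= min_peaks}
    if not analyzed:
        raise ValueError(f"no chromosome has >= {min_peaks} peaks")
    distances = np.array(closest_distance(peaks.sorted()))
    rng = np.random.default_rng(seed)
    max_lag_bins = max_lag // bin

    chrom_centers = []
    for chrom, ivs in analyzed.items():
        chrom_centers.append(np.sort(np.array([iv.center for iv in ivs], dtype=np.int64)))
    observed = np.zeros(max_lag_bins, dtype=np.int64)
    for centers in chrom_centers:
        observed += _pair_lag_counts(centers // bin, max_lag_bins)

    null_counts = np.zeros((n_perm, max_lag_bins), dtype=np.int64)
    for k in range(n_perm):
        for centers in chrom_centers:
            lo, hi = centers[0], centers[-1]
            if null == "uniform":
                interior = np.sort(rng.integers(lo, hi + 1, size=len(centers) - 2))
                sim = np.concatenate([[lo], interior, [hi]])
            else:
                gaps = np.diff(centers)
                sim = lo + np.concatenate([[0], np.cumsum(rng.permutation(gaps))])
            null_counts[k] += _pair_lag_counts(sim // bin, max_lag_bins)

    null_mean = null_counts.mean(axis=0)
    obs_excess = observed - null_mean
    stat = float(obs_excess.max())
    null_stats = (null_counts - null_mean).max(axis=1)
    p = float((1 + np.sum(null_stats >= stat)) / (n_perm + 1))
    period = int((int(np.argmax(obs_excess)) + 1) * bin) if p < alpha else None
    return SpacingAnalysis(
        distances=distances, bin=bin,
        lags=(np.arange(1, max_lag_bins + 1) * bin),
        autocorr=observed.astype(float), null_mean=null_mean,
        periodicity_stat=stat, p_value=p, period_estimate=period,
        n_perm=n_perm, alpha=alpha)


# ---------------------------------------------------------------------------
# intensity grouping and compartments
# ---------------------------------------------------------------------------

def score_peaks(track: CoverageTrack, peaks: PeakSet) -> PeakSet:
    """Attach the mean track density over each peak as its score."""
    scored = [
        GenomicInterval(iv.chrom, iv.start, iv.end, name=iv.name,
                        score=region_mean_density(track, iv), strand=iv.strand)
        for iv in peaks.intervals
    ]
    return PeakSet(peaks.label, scored, peaks.sorted_flag, dict(peaks.metadata))


def group_by_intensity(peaks: PeakSet, n_groups: int = 3) -> dict[str, PeakSet]:
    """Score-ordered partition into near-equal groups (remainder to the top).

    For ``n_groups=3`` the labels are high / intermediate / low; otherwise
    group1..groupN from strongest to weakest.  Ties are broken by genomic
    position so the partition is deterministic.
    """
    if n_groups < 2:
        raise ValueError("n_groups must be >= 2")
    if len(peaks) < n_groups:
        raise ValueError(f"cannot split {len(peaks)} peaks into {n_groups} groups")
    if any(iv.score is None for iv in peaks.intervals):
        raise ValueError("all peaks must be scored (see score_peaks)")
    order = sorted(peaks.intervals, key=lambda iv: (-iv.score,) + iv.sort_key())
    n = len(order)
    base, rem = divmod(n, n_groups)
    sizes = [base + 1 if i < rem else base for i in range(n_groups)]
    names = (["high", "intermediate", "low"] if n_groups == 3
             else [f"group{i + 1}" for i in range(n_groups)])
    out: dict[str, PeakSet] = {}
    at = 0
    for name, size in zip(names, sizes):
        out[name] = PeakSet(f"{peaks.label}:{name}", order[at: at + size]).sorted()
        at += size
    return out


def sex_autosome_comparison(track: CoverageTrack, peaks: PeakSet,
                            sex_chroms: Sequence[str]) -> dict:
    """Partition peaks by compartment and compare occupancy.

    Returns counts, the exact fraction of peaks on sex chromosomes, per-peak
    mean densities per compartment, and a Wilcoxon rank-sum comparison (sex
    vs autosome); when a compartment is empty the comparison is skipped with
    a warning.
    """
    missing = [c for c in sex_chroms if c not in track.sizes]
    if missing:
        raise ValueError(f"sex chromosomes absent from the genome: {missing}")
    sex_set = set(sex_chroms)
    sex_d, auto_d = [], []
    for iv in peaks.intervals:
        d = region_mean_density(track, iv)
        (sex_d if iv.chrom in sex_set else auto_d).append(d)
    n_sex, n_auto = len(sex_d), len(auto_d)
    out = {
        "n_sex": n_sex,
        "n_autosome": n_auto,
        "n_total": n_sex + n_auto,
        "sex_fraction": n_sex / (n_sex + n_auto) if (n_sex + n_auto) else np.nan,
        "sex_density": np.array(sex_d),
        "autosome_density": np.array(auto_d),
        "median_sex": float(np.median(sex_d)) if sex_d else np.nan,
        "median_autosome": float(np.median(auto_d)) if auto_d else np.nan,
        "statistic": np.nan,
        "p_value": np.nan,
    }
    if not sex_d or not auto_d:
        warnings.warn("a compartment has no peaks; intensity comparison skipped")
        return out
    stat, p = stats.ranksums(sex_d, auto_d)
    out["statistic"], out["p_value"] = float(stat), float(p)
    return out
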