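"""Binned coverage tracks: building, RPKM normalization, meta-profiles and
genome-wide correlation.

These are native implementations of the deepTools-style computations
(bamCoverage / computeMatrix / multiBigwigSummary + plotCorrelation) used for
occupancy profiling: a fragment overlapping k bins increments k bins, RPKM is
value / (bin kb) / (fragments per million), and meta-profiles sample a fixed
window around each peak center.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .intervals import ChromSizes, GenomicInterval, PeakSet

__all__ = [
    "CoverageTrack",
    "MetaProfile",
    "coverage_from_fragments",
    "rpkm_normalize",
    "region_mean_density",
    "meta_profile",
    "track_correlation",
]


@dataclass
class CoverageTrack:
    """Per-chromosome binned signal with a recorded normalization state."""

    sizes: ChromSizes
    bin_size: int
    values: dict[str, np.ndarray]
    normalization: str = "raw"  # raw | rpkm
    total_fragments: int | None = None
    source: str = "unknown"  # fragments | bedgraph | synthetic | derived

    def __post_init__(self) -> None:
        if self.bin_size <= 0:
            raise ValueError("bin_size must be positive")
        for chrom, length in self.sizes.items():
            n_bins = -(-length // self.bin_size)
            v = self.values.get(chrom)
            if v is None or len(v) != n_bins:
                raise ValueError(f"{chrom}: expected {n_bins} bins, got "
                                 f"{'none' if v is None else len(v)}")
            if not np.all(np.isfinite(v)) or np.any(v < 0):
                raise ValueError(f"{chrom}: track values must be finite and >= 0")

    def n_bins(self, chrom: str) -> int:
        return len(self.values[chrom])

    def value_at(self, chrom: str, pos: int) -> float:
        return float(self.values[chrom][pos // self.bin_size])

    def scaled(self, factor: float) -> "CoverageTrack":
        return replace(self, values={c: v * factor for c, v in self.values.items()})

    def rebin(self, bin_size: int) -> "CoverageTrack":
        """Aggregate to a coarser bin (length-weighted mean); ``bin_size``
        must be a multiple of the current bin size."""
        if bin_size == self.bin_size:
            return self
        if bin_size % self.bin_size:
            raise ValueError("target bin_size must be a multiple of the current bin size")
        k = bin_size // self.bin_size
        out = {}
        for chrom, v in self.values.items():
            length = self.sizes[chrom]
            n_out = -(-length // bin_size)
            padded = np.zeros(n_out * k)
            padded[: len(v)] = v
            # weight by bases actually inside the chromosome per fine bin
            weights = np.full(n_out * k, float(self.bin_size))
            covered = np.minimum(
                np.maximum(length - np.arange(n_out * k) * self.bin_size, 0), self.bin_size
            )
            weights = covered.astype(float)
            w = weights.reshape(n_out, k)
            x = padded.reshape(n_out, k)
            with np.errstate(invalid="ignore"):
                out[chrom] = np.where(w.sum(axis=1) > 0,
                                      (x * w).sum(axis=1) / np.maximum(w.sum(axis=1), 1e-300),
                                      0.0)
        return replace(self, bin_size=bin_size, values=out)

    def genome_vector(self) -> np.ndarray:
        return np.concatenate([self.values[c] for c in self.sizes])


def coverage_from_fragments(fragments: Sequence[GenomicInterval] | PeakSet,
                            sizes: ChromSizes, bin_size: int = 50) -> CoverageTrack:
    """Raw binned coverage: each bin counts the fragments overlapping it.

    A fragment spanning k bins increments all k bins (piecewise coverage
    semantics, not midpoint counting).
    """
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    ivs = fragments.intervals if isinstance(fragments, PeakSet) else list(fragments)
    diffs = {c: np.zeros(-(-length // bin_size) + 1) for c, length in sizes.items()}
    for iv in ivs:
        if iv.chrom not in sizes:
            raise ValueError(f"fragment on unknown chromosome {iv.chrom!r}")
        if iv.end > sizes[iv.chrom]:
            raise ValueError(f"fragment {iv.chrom}:{iv.start}-{iv.end} out of bounds")
        first = iv.start // bin_size
        last = (iv.end - 1) // bin_size
        diffs[iv.chrom][first] += 1
        diffs[iv.chrom][last + 1] -= 1
    values = {c: np.cumsum(d[:-1]) for c, d in diffs.items()}
    return CoverageTrack(sizes=sizes, bin_size=bin_size, values=values,
                         normalization="raw", total_fragments=len(ivs),
                         source="fragments")


def rpkm_normalize(track: CoverageTrack) -> CoverageTrack:
    """Reads per kilobase per million: v / (bin_size/1000) / (total/1e6)."""
    if track.normalization == "rpkm":
        return track
    if not track.total_fragments:
        raise ValueError("RPKM requires a raw track with total_fragments > 0")
    factor = 1.0 / (track.bin_size / 1000.0) / (track.total_fragments / 1e6)
    values = {c: v * factor for c, v in track.values.items()}
    return replace(track, values=values, normalization="rpkm")


def region_mean_density(track: CoverageTrack, region: GenomicInterval) -> float:
    """Length-weighted mean of bin values over a region; partial bins are
    weighted by the covered fraction."""
    if region.width <= 0:
        raise ValueError("zero-width region")
    if region.chrom not in track.sizes:
        raise ValueError(f"region on unknown chromosome {region.chrom!r}")
    if region.start < 0 or region.end > track.sizes[region.chrom]:
        raise ValueError(f"region {region.chrom}:{region.start}-{region.end} out of bounds")
    return _span_mean(track, region.chrom, region.start, region.end)


def _span_mean(track: CoverageTrack, chrom: str, start: int, end: int) -> float:
    b = track.bin_size
    v = track.values[chrom]
    first, last = start // b, (end - 1) // b
    if first == last:
        return float(v[first])
    span = v[first: last + 1]
    if span.min() == span.max():  # constant span: exact, no float accumulation
        return float(span[0])
    total = 0.0
    total += v[first] * (b * (first + 1) - start)
    total += v[last] * (end - b * last)
    if last - first > 1:
        total += v[first + 1: last].sum() * b
    return float(total / (end - start))


@dataclass
class MetaProfile:
    """Signal matrix over aligned windows (peak center +/- flank)."""

    regions: list[GenomicInterval]
    flank: int
    bin_size: int
    matrix: np.ndarray  # rows = regions, cols = 2*flank/bin_size; NaN past edges

    @property
    def offsets(self) -> np.ndarray:
        """Left edge of each column relative to the region center (bp)."""
        return np.arange(-self.flank, self.flank, self.bin_size)

    @property
    def mean_curve(self) -> np.ndarray:
        """Column means over finite entries (edge-truncated rows excluded);
        NaN where no region covers a column."""
        finite = np.isfinite(self.matrix)
        n = finite.sum(axis=0)
        sums = np.where(finite, self.matrix, 0.0).sum(axis=0)
        return np.where(n > 0, sums / np.maximum(n, 1), np.nan)

    def row_order(self) -> np.ndarray:
        """Heatmap row order: descending row mean, ties by genomic position."""
        finite = np.isfinite(self.matrix)
        n = finite.sum(axis=1)
        sums = np.where(finite, self.matrix, 0.0).sum(axis=1)
        means = np.where(n > 0, sums / np.maximum(n, 1), -np.inf)
        keys = [(-means[i],) + self.regions[i].sort_key() for i in range(len(self.regions))]
        return np.array(sorted(range(len(keys)), key=lambda i: keys[i]))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, columns=self.offsets)


def meta_profile(track: CoverageTrack, peaks: PeakSet, flank: int = 2000,
                 bin: int = 50, use_summits: bool = False) -> MetaProfile:
    """Sample the track in ``bin``-bp columns across center +/- ``flank``.

    Columns extending past a chromosome edge are NaN (excluded from column
    means, avoiding edge artifacts).  With ``use_summits`` narrowPeak summit
    offsets from the peak-set metadata replace the floor midpoint.
    """
    if len(peaks) == 0:
        raise ValueError("meta_profile of an empty PeakSet")
    if flank <= 0 or bin <= 0 or (2 * flank) % bin:
        raise ValueError("flank must be a positive multiple of bin")
    summits = peaks.metadata.get("summits", {}) if use_summits else {}
    n_cols = 2 * flank // bin
    mat = np.full((len(peaks), n_cols), np.nan)
    for i, iv in enumerate(peaks.intervals):
        center = iv.center
        if use_summits:
            off = summits.get((iv.chrom, iv.start, iv.end))
            if off is not None:
                center = iv.start + off
        length = track.sizes[iv.chrom]
        for j in range(n_cols):
            lo = center - flank + j * bin
            hi = lo + bin
            if lo < 0 or hi > length:
                continue
            mat[i, j] = _span_mean(track, iv.chrom, lo, hi)
    return MetaProfile(list(peaks.intervals), flank, bin, mat)


def track_correlation(tracks: Sequence[CoverageTrack], method: str = "spearman",
                      bin_size: int = 10_000, labels: Sequence[str] | None = None,
                      drop_all_zero: bool = False) -> pd.DataFrame:
    """Pairwise genome-wide correlation of rebinned tracks.

    All tracks must share ChromSizes; each is rebinned to ``bin_size``.
    ``drop_all_zero`` excludes bins at which every track is zero (off by
    default).  Returns a symmetric matrix with unit diagonal.
    """
    if method not in ("spearman", "pearson"):
        raise ValueError(f"unknown method {method!r}")
    if len(tracks) < 2:
        raise ValueError("need at least two tracks")
    ref = tracks[0].sizes
    for t in tracks[1:]:
        if dict(t.sizes) != dict(ref):
            raise ValueError("tracks have mismatched genomes")
    vectors = np.vstack([t.rebin(bin_size).genome_vector() for t in tracks])
    if drop_all_zero:
        keep = ~(vectors == 0).all(axis=0)
        vectors = vectors[:, keep]
    n = len(tracks)
    mat = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            if method == "spearman":
                r = stats.spearmanr(vectors[i], vectors[j]).statistic
            else:
                r = stats.pearsonr(vectors[i], vectors[j]).statistic
            mat[i, j] = mat[j, i] = r
    labels = list(labels) if labels is not None else [f"track{i}" for i in range(n)]
    return pd.DataFrame(mat, index=labels, columns=labels)
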