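"""Exact interval algebra over genomic coordinates.

All coordinates are 0-based, half-open (BED convention).  Every statistic in
the package is built on the primitives here: sorting/validation, gap-bridging
merge, covered-base intersection, k-way overlap partitioning, nearest-peak
distances and width summaries.  Algorithms are sorted sweeps chosen for
auditable correctness at desk scale, not interval trees.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GenomicInterval",
    "PeakSet",
    "ChromSizes",
    "OverlapPartition",
    "sort_and_validate",
    "merge_within",
    "intersect_length",
    "overlap_classify",
    "closest_distance",
    "width_stats",
]


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open genomic span ``[start, end)`` on ``chrom``.

    ``score`` (when present) must be non-negative; ``strand`` is one of
    ``+``, ``-`` or ``.`` (unstranded).
    """

    chrom: str
    start: int
    end: int
    name: str | None = None
    score: float | None = None
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start in {self._repr_coord()}")
        if self.start >= self.end:
            raise ValueError(f"start >= end in {self._repr_coord()}")
        if self.score is not None and self.score < 0:
            raise ValueError(f"negative score in {self._repr_coord()}")
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"bad strand {self.strand!r} in {self._repr_coord()}")

    def _repr_coord(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"

    @property
    def width(self) -> int:
        """Width in bp: end minus start."""
        return self.end - self.start

    @property
    def center(self) -> int:
        """Floor midpoint of the span."""
        return (self.start + self.end) // 2

    def sort_key(self) -> tuple[str, int, int]:
        return (self.chrom, self.start, self.end)

    def overlap_bp(self, other: "GenomicInterval") -> int:
        """Shared bases with ``other`` (0 if different chromosome)."""
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def gap_to(self, other: "GenomicInterval") -> int | None:
        """Gap in bp to ``other`` on the same chromosome (0 if touching or
        overlapping); ``None`` across chromosomes."""
        if self.chrom != other.chrom:
            return None
        return max(0, other.start - self.end, self.start - other.end)


class ChromSizes(dict):
    """Mapping chromosome name -> length (bp)."""

    def __init__(self, sizes: Mapping[str, int] | Iterable[tuple[str, int]] = ()):
        super().__init__(sizes)
        for chrom, length in self.items():
            if length <= 0:
                raise ValueError(f"non-positive length for chromosome {chrom}")

    @property
    def genome_size(self) -> int:
        return sum(self.values())

    def contains(self, iv: GenomicInterval) -> bool:
        return iv.chrom in self and 0 <= iv.start and iv.end <= self[iv.chrom]


@dataclass
class PeakSet:
    """An ordered collection of :class:`GenomicInterval` under one label.

    ``sorted_flag`` records whether intervals are sorted by
    ``(chrom, start, end)``; operations that require sorted input check it.
    """

    label: str
    intervals: list[GenomicInterval] = field(default_factory=list)
    sorted_flag: bool = False
    metadata: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self.intervals)

    def __getitem__(self, i):
        return self.intervals[i]

    def chromosomes(self) -> list[str]:
        seen: dict[str, None] = {}
        for iv in self.intervals:
            seen.setdefault(iv.chrom, None)
        return list(seen)

    def by_chrom(self) -> dict[str, list[GenomicInterval]]:
        out: dict[str, list[GenomicInterval]] = {}
        for iv in self.intervals:
            out.setdefault(iv.chrom, []).append(iv)
        return out

    def total_width(self) -> int:
        return sum(iv.width for iv in self.intervals)

    def is_sorted(self) -> bool:
        ivs = self.intervals
        return all(ivs[i].sort_key() <= ivs[i + 1].sort_key() for i in range(len(ivs) - 1))

    def sorted(self) -> "PeakSet":
        return PeakSet(
            self.label,
            builtins_sorted(self.intervals),
            sorted_flag=True,
            metadata=dict(self.metadata),
        )

    def with_label(self, label: str) -> "PeakSet":
        return PeakSet(label, list(self.intervals), self.sorted_flag, dict(self.metadata))


def builtins_sorted(ivs: Sequence[GenomicInterval]) -> list[GenomicInterval]:
    return sorted(ivs, key=GenomicInterval.sort_key)


def _require_sorted(peaks: PeakSet, op: str) -> None:
    if not peaks.sorted_flag and not peaks.is_sorted():
        raise ValueError(f"{op} requires a sorted PeakSet (got unsorted {peaks.label!r})")


def sort_and_validate(peaks: PeakSet, sizes: ChromSizes | None = None) -> PeakSet:
    """Sort by (chrom, start, end) and validate bounds.

    Duplicated identical intervals are retained.  With ``sizes`` given, every
    interval must lie within ``[0, chrom length]``; violations raise with the
    offending record named rather than being clamped.
    """
    if sizes is not None:
        for iv in peaks.intervals:
            if iv.chrom not in sizes:
                raise ValueError(f"unknown chromosome in {iv._repr_coord()}")
            if iv.end > sizes[iv.chrom]:
                raise ValueError(
                    f"interval {iv._repr_coord()} exceeds chromosome length {sizes[iv.chrom]}"
                )
    return peaks.sorted()


def merge_within(peaks: PeakSet, max_gap: int = 1000) -> PeakSet:
    """Combine peaks separated by a gap strictly less than ``max_gap`` bp.

    ``max_gap=1000`` reproduces the "peaks closer than 1 kb are combined"
    convention.  Output intervals are disjoint with inter-peak gaps >=
    ``max_gap`` on each chromosome; the operation is idempotent.  Name, score
    and strand are dropped (merged spans are anonymous).
    """
    if max_gap < 0:
        raise ValueError("max_gap must be >= 0")
    _require_sorted(peaks, "merge_within")
    merged: list[GenomicInterval] = []
    cur: list | None = None  # [chrom, start, end]
    for iv in peaks.intervals:
        # gaps strictly below max_gap are bridged; touching or overlapping
        # intervals always coalesce (their covered-base union is one run)
        if cur is not None and iv.chrom == cur[0] and (
                iv.start - cur[2] < max_gap or iv.start <= cur[2]):
            cur[2] = max(cur[2], iv.end)
        else:
            if cur is not None:
                merged.append(GenomicInterval(cur[0], cur[1], cur[2]))
            cur = [iv.chrom, iv.start, iv.end]
    if cur is not None:
        merged.append(GenomicInterval(cur[0], cur[1], cur[2]))
    return PeakSet(peaks.label, merged, sorted_flag=True, metadata=dict(peaks.metadata))


def covered_bp(peaks: PeakSet) -> int:
    """Bases covered by the union of the (possibly overlapping) peaks."""
    return merge_within(peaks.sorted(), max_gap=0).total_width()


def intersect_length(a: PeakSet, b: PeakSet) -> int:
    """Total bp covered by both sets; each side is internally merged first so
    every base counts once."""
    _require_sorted(a, "intersect_length")
    _require_sorted(b, "intersect_length")
    am = merge_within(a, 0).by_chrom()
    bm = merge_within(b, 0).by_chrom()
    total = 0
    for chrom in set(am) & set(bm):
        xs, ys = am[chrom], bm[chrom]
        i = j = 0
        while i < len(xs) and j < len(ys):
            lo = max(xs[i].start, ys[j].start)
            hi = min(xs[i].end, ys[j].end)
            if hi > lo:
                total += hi - lo
            if xs[i].end <= ys[j].end:
                i += 1
            else:
                j += 1
    return total


@dataclass
class OverlapPartition:
    """Result of a 2- or 3-way overlap classification.

    Counts are reported from each set's own perspective: ``labels[set_label]``
    gives, for every peak of that set in order, the frozenset of OTHER set
    labels it overlaps (>= ``min_overlap`` bp with at least one peak).
    Because overlaps may be many-to-many, the count of A-peaks overlapping B
    need not equal the count of B-peaks overlapping A.
    """

    set_labels: list[str]
    min_overlap: int
    labels: dict[str, list[frozenset]]

    convention: str = (
        "per-set perspective; many-to-many overlaps allowed, counts need not be symmetric"
    )

    def counts(self) -> pd.DataFrame:
        """Tidy counts: one row per (set, overlap-combination)."""
        rows = []
        for label, labs in self.labels.items():
            tallies: dict[frozenset, int] = {}
            for s in labs:
                tallies[s] = tallies.get(s, 0) + 1
            for combo, n in sorted(tallies.items(), key=lambda kv: sorted(kv[0])):
                name = "+".join(sorted(combo)) if combo else "specific"
                rows.append({"set": label, "overlaps": name, "count": n})
        return pd.DataFrame(rows, columns=["set", "overlaps", "count"])

    def count(self, set_label: str, overlapping: Iterable[str]) -> int:
        want = frozenset(overlapping)
        return sum(1 for s in self.labels[set_label] if s == want)


def _peaks_overlapping(query: list[GenomicInterval], subject: list[GenomicInterval],
                       min_overlap: int) -> list[bool]:
    """For each sorted query interval, whether some subject interval on the
    same chromosome shares >= min_overlap bp.  Sorted sweep."""
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in subject:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    flags = []
    for q in query:
        hit = False
        for s in by_chrom.get(q.chrom, ()):
            if s.start >= q.end:
                break
            if q.overlap_bp(s) >= min_overlap:
                hit = True
                break
        flags.append(hit)
    return flags


def overlap_classify(sets: Sequence[PeakSet], min_overlap: int = 1) -> OverlapPartition:
    """Label every peak of 2 or 3 sets with the subset of other sets it
    overlaps (Venn-style partition, per-set perspective)."""
    if not 2 <= len(sets) <= 3:
        raise ValueError("overlap_classify supports exactly 2 or 3 sets")
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    names = [s.label for s in sets]
    if len(set(names)) != len(names):
        raise ValueError("peak sets must have distinct labels")
    for s in sets:
        _require_sorted(s, "overlap_classify")
    labels: dict[str, list[frozenset]] = {}
    for s in sets:
        per_other: list[list[bool]] = []
        others = [o for o in sets if o.label != s.label]
        for o in others:
            per_other.append(_peaks_overlapping(s.intervals, o.intervals, min_overlap))
        labels[s.label] = [
            frozenset(o.label for o, f in zip(others, flags) if f)
            for flags in zip(*per_other)
        ] if len(s) else []
    return OverlapPartition(names, min_overlap, labels)


def closest_distance(peaks: PeakSet, mode: str = "gap") -> list[float]:
    """Distance from each peak to its nearest other peak on the same chromosome.

    ``mode='gap'`` (default): bp between the closest edges, 0 when peaks
    overlap or are book-ended.  ``mode='center'``: absolute center-to-center
    distance.  Peaks alone on their chromosome get NaN (distance undefined).
    Order of the returned list follows the input peak order.
    """
    if mode not in ("gap", "center"):
        raise ValueError(f"unknown mode {mode!r}")
    _require_sorted(peaks, "closest_distance")
    out = np.full(len(peaks), np.nan)
    by_chrom: dict[str, list[int]] = {}
    for idx, iv in enumerate(peaks.intervals):
        by_chrom.setdefault(iv.chrom, []).append(idx)
    for chrom, idxs in by_chrom.items():
        if len(idxs) < 2:
            continue
        ivs = [peaks.intervals[i] for i in idxs]
        if mode == "center":
            centers = np.sort(np.array([iv.center for iv in ivs], dtype=float))
            order = np.argsort([iv.center for iv in ivs], kind="stable")
            diffs = np.diff(centers)
            best = np.empty(len(ivs))
            best[0] = diffs[0]
            best[-1] = diffs[-1]
            if len(ivs) > 2:
                best[1:-1] = np.minimum(diffs[:-1], diffs[1:])
            for rank, pos in enumerate(order):
                out[idxs[pos]] = best[rank]
        else:
            # Left gap: start_i minus running max of previous ends (engulfing
            # peaks are caught by the running max).  Right gap: the next start
            # in sorted order is minimal, so it gives the nearest right edge.
            n = len(ivs)
            best = np.full(n, np.inf)
            max_end = -np.inf
            for i in range(n):
                if i > 0:
                    best[i] = max(0.0, ivs[i].start - max_end)
                max_end = max(max_end, ivs[i].end)
            for i in range(n - 1):
                right = max(0.0, ivs[i + 1].start - ivs[i].end)
                best[i] = min(best[i], right)
            for i, idx in enumerate(idxs):
                out[idx] = best[i]
    return out.tolist()


def width_stats(peaks: PeakSet) -> dict:
    """Per-peak widths with a quartile summary and log2 widths for plotting."""
    if len(peaks) == 0:
        raise ValueError("width_stats of an empty PeakSet")
    widths = np.array([iv.width for iv in peaks.intervals], dtype=float)
    q1, med, q3 = np.percentile(widths, [25, 50, 75])
    return {
        "widths": widths,
        "log2_widths": np.log2(widths),
        "median": float(med),
        "q1": float(q1),
        "q3": float(q3),
        "n": len(peaks),
    }
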