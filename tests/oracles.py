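"""Independent brute-force oracles used by the test suite.

Everything here works per base (or per pair) on small chromosomes, with no
shared code or algorithmic idea with the package's sorted-sweep
implementations, so agreement is evidence of correctness rather than of
consistency.
"""

from __future__ import annotations

import numpy as np

from axispeaks.intervals import GenomicInterval, PeakSet


def merge_oracle(intervals: list[tuple[str, int, int]], max_gap: int,
                 chrom_len: int) -> list[tuple[str, int, int]]:
    """Paint bases on an array, bridge gaps strictly below max_gap, read runs."""
    out = []
    for chrom in sorted({c for c, _, _ in intervals}):
        covered = np.zeros(chrom_len, dtype=bool)
        for c, s, e in intervals:
            if c == chrom:
                covered[s:e] = True
        # bridge gaps < max_gap between covered runs
        runs = _runs(covered)
        merged: list[list[int]] = []
        for s, e in runs:
            if merged and s - merged[-1][1] < max_gap:
                merged[-1][1] = e
            else:
                merged.append([s, e])
        out.extend((chrom, s, e) for s, e in merged)
    return out


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    runs = []
    in_run = False
    start = 0
    for i, v in enumerate(mask):
        if v and not in_run:
            in_run, start = True, i
        elif not v and in_run:
            in_run = False
            runs.append((start, i))
    if in_run:
        runs.append((start, len(mask)))
    return runs


def intersect_oracle(a: list[tuple[str, int, int]], b: list[tuple[str, int, int]],
                     chrom_len: int) -> int:
    """Boolean-AND bit arrays per chromosome."""
    total = 0
    for chrom in sorted({c for c, _, _ in a} | {c for c, _, _ in b}):
        mask_a = np.zeros(chrom_len, dtype=bool)
        mask_b = np.zeros(chrom_len, dtype=bool)
        for c, s, e in a:
            if c == chrom:
                mask_a[s:e] = True
        for c, s, e in b:
            if c == chrom:
                mask_b[s:e] = True
        total += int((mask_a & mask_b).sum())
    return total


def closest_oracle(intervals: list[tuple[str, int, int]]) -> list[float]:
    """All-pairs minimum gap per peak; NaN when alone on its chromosome."""
    out = []
    for i, (ci, si, ei) in enumerate(intervals):
        best = np.inf
        for j, (cj, sj, ej) in enumerate(intervals):
            if i == j or ci != cj:
                continue
            best = min(best, max(0, sj - ei, si - ej))
        out.append(float(best) if np.isfinite(best) else np.nan)
    return out


def coverage_oracle(fragments: list[tuple[str, int, int]], sizes: dict[str, int],
                    bin_size: int) -> dict[str, np.ndarray]:
    """Per-bin fragment-overlap counts by scanning every (fragment, bin) pair."""
    out = {}
    for chrom, length in sizes.items():
        n_bins = -(-length // bin_size)
        counts = np.zeros(n_bins)
        for b in range(n_bins):
            lo, hi = b * bin_size, (b + 1) * bin_size
            for c, s, e in fragments:
                if c == chrom and s < hi and e > lo:
                    counts[b] += 1
        out[chrom] = counts
    return out


def gc_window_oracle(seq: str, center: int, window: int) -> float | None:
    """GC fraction of the window centered at ``center`` over non-N bases."""
    lo = max(0, center - window // 2)
    hi = min(len(seq), center - window // 2 + window)
    chunk = seq[lo:hi].upper()
    known = sum(1 for b in chunk if b in "ACGT")
    if known == 0:
        return None
    gc = sum(1 for b in chunk if b in "GC")
    return gc / known


def random_intervals(rng: np.random.Generator, n: int, chrom_len: int,
                     chroms: tuple[str, ...] = ("chr1", "chr2")) -> list[tuple[str, int, int]]:
    out = []
    for _ in range(n):
        chrom = chroms[int(rng.integers(0, len(chroms)))]
        start = int(rng.integers(0, chrom_len - 1))
        width = int(rng.integers(1, max(2, chrom_len // 10)))
        out.append((chrom, start, min(start + width, chrom_len)))
    return out


def to_peakset(intervals: list[tuple[str, int, int]], label: str = "x") -> PeakSet:
    return PeakSet(label, [GenomicInterval(c, s, e) for c, s, e in intervals]).sorted()
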