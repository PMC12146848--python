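#!/usr/bin/env python
"""Transposable-element enrichment and methylation-class occupancy.

On the simulated scenario: per-family and per-class TE enrichment of the
control peaks, family-level length-weighted signal, methylome tiling
(1 kb windows, mincov 3) with hypo/intermediate/hyper classes, and the
occupancy contrast between hypo- and hypermethylated tiles.  Writes
results/te_methylation/.
"""

import argparse
from pathlib import Path

import pandas as pd

from axispeaks.genome_io import read_bed, read_bedgraph, read_cpg_report, read_repeat_annotation
from axispeaks.occupancy import (
    methylation_tile_table,
    occupancy_by_methylation,
    te_enrichment,
    te_family_signal,
    tile_methylome,
)
from axispeaks.pipeline import read_chrom_sizes

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--scenario", type=Path, default=ROOT / "results" / "scenario")
    ap.add_argument("--outdir", type=Path,
                    default=ROOT / "results" / "te_methylation")
    args = ap.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    sizes = read_chrom_sizes(args.scenario / "chrom.sizes")
    peaks = read_bed(args.scenario / "peaks_control.bed", sizes=sizes, label="control")
    track = read_bedgraph(args.scenario / "track_control.bedgraph", sizes)
    repeats = read_repeat_annotation(args.scenario / "repeats.tsv")

    rows = []
    for level in ("family", "class"):
        for group, e in te_enrichment(peaks, repeats, sizes, level=level).items():
            rows.append({"level": level, "group": group,
                         "bp_in_peaks": e.bp_in_peaks,
                         "total_peak_width": e.total_peak_width,
                         "bp_in_genome": e.bp_in_genome,
                         "genome_size": e.genome_size,
                         "enrichment": e.enrichment})
    enr = pd.DataFrame(rows)
    enr.to_csv(args.outdir / "te_enrichment.tsv", sep="\t", index=False)
    fam = enr[enr["level"] == "family"]
    print("TE enrichment (1 = none):",
          {r.group: round(r.enrichment, 2) for r in fam.itertuples()})

    sig = te_family_signal(track, repeats)
    pd.DataFrame(sorted(sig.items()),
                 columns=["family", "signal"]).to_csv(
        args.outdir / "te_family_signal.tsv", sep="\t", index=False)

    cpgs = read_cpg_report(args.scenario / "methylome.cov.txt")
    tiles = tile_methylome(cpgs, sizes)
    methylation_tile_table(tiles).to_csv(args.outdir / "methylation_tiles.tsv",
                                         sep="\t", index=False)
    counts = {k: sum(t.klass == k for t in tiles)
              for k in ("hypo", "intermediate", "hyper")}
    print(f"methylation tiles: {counts}")
    occ = occupancy_by_methylation(track, tiles)
    print(f"occupancy log2 medians hypo {occ['medians']['hypo']:.2f} vs hyper "
          f"{occ['medians']['hyper']:.2f}, Wilcoxon P = {occ['p_value']:.3g}")


if __name__ == "__main__":
    main()
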