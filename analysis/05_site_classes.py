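#!/usr/bin/env python
"""Peak taxonomies: genomic features, stage retention, core/non-core,
sex-chromosome compartment.

On the simulated scenario: center-based feature annotation of the control
peaks, stage-1 to stage-2 retention, the perturbation core/non-core split
with width and intensity contrasts, and the sex-vs-autosome comparison.
Writes results/site_classes/.
"""

import argparse
import json
from pathlib import Path

from axispeaks.classify import (
    annotate_features,
    classification_table,
    core_noncore,
    feature_counts,
    genic_peak_genes,
    stage_retention,
)
from axispeaks.genome_io import read_bed, read_bedgraph, read_gene_models
from axispeaks.intervals import PeakSet, width_stats
from axispeaks.occupancy import sex_autosome_comparison
from axispeaks.pipeline import read_chrom_sizes

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--scenario", type=Path, default=ROOT / "results" / "scenario")
    ap.add_argument("--outdir", type=Path, default=ROOT / "results" / "site_classes")
    args = ap.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    sizes = read_chrom_sizes(args.scenario / "chrom.sizes")
    genes = read_gene_models(args.scenario / "genes.tsv")
    control = read_bed(args.scenario / "peaks_control.bed", sizes=sizes, label="control")
    stage1 = read_bed(args.scenario / "peaks_stage1.bed", sizes=sizes, label="stage1")
    stage2 = read_bed(args.scenario / "peaks_stage2.bed", sizes=sizes, label="stage2")
    perturbed = read_bed(args.scenario / "peaks_perturbed.bed", sizes=sizes,
                         label="perturbed")
    track = read_bedgraph(args.scenario / "track_control.bedgraph", sizes)

    anns = annotate_features(control, genes)
    fc = feature_counts(anns)
    fc.to_csv(args.outdir / "feature_counts.tsv", sep="\t", index=False)
    (args.outdir / "genic_genes.txt").write_text(
        "\n".join(genic_peak_genes(anns)) + "\n")
    print("feature distribution:",
          {r.feature: round(r.fraction, 3) for r in fc.itertuples() if r.count})

    ret = stage_retention(stage1, stage2)
    print(f"stage retention: {100 * ret['retained_fraction']:.1f}% of "
          f"{ret['n_stage1']} stage-1 peaks persist at stage 2")

    cn = core_noncore(control, perturbed)
    classification_table(cn["classifications"]).to_csv(
        args.outdir / "core_noncore.tsv", sep="\t", index=False)
    core_ps = PeakSet("core", [c.peak for c in cn["classifications"]
                               if c.core_status == "core"]).sorted()
    noncore_ps = PeakSet("noncore", [c.peak for c in cn["classifications"]
                                     if c.core_status == "noncore"]).sorted()
    print(f"core/non-core: {100 * cn['core_fraction']:.1f}% core "
          f"({cn['n_core']}/{cn['n_control']}); median widths "
          f"{width_stats(core_ps)['median']:.0f} vs "
          f"{width_stats(noncore_ps)['median']:.0f} bp")

    comp = sex_autosome_comparison(track, control, ["chrX"])
    summary = {
        "retained_fraction": ret["retained_fraction"],
        "core_fraction": cn["core_fraction"],
        "sex_peak_fraction": comp["sex_fraction"],
        "sex_median_intensity": comp["median_sex"],
        "autosome_median_intensity": comp["median_autosome"],
        "sex_vs_autosome_p": comp["p_value"],
    }
    (args.outdir / "summary.json").write_text(json.dumps(summary, indent=1))
    print(f"sex chromosomes: {comp['n_sex']}/{comp['n_total']} peaks "
          f"({100 * comp['sex_fraction']:.2f}%), median intensity ratio "
          f"{comp['median_sex'] / comp['median_autosome']:.2f}, "
          f"Wilcoxon P = {comp['p_value']:.3g}")


if __name__ == "__main__":
    main()
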