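"""End-to-end orchestration: simulate a scenario to disk, run analysis stages
over input files, and summarize an analysis directory.

Every run writes a manifest (config snapshot, seeds, input digests, package
version, per-stage outputs and runtimes) so deterministic stages reproduce
identical outputs from an identical manifest.  All outputs are plain
TSV/BED/JSON for consumption outside the package.
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from .classify import (
    annotate_features,
    classification_table,
    core_noncore,
    feature_counts,
    genic_peak_genes,
    stage_retention,
)
from .genome_io import (
    read_bed,
    read_bedgraph,
    read_cpg_report,
    read_fasta,
    read_gene_models,
    read_repeat_annotation,
    write_bed,
    write_bedgraph,
    write_cpg_report,
    write_fasta,
    write_gene_models,
    write_repeat_annotation,
)
from .intervals import ChromSizes, width_stats
from .occupancy import (
    compare_or,
    gc_profile,
    methylation_tile_table,
    occupancy_by_methylation,
    occupancy_ratio,
    or_table,
    sex_autosome_comparison,
    spacing_periodicity,
    te_enrichment,
    te_family_signal,
    tile_methylome,
)
from .simulate import ScenarioConfig, generate_scenario
from .tracks import track_correlation

ALL_STAGES = (
    "annotate", "or", "te", "methylation", "gc", "spacing",
    "retention", "core", "correlation", "sex",
)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_manifest(outdir: Path, config: dict, stages: dict[str, dict],
                    inputs: dict[str, str] | None = None) -> None:
    manifest = {
        "tool": "axispeaks",
        "version": __version__,
        "config": config,
        "inputs": inputs or {},
        "stages": stages,
        "outputs": {p.name: _sha256(p) for p in sorted(outdir.iterdir())
                    if p.is_file() and p.name != "manifest.json"},
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)


def simulate_scenario(config: ScenarioConfig, outdir) -> Path:
    """Generate a full scenario and write every artifact to ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    scenario = generate_scenario(config)
    write_fasta(scenario.genome, outdir / "genome.fa")
    with open(outdir / "chrom.sizes", "w") as fh:
        for chrom, length in scenario.sizes.items():
            fh.write(f"{chrom}\t{length}\n")
    write_gene_models(scenario.genes, outdir / "genes.tsv")
    write_repeat_annotation(scenario.repeats, outdir / "repeats.tsv")
    write_cpg_report(scenario.methylome, outdir / "methylome.cov.txt")
    for name, ps in scenario.peaks.items():
        write_bed(ps, outdir / f"peaks_{name}.bed", dialect="bed3")
    for name, track in scenario.tracks.items():
        write_bedgraph(track, outdir / f"track_{name}.bedgraph")
    scenario.truth.to_json(outdir / "truth.json")
    _write_manifest(outdir, config.to_dict(),
                    {"simulate": {"runtime_s": round(time.time() - t0, 3)}})
    return outdir


def read_chrom_sizes(path) -> ChromSizes:
    sizes = {}
    with open(path) as fh:
        for line in fh:
            if line.strip():
                chrom, length = line.split("\t")
                sizes[chrom] = int(length)
    return ChromSizes(sizes)


def analyze(outdir, stages: Sequence[str] = ALL_STAGES, *,
            peaks_path=None, peaks2_path=None, perturbed_path=None,
            track_path=None, track2_path=None, sizes_path=None,
            genes_path=None, repeats_path=None, genome_path=None,
            cpg_path=None, sex_chroms: Sequence[str] = (),
            seed: int | None = None, min_overlap: int = 1, merge_gap: int = 1000,
            flank: int = 2000, bin: int = 50, corr_bin: int = 10_000,
            win: int = 1000, mincov: int = 3, alpha: float = 0.05) -> dict:
    """Run the requested analysis stages over input files.

    Each stage checks its own inputs and raises naming what is missing.
    Writes one TSV/BED per stage plus ``summary.json`` aggregating headline
    statistics; returns the summary dict.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    unknown = set(stages) - set(ALL_STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)} (known: {ALL_STAGES})")

    if sizes_path is None:
        raise ValueError("every analysis needs --sizes (chrom.sizes file)")
    sizes = read_chrom_sizes(sizes_path)

    def need(value, flag: str, stage: str):
        if value is None:
            raise ValueError(f"stage {stage!r} needs {flag}")
        return value

    peaks = read_bed(peaks_path, sizes=sizes, label="peaks") if peaks_path else None
    track = read_bedgraph(track_path, sizes) if track_path else None
    genes = read_gene_models(genes_path) if genes_path else None

    summary: dict = {"stages": {}, "parameters": {
        "min_overlap": min_overlap, "merge_gap": merge_gap, "flank": flank,
        "bin": bin, "corr_bin": corr_bin, "win": win, "mincov": mincov,
        "alpha": alpha, "seed": seed, "sex_chroms": list(sex_chroms)}}
    timings: dict[str, dict] = {}

    for stage in stages:
        t0 = time.time()
        if stage == "annotate":
            anns = annotate_features(need(peaks, "--peaks", stage),
                                     need(genes, "--genes", stage))
            feature_counts(anns).to_csv(outdir / "feature_counts.tsv", sep="\t", index=False)
            with open(outdir / "genic_genes.txt", "w") as fh:
                fh.write("\n".join(genic_peak_genes(anns)) + "\n")
            summary["stages"]["annotate"] = {
                "n_peaks": len(anns),
                "promoter_fraction": sum(a.feature == "promoter" for a in anns) / len(anns)}
        elif stage == "or":
            results = occupancy_ratio(need(track, "--track", stage),
                                      need(genes, "--genes", stage))
            or_table(results).to_csv(outdir / "or_values.tsv", sep="\t", index=False)
            eligible = [r for r in results if r.eligible]
            entry = {"n_genes": len(results), "n_eligible": len(eligible),
                     "median_or": float(np.median([r.or_value for r in eligible]))
                     if eligible else None}
            if track2_path:
                after = occupancy_ratio(read_bedgraph(track2_path, sizes), genes)
                shift = compare_or(results, after)
                or_table(after).to_csv(outdir / "or_values_after.tsv", sep="\t", index=False)
                entry["shift"] = {k: shift[k] for k in
                                  ("median_log2_shift", "direction", "p_value", "n")}
            summary["stages"]["or"] = entry
        elif stage == "te":
            repeats = read_repeat_annotation(need(repeats_path, "--repeats", stage))
            enr = te_enrichment(need(peaks, "--peaks", stage), repeats, sizes)
            pd.DataFrame([vars(e) for e in enr.values()]).to_csv(
                outdir / "te_enrichment.tsv", sep="\t", index=False)
            entry = {"enrichment": {k: e.enrichment for k, e in enr.items()}}
            if track is not None:
                sig = te_family_signal(track, repeats)
                pd.DataFrame(sorted(sig.items()), columns=["family", "signal"]).to_csv(
                    outdir / "te_family_signal.tsv", sep="\t", index=False)
                entry["family_signal"] = sig
            summary["stages"]["te"] = entry
        elif stage == "methylation":
            cpgs = read_cpg_report(need(cpg_path, "--cpg", stage))
            tiles = tile_methylome(cpgs, sizes, win=win, step=win, mincov=mincov)
            methylation_tile_table(tiles).to_csv(outdir / "methylation_tiles.tsv",
                                                 sep="\t", index=False)
            entry = {"n_tiles": len(tiles),
                     "class_counts": {k: sum(t.klass == k for t in tiles)
                                      for k in ("hypo", "intermediate", "hyper")}}
            if track is not None and entry["class_counts"]["hypo"] and \
                    entry["class_counts"]["hyper"]:
                occ = occupancy_by_methylation(track, tiles)
                entry["hypo_vs_hyper"] = {"medians": occ["medians"],
                                          "p_value": occ["p_value"]}
            summary["stages"]["methylation"] = entry
        elif stage == "gc":
            genome = read_fasta(need(genome_path, "--genome", stage))
            prof = gc_profile(genome, need(peaks, "--peaks", stage), flank=flank)
            prof.to_csv(outdir / "gc_profile.tsv", sep="\t", index=False)
            center = prof.loc[prof["offset"].abs().idxmin(), "mean_gc"]
            edge = prof.iloc[[0, -1]]["mean_gc"].mean()
            summary["stages"]["gc"] = {"center_gc": float(center),
                                       "flank_gc": float(edge)}
        elif stage == "spacing":
            res = spacing_periodicity(need(peaks, "--peaks", stage),
                                      seed=need(seed, "--seed", stage), alpha=alpha)
            pd.DataFrame({"lag_bp": res.lags, "pair_count": res.autocorr,
                          "null_mean": res.null_mean}).to_csv(
                outdir / "spacing_autocorrelation.tsv", sep="\t", index=False)
            d = res.distances[np.isfinite(res.distances)]
            pd.DataFrame({"distance_bp": d}).to_csv(outdir / "peak_distances.tsv",
                                                    sep="\t", index=False)
            ws = width_stats(peaks)
            summary["stages"]["spacing"] = {
                "median_gap": float(np.median(d)), "median_width": ws["median"],
                "periodicity_p": res.p_value, "period_estimate": res.period_estimate}
        elif stage == "retention":
            stage2 = read_bed(need(peaks2_path, "--peaks2", stage), sizes=sizes,
                              label="stage2")
            ret = stage_retention(need(peaks, "--peaks", stage).with_label("stage1"),
                                  stage2, min_overlap=min_overlap)
            classification_table(ret["classifications"]).to_csv(
                outdir / "stage_retention.tsv", sep="\t", index=False)
            summary["stages"]["retention"] = {
                k: ret[k] for k in ("retained_fraction", "reverse_retained_fraction",
                                    "n_stage1", "n_stage2")}
        elif stage == "core":
            perturbed = read_bed(need(perturbed_path, "--perturbed", stage),
                                 sizes=sizes, label="perturbed")
            cn = core_noncore(need(peaks, "--peaks", stage), perturbed,
                              min_overlap=min_overlap)
            classification_table(cn["classifications"]).to_csv(
                outdir / "core_noncore.tsv", sep="\t", index=False)
            summary["stages"]["core"] = {k: cn[k] for k in
                                         ("core_fraction", "n_control", "n_core")}
        elif stage == "correlation":
            t2 = read_bedgraph(need(track2_path, "--track2", stage), sizes)
            mat = track_correlation([need(track, "--track", stage), t2],
                                    bin_size=corr_bin, labels=["track1", "track2"])
            mat.to_csv(outdir / "track_correlation.tsv", sep="\t")
            summary["stages"]["correlation"] = {"spearman": float(mat.iloc[0, 1])}
        elif stage == "sex":
            if not sex_chroms:
                raise ValueError("stage 'sex' needs --sex-chroms")
            comp = sex_autosome_comparison(need(track, "--track", stage),
                                           need(peaks, "--peaks", stage), sex_chroms)
            summary["stages"]["sex"] = {
                k: comp[k] for k in ("n_sex", "n_autosome", "sex_fraction",
                                     "median_sex", "median_autosome", "p_value")}
        timings[stage] = {"runtime_s": round(time.time() - t0, 3)}

    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=1, default=_jsonable)
    inputs = {str(p): _sha256(Path(p)) for p in
              (peaks_path, peaks2_path, perturbed_path, track_path, track2_path,
               sizes_path, genes_path, repeats_path, genome_path, cpg_path) if p}
    _write_manifest(outdir, summary["parameters"], timings, inputs)
    return summary


def _jsonable(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, np.ndarray):
        return x.tolist()
    return str(x)


def report(analysis_dir) -> str:
    """Human-readable summary of an analysis directory."""
    analysis_dir = Path(analysis_dir)
    summary_path = analysis_dir / "summary.json"
    if not summary_path.exists():
        raise ValueError(f"no summary.json in {analysis_dir} (run analyze first)")
    with open(summary_path) as fh:
        summary = json.load(fh)
    lines = ["axispeaks analysis report", "=" * 26, ""]
    lines.append("parameters: " + json.dumps(summary.get("parameters", {})))
    lines.append("")
    ran = summary.get("stages", {})
    for stage in ALL_STAGES:
        if stage in ran:
            lines.append(f"[{stage}] " + json.dumps(ran[stage], default=str))
        else:
            lines.append(f"[{stage}] skipped")
    text = "\n".join(lines) + "\n"
    with open(analysis_dir / "report.txt", "w") as fh:
        fh.write(text)
    return text
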