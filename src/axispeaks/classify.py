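"""Peak taxonomies: genomic-feature annotation, stage retention, and the
core / non-core split under a perturbation that dissolves protein assemblies.

Feature annotation is center-based with a fixed priority ladder
(promoter > 5'UTR > 3'UTR > exon > intron > downstream > distal intergenic),
the behavior of common peak annotators.  Retention and core status use the
>= min_overlap bp rule shared with the Venn partitioning.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .genome_io import GeneModel, PROMOTER_FLANK
from .intervals import GenomicInterval, PeakSet, overlap_classify

__all__ = [
    "FeatureAnnotation",
    "SiteClassification",
    "FEATURE_PRIORITY",
    "annotate_features",
    "feature_counts",
    "stage_retention",
    "core_noncore",
    "genic_peak_genes",
]

FEATURE_PRIORITY = (
    "promoter", "5'UTR", "3'UTR", "exon", "intron", "downstream", "distal_intergenic",
)


@dataclass(frozen=True)
class FeatureAnnotation:
    """Feature assignment of one peak (exactly one feature per peak)."""

    peak: GenomicInterval
    feature: str
    gene_id: str | None
    distance_to_tss: int | None  # signed; positive downstream of the TSS


@dataclass(frozen=True)
class SiteClassification:
    """Stage / perturbation status of one peak."""

    peak: GenomicInterval
    stage_status: str = "not_applicable"  # stage1_specific | stage2_specific | overlapping
    core_status: str = "not_applicable"   # core | noncore


def _signed_tss_distance(center: int, gene: GeneModel) -> int:
    d = center - gene.tss
    return d if gene.strand == "+" else -d


def _in_exon(center: int, gene: GeneModel) -> bool:
    if gene.exons is None:
        return False
    return any(s <= center < e for s, e in gene.exons)


def _utr_side(center: int, gene: GeneModel) -> str | None:
    """5'/3' UTR call for an exonic position, when a CDS span is present."""
    if gene.cds_start is None or gene.cds_end is None:
        return None
    if gene.cds_start <= center < gene.cds_end:
        return None
    before_cds = center < gene.cds_start  # genomically left of the CDS
    if gene.strand == "+":
        return "5'UTR" if before_cds else "3'UTR"
    return "3'UTR" if before_cds else "5'UTR"


def annotate_features(peaks: PeakSet, genes: Sequence[GeneModel],
                      downstream_window: int = 3000,
                      promoter_flank: int = PROMOTER_FLANK) -> list[FeatureAnnotation]:
    """Assign each peak (by its center) one genomic feature.

    Priority: promoter (TSS +/- promoter_flank) > 5'UTR > 3'UTR > exon >
    intron > downstream (<= downstream_window past the TES) > distal
    intergenic.  Within a priority level the gene with the nearest TSS wins.
    UTR calls require exon blocks plus a CDS span in the gene model;
    otherwise exonic positions are labeled exon.
    """
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)

    annotations = []
    for peak in peaks.intervals:
        center = peak.center
        candidates: dict[str, list[GeneModel]] = {f: [] for f in FEATURE_PRIORITY[:-1]}
        for g in by_chrom.get(peak.chrom, ()):
            if -promoter_flank <= center - g.tss < promoter_flank:
                candidates["promoter"].append(g)
            if g.start <= center < g.end:
                if _in_exon(center, g):
                    side = _utr_side(center, g)
                    candidates[side if side else "exon"].append(g)
                elif g.exons is not None:
                    candidates["intron"].append(g)
                else:
                    # no block structure: the whole span counts as exonic
                    candidates["exon"].append(g)
            ds = g.downstream(downstream_window)
            if ds is not None and ds.start <= center < ds.end:
                candidates["downstream"].append(g)
        chosen_feature = "distal_intergenic"
        chosen_gene: GeneModel | None = None
        for feature in FEATURE_PRIORITY[:-1]:
            if candidates[feature]:
                chosen_feature = feature
                chosen_gene = min(candidates[feature], key=lambda g: abs(center - g.tss))
                break
        annotations.append(FeatureAnnotation(
            peak=peak,
            feature=chosen_feature,
            gene_id=chosen_gene.gene_id if chosen_gene else None,
            distance_to_tss=(_signed_tss_distance(center, chosen_gene)
                             if chosen_gene else None),
        ))
    return annotations


def feature_counts(annotations: Sequence[FeatureAnnotation]) -> pd.DataFrame:
    """Category frequency table; counts sum to the number of peaks."""
    counts = {f: 0 for f in FEATURE_PRIORITY}
    for a in annotations:
        counts[a.feature] += 1
    total = len(annotations)
    return pd.DataFrame({
        "feature": list(counts),
        "count": list(counts.values()),
        "fraction": [c / total if total else float("nan") for c in counts.values()],
    })


def stage_retention(stage1: PeakSet, stage2: PeakSet, min_overlap: int = 1) -> dict:
    """Overlap-based retention of stage-1 peaks at stage 2.

    Each peak of each stage is labeled specific or overlapping; the headline
    retained fraction is directional (overlapping stage-1 peaks / stage-1
    total), with the reverse direction reported alongside.
    """
    if len(stage1) == 0 or len(stage2) == 0:
        raise ValueError("stage_retention requires two non-empty peak sets")
    s1 = stage1.sorted().with_label("stage1") if stage1.label == stage2.label else stage1.sorted()
    s2 = stage2.sorted().with_label("stage2") if stage1.label == stage2.label else stage2.sorted()
    part = overlap_classify([s1, s2], min_overlap=min_overlap)
    l1, l2 = s1.label, s2.label
    classes = []
    n_overlap1 = 0
    for iv, labs in zip(s1.intervals, part.labels[l1]):
        overlapping = l2 in labs
        n_overlap1 += overlapping
        classes.append(SiteClassification(
            iv, stage_status="overlapping" if overlapping else "stage1_specific"))
    n_overlap2 = 0
    for iv, labs in zip(s2.intervals, part.labels[l2]):
        overlapping = l1 in labs
        n_overlap2 += overlapping
        classes.append(SiteClassification(
            iv, stage_status="overlapping" if overlapping else "stage2_specific"))
    return {
        "classifications": classes,
        "retained_fraction": n_overlap1 / len(s1),
        "reverse_retained_fraction": n_overlap2 / len(s2),
        "n_stage1": len(s1),
        "n_stage2": len(s2),
        "n_stage1_overlapping": n_overlap1,
        "n_stage2_overlapping": n_overlap2,
    }


def core_noncore(control: PeakSet, perturbed: PeakSet,
                 min_overlap: int = 1) -> dict:
    """Split control peaks into core (retained under perturbation) and
    non-core (lost).  Core and non-core partition the control set exactly."""
    if len(control) == 0:
        raise ValueError("core_noncore requires a non-empty control set")
    ctl = control.sorted()
    classes: list[SiteClassification] = []
    n_core = 0
    if len(perturbed) == 0:
        flags = [False] * len(ctl)
    else:
        prt = perturbed.sorted()
        from .intervals import _peaks_overlapping
        flags = _peaks_overlapping(ctl.intervals, prt.intervals, min_overlap)
    for iv, hit in zip(ctl.intervals, flags):
        n_core += hit
        classes.append(SiteClassification(iv, core_status="core" if hit else "noncore"))
    return {
        "classifications": classes,
        "core_fraction": n_core / len(ctl),
        "n_control": len(ctl),
        "n_core": n_core,
        "n_noncore": len(ctl) - n_core,
    }


def genic_peak_genes(annotations: Sequence[FeatureAnnotation]) -> list[str]:
    """Unique ids of genes whose non-distal features carry at least one peak,
    in first-seen order (exportable for external GO tooling)."""
    seen: dict[str, None] = {}
    for a in annotations:
        if a.feature != "distal_intergenic" and a.gene_id is not None:
            seen.setdefault(a.gene_id, None)
    return list(seen)


def classification_table(classes: Sequence[SiteClassification]) -> pd.DataFrame:
    return pd.DataFrame([{
        "chrom": c.peak.chrom, "start": c.peak.start, "end": c.peak.end,
        "stage_status": c.stage_status, "core_status": c.core_status,
    } for c in classes])
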