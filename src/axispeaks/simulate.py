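"""Seeded synthetic scenarios with recorded ground truth.

Generates a GC-heterogeneous genome, non-overlapping gene models, repeat
families with planted peak-enrichment folds, a promoter-biased hypomethylated
peak landscape, a two-stage retention structure (early -> late meiotic
stage), a perturbation core/non-core split, and fragment-sampled coverage
tracks — everything the downstream statistics consume, with every planted
property recorded so recovery can be tested.

Determinism: all randomness flows from ``config.seed`` through named
``numpy.random.SeedSequence`` children, so identical config + seed gives
bit-identical outputs and each generation stage is independent of the others.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, replace
from typing import Sequence

import numpy as np
import yaml

from .genome_io import (
    CpGSiteTable,
    GeneModel,
    GenomeSequence,
    RepeatAnnotation,
)
from .intervals import ChromSizes, GenomicInterval, PeakSet
from .tracks import CoverageTrack, coverage_from_fragments, rpkm_normalize

import pandas as pd

__all__ = [
    "TEFamilyConfig",
    "ScenarioConfig",
    "GroundTruth",
    "Scenario",
    "generate_genome",
    "generate_annotations",
    "generate_methylome",
    "generate_peaks",
    "generate_coverage",
    "generate_gene_fragments",
    "generate_scenario",
]


@dataclass(frozen=True)
class TEFamilyConfig:
    """One repeat family: genome fraction to cover, planted peak-enrichment
    fold, element-length range and class label."""

    name: str
    te_class: str
    genome_fraction: float
    enrichment_fold: float = 1.0
    element_length: tuple[int, int] = (1500, 4000)


@dataclass(frozen=True)
class ScenarioConfig:
    """Parameters of one synthetic study.

    Defaults describe the emulated study conditions: a small GC-heterogeneous
    genome with one sex chromosome, promoter-biased peaks, ~70% stage
    retention, ~67% of peaks resistant to the assembly-dissolving
    perturbation, an Alu-like SINE family with a strong planted peak bias,
    and a mostly methylated background genome with hypomethylated promoters.
    """

    seed: int = 0
    n_chroms: int = 3
    chrom_length: int = 1_500_000
    sex_chrom_names: tuple[str, ...] = ("chrX",)
    sex_chrom_length: int = 750_000

    n_genes: int = 400
    gene_length_range: tuple[int, int] = (2_000, 10_000)

    te_families: tuple[TEFamilyConfig, ...] = (
        TEFamilyConfig("AluY", "SINE", 0.06, 5.0),
        TEFamilyConfig("DeuX", "SINE", 0.04, 3.0),
        TEFamilyConfig("L1Md", "LINE", 0.10, 1.0, (3000, 8000)),
        TEFamilyConfig("ERVK", "LTR", 0.05, 1.0),
    )

    n_peaks: int = 1000
    peak_width_lognorm: tuple[float, float] = (6.0, 0.40)  # ln-scale mu, sigma
    promoter_peak_fraction: float = 0.4
    retention_fraction: float = 0.70
    core_fraction: float = 0.67
    stage2_extra_fraction: float = 0.3  # de-novo stage-2 peaks, relative to n_peaks

    gc_background: float = 0.42
    peak_gc_boost: float = 0.15
    gc_boost_halfwidth: int = 300

    promoter_hypo_prob: float = 0.9
    promoter_meth_beta: tuple[float, float] = (1.0, 12.0)
    background_meth_beta: tuple[float, float] = (8.0, 2.0)
    cpg_coverage_mean: float = 10.0

    fragments_per_peak: float = 40.0
    fragment_length: int = 150
    background_fragment_rate: float = 2e-4  # fragments per bp of genome
    sex_intensity_boost: float = 2.0
    track_bin_size: int = 50

    def __post_init__(self) -> None:
        for name, frac in [
            ("promoter_peak_fraction", self.promoter_peak_fraction),
            ("retention_fraction", self.retention_fraction),
            ("core_fraction", self.core_fraction),
            ("gc_background", self.gc_background),
            ("promoter_hypo_prob", self.promoter_hypo_prob),
        ]:
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {frac}")
        te_total = sum(f.genome_fraction for f in self.te_families)
        if te_total > 0.6:
            raise ValueError(f"TE genome fractions sum to {te_total:.2f} > 0.6")
        planted = sum(f.enrichment_fold * f.genome_fraction for f in self.te_families)
        if planted > 1.0:
            raise ValueError(
                f"sum of fold x genome_fraction is {planted:.2f} > 1; the planted "
                "peak allocation is infeasible")

    @property
    def chrom_sizes(self) -> ChromSizes:
        sizes = {f"chr{i + 1}": self.chrom_length for i in range(self.n_chroms)}
        for name in self.sex_chrom_names:
            sizes[name] = self.sex_chrom_length
        return ChromSizes(sizes)

    def rng(self, stage: str) -> np.random.Generator:
        """Independent, named random stream for one generation stage."""
        digest = int.from_bytes(stage.encode(), "big") % (2**32)
        return np.random.default_rng(np.random.SeedSequence(entropy=self.seed,
                                                            spawn_key=(digest,)))

    @classmethod
    def from_yaml(cls, path) -> "ScenarioConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "ScenarioConfig":
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "seed" not in raw:
            raise ValueError("config must set a seed (seeds are never defaulted silently)")
        raw = dict(raw)
        if "te_families" in raw:
            fams = []
            for f in raw["te_families"]:
                if isinstance(f, dict):
                    if "element_length" in f:
                        f = {**f, "element_length": tuple(f["element_length"])}
                    fams.append(TEFamilyConfig(**f))
                else:
                    fams.append(f)
            raw["te_families"] = tuple(fams)
        for key in ("sex_chrom_names", "gene_length_range", "peak_width_lognorm",
                    "promoter_meth_beta", "background_meth_beta"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["te_families"] = [asdict(f) for f in self.te_families]
        return d


@dataclass
class GroundTruth:
    """Planted labels for every generated peak plus scenario-level truths."""

    peaks: pd.DataFrame  # peak_id, chrom, start, end, promoter, te_family,
                         # retained, core, compartment
    family_folds: dict[str, float]
    retention_fraction: float
    core_fraction: float
    promoter_peak_fraction: float
    or_body_scale: float | None = None

    def to_json(self, path) -> None:
        payload = {
            "peaks": self.peaks.to_dict(orient="list"),
            "family_folds": self.family_folds,
            "retention_fraction": self.retention_fraction,
            "core_fraction": self.core_fraction,
            "promoter_peak_fraction": self.promoter_peak_fraction,
            "or_body_scale": self.or_body_scale,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


# ---------------------------------------------------------------------------
# genome
# ---------------------------------------------------------------------------

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def generate_genome(config: ScenarioConfig,
                    gc_boost_centers: dict[str, np.ndarray] | None = None) -> GenomeSequence:
    """Random genome at the configured background GC.

    ``gc_boost_centers`` (chrom -> center positions) raises the per-base GC
    probability by ``peak_gc_boost`` within ``gc_boost_halfwidth`` of each
    center, planting the elevated GC the real peak landscape shows.
    """
    sizes = config.chrom_sizes
    if min(sizes.values()) < 10_000:
        raise ValueError("chromosomes must be >= 10 kb for flanked profiles")
    rng = config.rng("genome")
    seqs: dict[str, str] = {}
    for chrom, length in sizes.items():
        p_gc = np.full(length, config.gc_background)
        if gc_boost_centers and chrom in gc_boost_centers:
            for c in gc_boost_centers[chrom]:
                lo = max(0, int(c) - config.gc_boost_halfwidth)
                hi = min(length, int(c) + config.gc_boost_halfwidth)
                p_gc[lo:hi] = np.minimum(p_gc[lo:hi] + config.peak_gc_boost, 1.0)
        u = rng.random(length)
        is_gc = u < p_gc
        # within each class, pick the two bases evenly
        second = rng.random(length) < 0.5
        codes = np.where(is_gc, np.where(second, ord("G"), ord("C")),
                         np.where(second, ord("A"), ord("T")))
        seqs[chrom] = codes.astype(np.uint8).tobytes().decode("ascii")
    return GenomeSequence(seqs)


# ---------------------------------------------------------------------------
# annotations
# ---------------------------------------------------------------------------

def _place_nonoverlapping(rng: np.random.Generator, length: int, widths: Sequence[int],
                          occupied: list[tuple[int, int]], max_tries: int = 200) -> list[tuple[int, int]]:
    """Greedy rejection placement of widths into [0, length) avoiding
    ``occupied`` and each other."""
    placed: list[tuple[int, int]] = []
    taken = sorted(occupied)
    for w in widths:
        ok = False
        for _ in range(max_tries):
            s = int(rng.integers(0, max(1, length - w)))
            e = s + w
            if all(e <= ts or s >= te for ts, te in taken):
                ok = True
                break
        if not ok:
            raise ValueError("infeasible packing: could not place interval after retries")
        placed.append((s, e))
        taken.append((s, e))
        taken.sort()
    return placed


def _gene_structure(rng: np.random.Generator, start: int, end: int
                    ) -> tuple[tuple[tuple[int, int], ...], tuple[int, int]]:
    """Random exon blocks (first starts at the span start, last ends at the
    span end) and a CDS leaving terminal UTR stubs."""
    length = end - start
    n_exons = int(rng.integers(2, 6)) if length >= 2000 else 1
    if n_exons == 1:
        exons = ((start, end),)
    else:
        cuts = np.sort(rng.choice(np.arange(1, length), size=2 * (n_exons - 1),
                                  replace=False))
        bounds = np.concatenate([[0], cuts, [length]]) + start
        exons = tuple((int(bounds[2 * i]), int(bounds[2 * i + 1]))
                      for i in range(n_exons))
    utr5 = min(200, (exons[0][1] - exons[0][0]) // 2)
    utr3 = min(200, (exons[-1][1] - exons[-1][0]) // 2)
    cds = (exons[0][0] + utr5, exons[-1][1] - utr3)
    return exons, cds


def generate_annotations(config: ScenarioConfig, genome: GenomeSequence
                         ) -> tuple[list[GeneModel], RepeatAnnotation]:
    """Non-overlapping genes plus per-family TE intervals.

    Genes never overlap each other; TE elements never overlap other TEs (they
    may sit inside genes, as in real genomes).  Family footprints hit the
    configured genome fractions up to discretization of element counts.
    """
    sizes = genome.sizes
    rng = config.rng("annotations")
    chroms = list(sizes)
    genes: list[GeneModel] = []
    occupied_genes: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
    lengths = rng.integers(config.gene_length_range[0], config.gene_length_range[1] + 1,
                           size=config.n_genes)
    # genes share chromosomes proportionally to length
    weights = np.array([sizes[c] for c in chroms], dtype=float)
    weights /= weights.sum()
    gene_chroms = rng.choice(len(chroms), size=config.n_genes, p=weights)
    for i in range(config.n_genes):
        chrom = chroms[gene_chroms[i]]
        w = int(lengths[i])
        span = _place_nonoverlapping(rng, sizes[chrom], [w], occupied_genes[chrom])[0]
        occupied_genes[chrom].append(span)
        strand = "+" if rng.random() < 0.5 else "-"
        exons, cds = _gene_structure(rng, span[0], span[1])
        genes.append(GeneModel(f"gene{i:04d}", chrom, strand, span[0], span[1],
                               exons=exons, cds_start=cds[0], cds_end=cds[1]))

    te_rows = []
    occupied_tes: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
    for fam in config.te_families:
        target = fam.genome_fraction * sizes.genome_size
        placed_bp = 0
        counter = 0
        while placed_bp < target:
            w = int(rng.integers(fam.element_length[0], fam.element_length[1] + 1))
            chrom = chroms[int(rng.choice(len(chroms), p=weights))]
            span = _place_nonoverlapping(rng, sizes[chrom], [w], occupied_tes[chrom])[0]
            occupied_tes[chrom].append(span)
            te_rows.append({
                "chrom": chrom, "start": span[0], "end": span[1],
                "strand": "+" if rng.random() < 0.5 else "-",
                "element": f"{fam.name}_{counter}", "family": fam.name,
                "te_class": fam.te_class,
            })
            placed_bp += w
            counter += 1
    repeats = RepeatAnnotation(pd.DataFrame(
        te_rows, columns=["chrom", "start", "end", "strand", "element", "family", "te_class"]))
    return genes, repeats


# ---------------------------------------------------------------------------
# methylome
# ---------------------------------------------------------------------------

def generate_methylome(config: ScenarioConfig, genome: GenomeSequence,
                       genes: Sequence[GeneModel]) -> CpGSiteTable:
    """Per-CpG counts: hypomethylated promoters on a methylated background.

    Every genomic CpG receives strand-resolved counts: coverage is Poisson
    (``cpg_coverage_mean`` per strand, exercising the mincov filter) and the
    methylated count is Binomial at the site's level, drawn from the promoter
    beta with probability ``promoter_hypo_prob`` inside promoters and from
    the background beta elsewhere.
    """
    rng = config.rng("methylome")
    promoter_mask: dict[str, np.ndarray] = {
        c: np.zeros(length, dtype=bool) for c, length in genome.sizes.items()}
    for g in genes:
        p = g.promoter(genome.sizes)
        promoter_mask[g.chrom][p.start:p.end] = True
    rows = {"chrom": [], "pos": [], "strand": [], "meth": [], "total": []}
    for chrom in genome.chromosomes():
        seq = np.frombuffer(genome.sequence(chrom).encode("ascii"), dtype=np.uint8)
        cpg_pos = np.where((seq[:-1] == ord("C")) & (seq[1:] == ord("G")))[0]
        if len(cpg_pos) == 0:
            continue
        in_prom = promoter_mask[chrom][cpg_pos]
        use_prom = in_prom & (rng.random(len(cpg_pos)) < config.promoter_hypo_prob)
        a_p, b_p = config.promoter_meth_beta
        a_b, b_b = config.background_meth_beta
        levels = np.where(use_prom, rng.beta(a_p, b_p, size=len(cpg_pos)),
                          rng.beta(a_b, b_b, size=len(cpg_pos)))
        for strand, offset in (("+", 0), ("-", 1)):
            cov = rng.poisson(config.cpg_coverage_mean, size=len(cpg_pos))
            meth = rng.binomial(cov, levels)
            rows["chrom"].extend([chrom] * len(cpg_pos))
            rows["pos"].extend((cpg_pos + offset).tolist())
            rows["strand"].extend([strand] * len(cpg_pos))
            rows["meth"].extend(meth.tolist())
            rows["total"].extend(cov.tolist())
    table = pd.DataFrame(rows)
    if len(table):
        table = table.sort_values(["chrom", "pos", "strand"], kind="stable").reset_index(drop=True)
    return CpGSiteTable(table)


# ---------------------------------------------------------------------------
# peaks
# ---------------------------------------------------------------------------

def _sample_widths(rng: np.random.Generator, config: ScenarioConfig, n: int) -> np.ndarray:
    mu, sigma = config.peak_width_lognorm
    w = np.exp(rng.normal(mu, sigma, size=n))
    return np.maximum(w.astype(int), 50)


def _footprint_arrays(repeats: RepeatAnnotation, sizes: ChromSizes
                      ) -> dict[str, list[tuple[str, int, int]]]:
    """family -> list of (chrom, start, end) merged elements."""
    out = {}
    for fam in repeats.families:
        out[fam] = [(iv.chrom, iv.start, iv.end) for iv in repeats.family_footprint(fam)]
    return out


class _Occupancy:
    """Tracks placed peaks per chromosome, each expanded by a jitter margin
    (a quarter of its width), so later position jitter of <= width/4 can
    never create a spurious overlap between distinct peaks."""

    def __init__(self) -> None:
        self.spans: dict[str, list[tuple[int, int]]] = {}

    def free(self, chrom: str, start: int, end: int, margin: int) -> bool:
        lo, hi = start - margin, end + margin
        return all(hi <= s or lo >= e for s, e in self.spans.get(chrom, ()))

    def add(self, chrom: str, start: int, end: int, margin: int) -> None:
        self.spans.setdefault(chrom, []).append((start - margin, end + margin))


def _place_peak_inside(rng: np.random.Generator, spans: list[tuple[str, int, int]],
                       width: int, occupied: _Occupancy,
                       tries: int = 200) -> tuple[str, int, int] | None:
    """Place a peak fully inside one of ``spans`` (chosen length-weighted),
    avoiding already-occupied positions."""
    fitting = [(c, s, e) for c, s, e in spans if e - s >= width]
    if not fitting:
        return None
    lens = np.array([e - s - width + 1 for _, s, e in fitting], dtype=float)
    p = lens / lens.sum()
    margin = width // 4 + 1
    for _ in range(tries):
        idx = int(rng.choice(len(fitting), p=p))
        c, s, e = fitting[idx]
        start = int(rng.integers(s, e - width + 1))
        if occupied.free(c, start, start + width, margin):
            return c, start, start + width
    return None


def _place_with_shrink(rng: np.random.Generator, spans: list[tuple[str, int, int]],
                       width: int, occupied: _Occupancy
                       ) -> tuple[tuple[str, int, int] | None, int]:
    """Place a peak inside ``spans``, halving wide-tail widths (down to
    200 bp) when crowding leaves no room at the drawn width."""
    w = width
    for _ in range(6):
        placed = _place_peak_inside(rng, spans, w, occupied)
        if placed is not None:
            return placed, w
        if w <= 200:
            break
        w = max(200, int(w * 0.6))
    return None, w


def generate_peaks(config: ScenarioConfig, genes: Sequence[GeneModel],
                   repeats: RepeatAnnotation, sizes: ChromSizes
                   ) -> tuple[dict[str, PeakSet], GroundTruth]:
    """Stage-1/stage-2/control/perturbed peak sets with recorded truth.

    Placement per peak: with probability ``promoter_peak_fraction`` fully
    inside a random promoter; otherwise inside TE family f with probability
    fold_f x genome_fraction_f (peak fully inside one element, so the bp
    enrichment statistic recovers the fold among non-promoter peaks), else
    fully outside every TE footprint.  Peaks are mutually disjoint with a
    quarter-width safety margin so the jitter applied to stage-2 and
    perturbed copies cannot create overlaps with unrelated peaks — planted
    retention and core fractions are then recoverable to binomial accuracy.
    Stage 2 keeps a ``retention_fraction`` Bernoulli subset of stage 1
    (positions jittered by <= 25% of width, overlap with the original
    guaranteed) plus de-novo peaks placed clear of stage 1; the perturbed set
    keeps a ``core_fraction`` subset of the control peaks.
    """
    rng = config.rng("peaks")
    chroms = list(sizes)
    widths = _sample_widths(rng, config, config.n_peaks)
    footprints = _footprint_arrays(repeats, sizes)
    promoters = [g.promoter(sizes) for g in genes]
    prom_spans = [(p.chrom, p.start, p.end) for p in promoters]
    fam_probs = {f.name: f.enrichment_fold * f.genome_fraction for f in config.te_families}
    all_te = [span for spans in footprints.values() for span in spans]
    te_by_chrom: dict[str, list[tuple[int, int]]] = {}
    for c, s, e in all_te:
        te_by_chrom.setdefault(c, []).append((s, e))
    occupied = _Occupancy()
    chrom_w = np.array([sizes[c] for c in chroms], dtype=float)
    chrom_p = chrom_w / chrom_w.sum()

    peaks: list[GenomicInterval] = []
    truth_rows = []
    for i in range(config.n_peaks):
        w = int(widths[i])
        margin = w // 4 + 1
        is_prom = bool(rng.random() < config.promoter_peak_fraction) and bool(prom_spans)
        family = None
        placed = None
        if is_prom:
            placed, w = _place_with_shrink(rng, prom_spans, w, occupied)
            if placed is None:
                raise ValueError("demands exceed genome capacity: promoters are full")
            margin = w // 4 + 1
        if placed is None:
            is_prom = False
            u = rng.random()
            acc = 0.0
            for fam, pf in fam_probs.items():
                acc += pf
                if u < acc:
                    family = fam
                    break
            if family is not None:
                placed, w = _place_with_shrink(rng, footprints[family], w, occupied)
                if placed is None:
                    raise ValueError(
                        f"demands exceed genome capacity: family {family} footprint "
                        "cannot host another peak")
                margin = w // 4 + 1
            else:
                # background: fully outside every TE footprint
                for _ in range(500):
                    chrom = chroms[int(rng.choice(len(chroms), p=chrom_p))]
                    start = int(rng.integers(0, sizes[chrom] - w))
                    outside_te = all(start + w <= s or start >= e
                                     for s, e in te_by_chrom.get(chrom, ()))
                    if outside_te and occupied.free(chrom, start, start + w, margin):
                        placed = (chrom, start, start + w)
                        break
                if placed is None:
                    raise ValueError("demands exceed genome capacity: cannot place "
                                     "a background peak outside TE footprints")
        chrom, start, end = placed
        occupied.add(chrom, start, end, margin)
        peaks.append(GenomicInterval(chrom, start, end, name=f"peak{i:05d}"))
        truth_rows.append({
            "peak_id": f"peak{i:05d}", "chrom": chrom, "start": start, "end": end,
            "promoter": is_prom, "te_family": family,
            "compartment": "sex" if chrom in config.sex_chrom_names else "autosome",
        })

    truth = pd.DataFrame(truth_rows)
    retained = rng.random(config.n_peaks) < config.retention_fraction
    core = rng.random(config.n_peaks) < config.core_fraction
    truth["retained"] = retained
    truth["core"] = core

    def jitter(iv: GenomicInterval) -> GenomicInterval:
        max_shift = max(1, iv.width // 4)
        shift = int(rng.integers(-max_shift, max_shift + 1))
        start = max(0, min(iv.start + shift, sizes[iv.chrom] - iv.width))
        return GenomicInterval(iv.chrom, start, start + iv.width, name=iv.name)

    stage1 = PeakSet("stage1", list(peaks)).sorted()
    stage2_ivs = [jitter(iv) for iv, keep in zip(peaks, retained) if keep]
    n_extra = int(config.stage2_extra_fraction * config.n_peaks)
    extra_w = _sample_widths(rng, config, n_extra)
    s1_spans = [(iv.chrom, iv.start, iv.end) for iv in peaks]
    for j in range(n_extra):
        w = int(extra_w[j])
        for _ in range(500):
            chrom = chroms[int(rng.integers(0, len(chroms)))]
            start = int(rng.integers(0, sizes[chrom] - w))
            if all(c != chrom or start + w <= s or start >= e for c, s, e in s1_spans):
                stage2_ivs.append(GenomicInterval(chrom, start, start + w,
                                                  name=f"denovo{j:05d}"))
                break
    stage2 = PeakSet("stage2", stage2_ivs).sorted()
    control = PeakSet("control", list(peaks)).sorted()
    perturbed = PeakSet("perturbed",
                        [jitter(iv) for iv, keep in zip(peaks, core) if keep]).sorted()
    gt = GroundTruth(
        peaks=truth,
        family_folds={f.name: f.enrichment_fold for f in config.te_families},
        retention_fraction=float(retained.mean()),
        core_fraction=float(core.mean()),
        promoter_peak_fraction=float(truth["promoter"].mean()),
    )
    return ({"stage1": stage1, "stage2": stage2, "control": control,
             "perturbed": perturbed}, gt)


# ---------------------------------------------------------------------------
# coverage
# ---------------------------------------------------------------------------

def generate_coverage(config: ScenarioConfig, peaks: PeakSet, sizes: ChromSizes,
                      stream: str = "coverage", kernel: str = "triangular",
                      intensity: dict[str, float] | None = None) -> CoverageTrack:
    """Fragment-sampled RPKM track for one condition.

    Fragment centers are offset from peak centers by a triangular (default)
    or Gaussian kernel scaled to the peak half-width; each peak emits
    Poisson(``fragments_per_peak`` x multiplier) fragments, where the
    multiplier is ``intensity`` per peak name (falling back to the
    sex-chromosome boost for peaks on sex chromosomes).  Uniform background
    fragments are added at ``background_fragment_rate`` per bp.
    """
    if kernel not in ("triangular", "gaussian"):
        raise ValueError(f"unknown kernel {kernel!r}")
    rng = config.rng(stream)
    frag_len = config.fragment_length
    fragments: list[GenomicInterval] = []
    intensity = intensity or {}
    for iv in peaks.intervals:
        mult = intensity.get(iv.name if iv.name else "", None)
        if mult is None:
            mult = (config.sex_intensity_boost
                    if iv.chrom in config.sex_chrom_names else 1.0)
        n = rng.poisson(config.fragments_per_peak * mult)
        if n == 0:
            continue
        half = iv.width / 2
        if kernel == "triangular":
            offsets = rng.triangular(-half, 0, half, size=n)
        else:
            offsets = rng.normal(0, half / 2, size=n)
        centers = np.clip(iv.center + offsets, frag_len // 2,
                          sizes[iv.chrom] - frag_len // 2 - 1).astype(int)
        for c in centers:
            fragments.append(GenomicInterval(iv.chrom, int(c - frag_len // 2),
                                             int(c - frag_len // 2 + frag_len)))
    for chrom, length in sizes.items():
        n_bg = rng.poisson(config.background_fragment_rate * length)
        starts = rng.integers(0, max(1, length - frag_len), size=n_bg)
        for s in starts:
            fragments.append(GenomicInterval(chrom, int(s), int(s) + frag_len))
    if not fragments:
        raise ValueError("zero total fragments generated")
    raw = coverage_from_fragments(fragments, sizes, config.track_bin_size)
    track = rpkm_normalize(raw)
    return replace(track, source="synthetic")


def generate_gene_fragments(config: ScenarioConfig, genes: Sequence[GeneModel],
                            sizes: ChromSizes, stream: str = "genic",
                            promoter_fragments: float = 60.0,
                            body_fragments_per_kb: float = 15.0,
                            body_scale: float = 1.0) -> CoverageTrack:
    """Transcription-like coverage: promoter plus gene-body fragments.

    ``body_scale`` multiplies the body fragment rate only — the
    elongation-block scenario (``body_scale=0.5``) suppresses gene-body
    signal while promoter signal is preserved, which doubles the expected
    promoter/body occupancy ratio.
    """
    rng = config.rng(stream)
    frag_len = config.fragment_length
    fragments: list[GenomicInterval] = []
    for g in genes:
        prom = g.promoter(sizes)
        n_p = rng.poisson(promoter_fragments)
        if n_p:
            centers = rng.integers(prom.start, prom.end, size=n_p)
            fragments.extend(_clipped_fragments(g.chrom, centers, frag_len, sizes))
        body = g.body()
        if body is None:
            continue
        n_b = rng.poisson(body_fragments_per_kb * body.width / 1000 * body_scale)
        if n_b:
            centers = rng.integers(body.start, body.end, size=n_b)
            fragments.extend(_clipped_fragments(g.chrom, centers, frag_len, sizes))
    for chrom, length in sizes.items():
        n_bg = rng.poisson(config.background_fragment_rate * length)
        starts = rng.integers(0, max(1, length - frag_len), size=n_bg)
        fragments.extend(GenomicInterval(chrom, int(s), int(s) + frag_len) for s in starts)
    if not fragments:
        raise ValueError("zero total fragments generated")
    return replace(rpkm_normalize(coverage_from_fragments(fragments, sizes,
                                                          config.track_bin_size)),
                   source="synthetic")


def _clipped_fragments(chrom: str, centers: np.ndarray, frag_len: int,
                       sizes: ChromSizes) -> list[GenomicInterval]:
    out = []
    for c in centers:
        start = int(np.clip(c - frag_len // 2, 0, sizes[chrom] - frag_len))
        out.append(GenomicInterval(chrom, start, start + frag_len))
    return out


# ---------------------------------------------------------------------------
# full scenario
# ---------------------------------------------------------------------------

@dataclass
class Scenario:
    """Everything one synthetic study produces."""

    config: ScenarioConfig
    genome: GenomeSequence
    sizes: ChromSizes
    genes: list[GeneModel]
    repeats: RepeatAnnotation
    methylome: CpGSiteTable
    peaks: dict[str, PeakSet]
    tracks: dict[str, CoverageTrack]
    truth: GroundTruth


def generate_scenario(config: ScenarioConfig, with_genome: bool = True,
                      with_methylome: bool = True) -> Scenario:
    """Run every generation stage in order and bundle the outputs.

    The genome is generated with GC boosts planted at the final peak centers
    (annotation and peak placement need only chromosome sizes, so peaks are
    drawn first and the sequence second).
    """
    sizes = config.chrom_sizes
    proto = _SizesOnlyGenome(sizes)  # annotations and peaks need sizes only
    genes, repeats = generate_annotations(config, proto)
    peaks, truth = generate_peaks(config, genes, repeats, sizes)
    genome = None
    methylome = CpGSiteTable(pd.DataFrame(
        {"chrom": [], "pos": [], "strand": [], "meth": [], "total": []}))
    if with_genome:
        boost = {}
        for iv in peaks["control"].intervals:
            boost.setdefault(iv.chrom, []).append(iv.center)
        genome = generate_genome(config, {c: np.array(v) for c, v in boost.items()})
        if with_methylome:
            methylome = generate_methylome(config, genome, genes)
    tracks = {
        "control": generate_coverage(config, peaks["control"], sizes, stream="cov-control"),
        "perturbed": generate_coverage(config, peaks["perturbed"], sizes,
                                       stream="cov-perturbed"),
        "stage1": generate_coverage(config, peaks["stage1"], sizes, stream="cov-stage1"),
        "stage2": generate_coverage(config, peaks["stage2"], sizes, stream="cov-stage2"),
    }
    return Scenario(config=config, genome=genome, sizes=sizes, genes=genes,
                    repeats=repeats, methylome=methylome, peaks=peaks,
                    tracks=tracks, truth=truth)


class _SizesOnlyGenome:
    """Stands in for a GenomeSequence when only chromosome sizes are needed
    (annotation and peak placement are sequence-free)."""

    def __init__(self, sizes: ChromSizes):
        self.sizes = sizes

    def chromosomes(self) -> list[str]:
        return list(self.sizes)
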