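"""Readers and writers for the external formats the pipeline consumes.

Formats: BED3/BED6/narrowPeak, bedGraph, FASTA, a documented gene-model TSV,
a RepeatMasker-like repeat TSV and the Bismark-style per-cytosine report.
Coordinates are converted to the internal 0-based half-open convention at the
boundary; readers reject coordinate violations rather than clamping, and BED /
bedGraph round-trip bit-identically.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

from .intervals import ChromSizes, GenomicInterval, PeakSet, merge_within, sort_and_validate

__all__ = [
    "GeneModel",
    "GenomeSequence",
    "RepeatAnnotation",
    "CpGSiteTable",
    "read_bed",
    "write_bed",
    "read_bedgraph",
    "write_bedgraph",
    "read_fasta",
    "write_fasta",
    "read_gene_models",
    "write_gene_models",
    "read_repeat_annotation",
    "write_repeat_annotation",
    "read_cpg_report",
    "write_cpg_report",
    "destrand",
]

PROMOTER_FLANK = 1000  # bp either side of the TSS
BODY_OFFSET = 1000  # gene body starts this far downstream of the TSS

TE_CLASSES = ("SINE", "LINE", "LTR", "other")


# ---------------------------------------------------------------------------
# gene models
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneModel:
    """A strand-aware gene span stored canonically as start < end.

    The TSS is the strand-aware 5' end of the span, the TES the 3' end.  The
    promoter is TSS +/- 1 kb and the gene body runs from 1 kb downstream of
    the TSS (in the direction of transcription) to the TES; genes of span
    <= 1 kb have an empty body and are ineligible for promoter/body ratios.
    Optional exon blocks and a CDS span allow UTR-aware feature annotation.
    """

    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    exons: tuple[tuple[int, int], ...] | None = None
    cds_start: int | None = None
    cds_end: int | None = None
    biotype: str | None = None

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be + or -, got {self.strand!r}")
        if not 0 <= self.start < self.end:
            raise ValueError(f"gene {self.gene_id}: bad span [{self.start},{self.end})")
        if self.exons is not None:
            for s, e in self.exons:
                if not self.start <= s < e <= self.end:
                    raise ValueError(f"gene {self.gene_id}: exon [{s},{e}) outside span")

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end

    @property
    def tes(self) -> int:
        return self.end if self.strand == "+" else self.start

    @property
    def length(self) -> int:
        return self.end - self.start

    def promoter(self, sizes: ChromSizes | None = None, flank: int = PROMOTER_FLANK) -> GenomicInterval:
        lo = max(0, self.tss - flank)
        hi = self.tss + flank
        if sizes is not None and self.chrom in sizes:
            hi = min(hi, sizes[self.chrom])
        return GenomicInterval(self.chrom, lo, hi, name=self.gene_id, strand=self.strand)

    def body(self, offset: int = BODY_OFFSET) -> GenomicInterval | None:
        """Gene body from ``offset`` bp downstream of the TSS to the TES, or
        ``None`` for genes too short to have one."""
        if self.length <= offset:
            return None
        if self.strand == "+":
            return GenomicInterval(self.chrom, self.start + offset, self.end,
                                   name=self.gene_id, strand="+")
        return GenomicInterval(self.chrom, self.start, self.end - offset,
                               name=self.gene_id, strand="-")

    def downstream(self, window: int = 3000, sizes: ChromSizes | None = None) -> GenomicInterval | None:
        """Window of ``window`` bp immediately past the TES."""
        if self.strand == "+":
            lo, hi = self.end, self.end + window
        else:
            lo, hi = max(0, self.start - window), self.start
        if sizes is not None and self.chrom in sizes:
            hi = min(hi, sizes[self.chrom])
        if hi <= lo:
            return None
        return GenomicInterval(self.chrom, lo, hi, name=self.gene_id, strand=self.strand)


GENE_COLUMNS = ["gene_id", "chrom", "strand", "start", "end"]
OPTIONAL_GENE_COLUMNS = ["exon_starts", "exon_ends", "cds_start", "cds_end", "biotype"]


def read_gene_models(path) -> list[GeneModel]:
    """Read the documented gene-model TSV.

    Required columns: gene_id, chrom, strand, start, end (0-based half-open
    span).  Optional: exon_starts/exon_ends (comma-separated block lists),
    cds_start/cds_end, biotype.
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "gene_id": str})
    missing = [c for c in GENE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"gene-model file {path} missing columns: {missing}")
    genes = []
    for row in df.itertuples(index=False):
        exons = None
        if "exon_starts" in df.columns and isinstance(row.exon_starts, str) and row.exon_starts:
            starts = [int(x) for x in str(row.exon_starts).rstrip(",").split(",")]
            ends = [int(x) for x in str(row.exon_ends).rstrip(",").split(",")]
            exons = tuple(zip(starts, ends))
        cds_start = getattr(row, "cds_start", None)
        cds_end = getattr(row, "cds_end", None)
        cds_start = int(cds_start) if cds_start is not None and not pd.isna(cds_start) else None
        cds_end = int(cds_end) if cds_end is not None and not pd.isna(cds_end) else None
        biotype = getattr(row, "biotype", None)
        if biotype is not None and pd.isna(biotype):
            biotype = None
        genes.append(GeneModel(
            gene_id=str(row.gene_id), chrom=str(row.chrom), strand=str(row.strand),
            start=int(row.start), end=int(row.end), exons=exons,
            cds_start=cds_start, cds_end=cds_end, biotype=biotype,
        ))
    return genes


def write_gene_models(genes: Sequence[GeneModel], path) -> None:
    rows = []
    for g in genes:
        rows.append({
            "gene_id": g.gene_id, "chrom": g.chrom, "strand": g.strand,
            "start": g.start, "end": g.end,
            "exon_starts": ",".join(str(s) for s, _ in g.exons) if g.exons else "",
            "exon_ends": ",".join(str(e) for _, e in g.exons) if g.exons else "",
            "cds_start": "" if g.cds_start is None else g.cds_start,
            "cds_end": "" if g.cds_end is None else g.cds_end,
            "biotype": g.biotype or "",
        })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# genome sequence
# ---------------------------------------------------------------------------

class GenomeSequence:
    """Per-chromosome DNA held in memory, upper-cased; N is allowed."""

    def __init__(self, seqs: dict[str, str]):
        self._seqs = {name: s.upper() for name, s in seqs.items()}

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._seqs

    def chromosomes(self) -> list[str]:
        return list(self._seqs)

    @property
    def sizes(self) -> ChromSizes:
        return ChromSizes({c: len(s) for c, s in self._seqs.items()})

    def sequence(self, chrom: str) -> str:
        return self._seqs[chrom]

    def base(self, chrom: str, pos: int) -> str:
        return self._seqs[chrom][pos]

    def slice(self, chrom: str, start: int, end: int) -> str:
        return self._seqs[chrom][start:end]

    def gc_arrays(self) -> dict[str, tuple[np.ndarray, np.ndarray]]:
        """Per chromosome: (is_gc, is_acgt) uint8 arrays for window counting."""
        out = {}
        for chrom, s in self._seqs.items():
            arr = np.frombuffer(s.encode("ascii"), dtype=np.uint8)
            is_gc = ((arr == ord("G")) | (arr == ord("C"))).astype(np.uint8)
            is_known = ((arr == ord("A")) | (arr == ord("C"))
                        | (arr == ord("G")) | (arr == ord("T"))).astype(np.uint8)
            out[chrom] = (is_gc, is_known)
        return out


def read_fasta(path) -> GenomeSequence:
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seqs:
            raise ValueError(f"duplicate FASTA header {rec.id!r} in {path}")
        seqs[rec.id] = str(rec.seq)
    return GenomeSequence(seqs)


def write_fasta(genome: GenomeSequence, path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for chrom in genome.chromosomes():
            fh.write(f">{chrom}\n")
            s = genome.sequence(chrom)
            for i in range(0, len(s), width):
                fh.write(s[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# BED dialects
# ---------------------------------------------------------------------------

def _parse_bed_line(line: str, dialect: str, lineno: int) -> GenomicInterval:
    parts = line.rstrip("\n").split("\t")
    try:
        chrom, start, end = parts[0], int(parts[1]), int(parts[2])
        name = score = None
        strand = "."
        if dialect in ("bed6", "narrowPeak"):
            name = parts[3] if parts[3] != "." else None
            score = float(parts[4]) if parts[4] != "." else None
            strand = parts[5]
        return GenomicInterval(chrom, start, end, name=name, score=score, strand=strand)
    except (IndexError, ValueError) as exc:
        raise ValueError(f"malformed {dialect} line {lineno}: {line.rstrip()!r} ({exc})") from exc


def read_bed(path, dialect: str = "bed3", sizes: ChromSizes | None = None,
             label: str | None = None) -> PeakSet:
    """Read a BED3/BED6/narrowPeak file into a validated, sorted PeakSet.

    narrowPeak summit offsets (column 10) are preserved in
    ``metadata['summits']`` keyed by (chrom, start, end).
    """
    if dialect not in ("bed3", "bed6", "narrowPeak"):
        raise ValueError(f"unknown BED dialect {dialect!r}")
    intervals = []
    summits: dict[tuple, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            iv = _parse_bed_line(line, dialect, lineno)
            if dialect == "narrowPeak":
                parts = line.rstrip("\n").split("\t")
                if len(parts) < 10:
                    raise ValueError(f"narrowPeak line {lineno} has {len(parts)} columns, needs 10")
                summit = int(parts[9])
                if summit >= 0:
                    summits[(iv.chrom, iv.start, iv.end)] = summit
            intervals.append(iv)
    ps = PeakSet(label or Path(str(path)).stem, intervals)
    ps = sort_and_validate(ps, sizes)
    if summits:
        ps.metadata["summits"] = summits
    return ps


def write_bed(peaks: PeakSet, path, dialect: str = "bed3") -> None:
    """Write a PeakSet (sorted on output); BED3 and BED6 round-trip exactly."""
    if dialect not in ("bed3", "bed6", "narrowPeak"):
        raise ValueError(f"unknown BED dialect {dialect!r}")
    summits = peaks.metadata.get("summits", {})
    with open(path, "w") as fh:
        for iv in sorted(peaks.intervals, key=GenomicInterval.sort_key):
            if dialect == "bed3":
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")
                continue
            name = iv.name if iv.name is not None else "."
            score = "." if iv.score is None else format_number(iv.score)
            if dialect == "bed6":
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t{score}\t{iv.strand}\n")
            else:
                summit = summits.get((iv.chrom, iv.start, iv.end), -1)
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t{score}\t{iv.strand}"
                         f"\t0\t-1\t-1\t{summit}\n")


def format_number(x: float) -> str:
    """Integer-valued floats print without a trailing .0 (BED convention)."""
    return str(int(x)) if float(x).is_integer() else repr(float(x))


# ---------------------------------------------------------------------------
# bedGraph
# ---------------------------------------------------------------------------

def read_bedgraph(path, sizes: ChromSizes, bin_size: int = 1):
    """Read a bedGraph into a :class:`~axispeaks.tracks.CoverageTrack`.

    Records must be ascending and non-overlapping per chromosome; uncovered
    bases are 0.  With ``bin_size`` > 1 each record must align to bin
    boundaries (the piecewise-constant value is assigned per bin).
    """
    from .tracks import CoverageTrack  # local import to avoid a cycle

    values = {c: np.zeros(-(-length // bin_size)) for c, length in sizes.items()}
    last_end: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track")):
                continue
            parts = line.rstrip("\n").split("\t")
            try:
                chrom, start, end, value = parts[0], int(parts[1]), int(parts[2]), float(parts[3])
            except (IndexError, ValueError) as exc:
                raise ValueError(f"malformed bedGraph line {lineno}: {line.rstrip()!r}") from exc
            if chrom not in sizes:
                raise ValueError(f"bedGraph line {lineno}: unknown chromosome {chrom!r}")
            if not 0 <= start < end <= sizes[chrom]:
                raise ValueError(f"bedGraph line {lineno}: bad span [{start},{end})")
            if start < last_end.get(chrom, 0):
                raise ValueError(f"bedGraph line {lineno}: records overlap or are unsorted")
            last_end[chrom] = end
            if bin_size > 1 and (start % bin_size or end % bin_size and end != sizes[chrom]):
                raise ValueError(f"bedGraph line {lineno}: span not aligned to bin_size {bin_size}")
            values[chrom][start // bin_size: -(-end // bin_size)] = value
    return CoverageTrack(sizes=sizes, bin_size=bin_size, values=values,
                         normalization="raw", source="bedgraph")


def write_bedgraph(track, path) -> None:
    """Write a track as bedGraph runs; zero-valued runs are omitted."""
    with open(path, "w") as fh:
        for chrom in track.sizes:
            vals = track.values[chrom]
            length = track.sizes[chrom]
            b = track.bin_size
            start_bin = 0
            for i in range(1, len(vals) + 1):
                if i == len(vals) or vals[i] != vals[start_bin]:
                    v = vals[start_bin]
                    if v != 0:
                        lo = start_bin * b
                        hi = min(i * b, length)
                        fh.write(f"{chrom}\t{lo}\t{hi}\t{format_number(float(v))}\n")
                    start_bin = i


# ---------------------------------------------------------------------------
# repeat annotation
# ---------------------------------------------------------------------------

@dataclass
class RepeatAnnotation:
    """Repeat intervals tagged with element / family / class.

    ``table`` columns: chrom, start, end, strand, element, family, te_class.
    Per-family merged footprints are cached for enrichment scoring.
    """

    table: pd.DataFrame
    _family_footprints: dict[str, PeakSet] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        bad = ~self.table["te_class"].isin(TE_CLASSES)
        if bad.any():
            unknown = sorted(self.table.loc[bad, "te_class"].unique())
            warnings.warn(f"unknown TE class labels {unknown} mapped to 'other'")
            self.table = self.table.copy()
            self.table.loc[bad, "te_class"] = "other"
        fam_cls = self.table.groupby("family")["te_class"].nunique()
        if (fam_cls > 1).any():
            offenders = fam_cls[fam_cls > 1].index.tolist()
            raise ValueError(f"families mapped to multiple classes: {offenders}")

    def __len__(self) -> int:
        return len(self.table)

    @property
    def families(self) -> list[str]:
        return sorted(self.table["family"].unique())

    @property
    def classes(self) -> list[str]:
        return sorted(self.table["te_class"].unique())

    def family_class(self, family: str) -> str:
        return self.table.loc[self.table["family"] == family, "te_class"].iloc[0]

    def intervals(self, family: str | None = None, te_class: str | None = None) -> PeakSet:
        df = self.table
        label = "repeats"
        if family is not None:
            df = df[df["family"] == family]
            label = family
        if te_class is not None:
            df = df[df["te_class"] == te_class]
            label = te_class
        ivs = [GenomicInterval(r.chrom, int(r.start), int(r.end), name=r.element,
                               strand=r.strand)
               for r in df.itertuples(index=False)]
        return PeakSet(label, ivs).sorted()

    def family_footprint(self, family: str) -> PeakSet:
        """Merged (non-redundant) interval set of one family, cached."""
        if family not in self._family_footprints:
            self._family_footprints[family] = merge_within(self.intervals(family=family), 0)
        return self._family_footprints[family]

    def class_footprint(self, te_class: str) -> PeakSet:
        return merge_within(self.intervals(te_class=te_class), 0)

    def all_footprint(self) -> PeakSet:
        return merge_within(self.intervals(), 0)


REPEAT_COLUMNS = ["chrom", "start", "end", "strand", "element", "family", "te_class"]


def read_repeat_annotation(path) -> RepeatAnnotation:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = [c for c in REPEAT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"repeat file {path} missing columns: {missing}")
    if ((df["start"] < 0) | (df["start"] >= df["end"])).any():
        raise ValueError(f"repeat file {path} contains invalid coordinates")
    return RepeatAnnotation(df[REPEAT_COLUMNS].copy())


def write_repeat_annotation(repeats: RepeatAnnotation, path) -> None:
    repeats.table.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# CpG methylation
# ---------------------------------------------------------------------------

@dataclass
class CpGSiteTable:
    """Per-CpG methylated/total counts.

    ``table`` columns: chrom, pos (0-based position of the C), strand,
    meth, total.  ``destranded`` marks tables where symmetric CpGs have been
    combined onto the plus strand.
    """

    table: pd.DataFrame
    destranded: bool = False

    def __post_init__(self) -> None:
        t = self.table
        if ((t["meth"] < 0) | (t["total"] < 0)).any():
            raise ValueError("negative methylation counts")
        if (t["meth"] > t["total"]).any():
            raise ValueError("meth count exceeds total count")

    def __len__(self) -> int:
        return len(self.table)


def destrand(cpgs: CpGSiteTable) -> CpGSiteTable:
    """Combine symmetric CpG measurements onto the plus strand.

    A minus-strand C at position p reports the same CpG dinucleotide as the
    plus-strand C at p-1; counts are summed at the plus-strand position.
    Applying destrand to an already-destranded table is a no-op.
    """
    if cpgs.destranded:
        return cpgs
    t = cpgs.table.copy()
    minus = t["strand"] == "-"
    t.loc[minus, "pos"] = t.loc[minus, "pos"] - 1
    t["strand"] = "+"
    out = (t.groupby(["chrom", "pos"], as_index=False)
             .agg(meth=("meth", "sum"), total=("total", "sum")))
    out["strand"] = "+"
    out = out[["chrom", "pos", "strand", "meth", "total"]]
    out = out.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)
    return CpGSiteTable(out, destranded=True)


def read_cpg_report(path, apply_destrand: bool = True) -> CpGSiteTable:
    """Read a Bismark-style cytosine report.

    Columns: chrom, position (1-based), strand, count_methylated,
    count_unmethylated, context, trinucleotide.  Only CpG-context rows are
    retained; positions are converted to 0-based.  Destranding (on by
    default) mirrors the destrand=TRUE convention of methylKit.
    """
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["chrom", "pos1", "strand", "meth", "unmeth", "context", "tri"],
                     dtype={"chrom": str, "context": str})
    if ((df["meth"] < 0) | (df["unmeth"] < 0)).any():
        raise ValueError(f"negative counts in cytosine report {path}")
    df = df[df["context"] == "CG"].copy()
    df["pos"] = df["pos1"].astype(int) - 1
    df["total"] = df["meth"] + df["unmeth"]
    table = df[["chrom", "pos", "strand", "meth", "total"]].reset_index(drop=True)
    cpgs = CpGSiteTable(table)
    return destrand(cpgs) if apply_destrand else cpgs


def write_cpg_report(cpgs: CpGSiteTable, path) -> None:
    """Write the table back in cytosine-report layout (1-based positions)."""
    t = cpgs.table
    with open(path, "w") as fh:
        for row in t.itertuples(index=False):
            unmeth = int(row.total) - int(row.meth)
            fh.write(f"{row.chrom}\t{int(row.pos) + 1}\t{row.strand}\t{int(row.meth)}"
                     f"\t{unmeth}\tCG\tCGN\n")
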