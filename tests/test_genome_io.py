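"""Format readers/writers: round-trip fidelity, dialect handling, destranding."""

import numpy as np
import pandas as pd
import pytest

from axispeaks.genome_io import (
    CpGSiteTable,
    GeneModel,
    GenomeSequence,
    destrand,
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
from axispeaks.intervals import ChromSizes, GenomicInterval, PeakSet
from axispeaks.tracks import CoverageTrack


class TestBed:
    def test_read_bed3(self, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text("chr1\t0\t100\nchr1\t200\t300\n")
        ps = read_bed(p)
        assert [(iv.chrom, iv.start, iv.end) for iv in ps] == \
               [("chr1", 0, 100), ("chr1", 200, 300)]

    def test_empty_file(self, tmp_path):
        p = tmp_path / "e.bed"
        p.write_text("")
        assert len(read_bed(p)) == 0

    def test_invalid_span_reports_line(self, tmp_path):
        p = tmp_path / "bad.bed"
        p.write_text("chr1\t100\t50\n")
        with pytest.raises(ValueError, match="line 1"):
            read_bed(p)

    def test_bed6_round_trip(self, tmp_path):
        ps = PeakSet("x", [
            GenomicInterval("chr1", 0, 100, name="p1", score=5.5, strand="+"),
            GenomicInterval("chr2", 50, 80, name="p2", score=3.0, strand="-"),
        ]).sorted()
        p = tmp_path / "a.bed"
        write_bed(ps, p, dialect="bed6")
        back = read_bed(p, dialect="bed6")
        assert [(iv.chrom, iv.start, iv.end, iv.name, iv.score, iv.strand)
                for iv in back] == \
               [(iv.chrom, iv.start, iv.end, iv.name, iv.score, iv.strand)
                for iv in ps]

    def test_narrowpeak_summit_preserved(self, tmp_path):
        p = tmp_path / "a.narrowPeak"
        p.write_text("chr1\t100\t400\tpk1\t50\t.\t2.0\t-1\t-1\t75\n")
        ps = read_bed(p, dialect="narrowPeak")
        assert ps.metadata["summits"][("chr1", 100, 400)] == 75
        out = tmp_path / "b.narrowPeak"
        write_bed(ps, out, dialect="narrowPeak")
        assert read_bed(out, dialect="narrowPeak").metadata["summits"] == \
               ps.metadata["summits"]

    def test_random_round_trips_bit_identical(self, tmp_path, rng):
        for rep in range(10):
            n = int(rng.integers(1, 40))
            ivs = [GenomicInterval("chr1", int(s), int(s) + int(w),
                                   name=f"p{k}", score=float(int(rng.integers(0, 1000))),
                                   strand="+" if rng.random() < 0.5 else "-")
                   for k, (s, w) in enumerate(zip(rng.integers(0, 10_000, n),
                                                  rng.integers(1, 500, n)))]
            ps = PeakSet("r", ivs).sorted()
            p1, p2 = tmp_path / f"a{rep}.bed", tmp_path / f"b{rep}.bed"
            write_bed(ps, p1, dialect="bed6")
            write_bed(read_bed(p1, dialect="bed6"), p2, dialect="bed6")
            assert p1.read_bytes() == p2.read_bytes()


class TestBedGraph:
    def test_piecewise_values(self, tmp_path, sizes):
        p = tmp_path / "t.bedgraph"
        p.write_text("chr1\t0\t100\t2.0\n")
        track = read_bedgraph(p, sizes)
        assert track.values["chr1"][0] == 2.0
        assert track.values["chr1"][99] == 2.0
        assert track.values["chr1"][100] == 0.0
        assert track.values["chr2"].sum() == 0.0

    def test_empty_file_all_zero(self, tmp_path, sizes):
        p = tmp_path / "t.bedgraph"
        p.write_text("")
        assert read_bedgraph(p, sizes).genome_vector().sum() == 0

    def test_overlapping_records_rejected(self, tmp_path, sizes):
        p = tmp_path / "t.bedgraph"
        p.write_text("chr1\t0\t100\t1.0\nchr1\t50\t150\t2.0\n")
        with pytest.raises(ValueError, match="overlap"):
            read_bedgraph(p, sizes)

    def test_unknown_chromosome_rejected(self, tmp_path, sizes):
        p = tmp_path / "t.bedgraph"
        p.write_text("chrZ\t0\t100\t1.0\n")
        with pytest.raises(ValueError, match="unknown chromosome"):
            read_bedgraph(p, sizes)

    def test_round_trip_preserves_values_exactly(self, tmp_path, sizes, rng):
        values = {c: np.round(rng.random(n.item() if hasattr(n, 'item') else n), 6)
                  for c, n in (("chr1", 20_000), ("chr2", 20_000))}
        values["chr1"][rng.random(20_000) < 0.5] = 0.0
        track = CoverageTrack(sizes=sizes, bin_size=1, values=values)
        p1, p2 = tmp_path / "a.bedgraph", tmp_path / "b.bedgraph"
        write_bedgraph(track, p1)
        back = read_bedgraph(p1, sizes)
        for chrom in sizes:
            assert np.array_equal(back.values[chrom], track.values[chrom])
        write_bedgraph(back, p2)
        assert p1.read_bytes() == p2.read_bytes()


class TestFasta:
    def test_basic_access(self, tmp_path):
        p = tmp_path / "g.fa"
        p.write_text(">chr1\nACGT\n")
        g = read_fasta(p)
        assert g.sizes["chr1"] == 4
        assert g.base("chr1", 2) == "G"

    def test_lowercase_uppercased(self, tmp_path):
        p = tmp_path / "g.fa"
        p.write_text(">chr1\nacgtn\n")
        assert read_fasta(p).sequence("chr1") == "ACGTN"

    def test_multi_record_and_duplicate_header(self, tmp_path):
        p = tmp_path / "g.fa"
        p.write_text(">chr1\nAC\n>chr2\nGT\n")
        g = read_fasta(p)
        assert g.chromosomes() == ["chr1", "chr2"]
        bad = tmp_path / "dup.fa"
        bad.write_text(">chr1\nAC\n>chr1\nGT\n")
        with pytest.raises(ValueError, match="duplicate"):
            read_fasta(bad)

    def test_write_read_round_trip(self, tmp_path, rng):
        seq = "".join(rng.choice(list("ACGTN"), size=500))
        g = GenomeSequence({"chr1": seq})
        p = tmp_path / "g.fa"
        write_fasta(g, p)
        assert read_fasta(p).sequence("chr1") == seq


class TestGeneModels:
    def test_plus_strand_features(self):
        g = GeneModel("g1", "chr1", "+", 5000, 9000)
        assert g.tss == 5000 and g.tes == 9000
        prom = g.promoter()
        assert (prom.start, prom.end) == (4000, 6000)
        body = g.body()
        assert (body.start, body.end) == (6000, 9000)

    def test_minus_strand_features(self):
        g = GeneModel("g1", "chr1", "-", 5000, 9000)
        assert g.tss == 9000 and g.tes == 5000
        prom = g.promoter()
        assert (prom.start, prom.end) == (8000, 10_000)
        body = g.body()
        assert (body.start, body.end) == (5000, 8000)

    def test_short_gene_has_no_body(self):
        g = GeneModel("g1", "chr1", "+", 1000, 1800)
        assert g.body() is None

    def test_bad_strand_rejected(self):
        with pytest.raises(ValueError, match="strand"):
            GeneModel("g1", "chr1", ".", 0, 100)

    def test_tsv_round_trip(self, tmp_path):
        genes = [
            GeneModel("g1", "chr1", "+", 5000, 9000,
                      exons=((5000, 5500), (8000, 9000)), cds_start=5200, cds_end=8800),
            GeneModel("g2", "chr2", "-", 100, 4000),
        ]
        p = tmp_path / "genes.tsv"
        write_gene_models(genes, p)
        back = read_gene_models(p)
        assert back == genes

    def test_promoter_clipped_to_chromosome(self):
        g = GeneModel("g1", "chr1", "+", 200, 3000)
        prom = g.promoter(ChromSizes({"chr1": 2500}))
        assert (prom.start, prom.end) == (0, 1200)


class TestRepeatAnnotation:
    def _table(self, rows):
        return pd.DataFrame(rows, columns=["chrom", "start", "end", "strand",
                                           "element", "family", "te_class"])

    def test_read_and_classes(self, tmp_path):
        p = tmp_path / "rep.tsv"
        self._table([("chr1", 0, 300, "+", "AluY_1", "Alu", "SINE")]).to_csv(
            p, sep="\t", index=False)
        rep = read_repeat_annotation(p)
        assert rep.families == ["Alu"]
        assert rep.family_class("Alu") == "SINE"

    def test_unknown_class_mapped_to_other_with_warning(self, tmp_path):
        p = tmp_path / "rep.tsv"
        self._table([("chr1", 0, 300, "+", "X_1", "X", "Satellite")]).to_csv(
            p, sep="\t", index=False)
        with pytest.warns(UserWarning, match="other"):
            rep = read_repeat_annotation(p)
        assert rep.family_class("X") == "other"

    def test_overlapping_family_records_merge_in_footprint(self, tmp_path):
        p = tmp_path / "rep.tsv"
        self._table([("chr1", 0, 300, "+", "A_1", "Alu", "SINE"),
                     ("chr1", 200, 500, "-", "A_2", "Alu", "SINE")]).to_csv(
            p, sep="\t", index=False)
        rep = read_repeat_annotation(p)
        fp = rep.family_footprint("Alu")
        assert [(iv.start, iv.end) for iv in fp] == [(0, 500)]

    def test_round_trip(self, tmp_path):
        t = self._table([("chr1", 0, 300, "+", "A_1", "Alu", "SINE"),
                         ("chr2", 10, 50, "-", "L1_1", "L1", "LINE")])
        p = tmp_path / "rep.tsv"
        from axispeaks.genome_io import RepeatAnnotation
        write_repeat_annotation(RepeatAnnotation(t), p)
        assert read_repeat_annotation(p).table.equals(t)


class TestCpGReport:
    def _report(self, tmp_path, rows):
        p = tmp_path / "cpg.txt"
        p.write_text("".join(f"{c}\t{pos}\t{s}\t{m}\t{u}\t{ctx}\tCGN\n"
                             for c, pos, s, m, u, ctx in rows))
        return p

    def test_destrand_sums_symmetric_pair(self, tmp_path):
        # plus C at 1-based 101 pairs with minus C at 102
        p = self._report(tmp_path, [("chr1", 101, "+", 3, 7, "CG"),
                                    ("chr1", 102, "-", 2, 8, "CG")])
        cpgs = read_cpg_report(p)
        assert len(cpgs) == 1
        row = cpgs.table.iloc[0]
        assert (row["pos"], row["meth"], row["total"]) == (100, 5, 20)

    def test_non_cpg_context_skipped(self, tmp_path):
        p = self._report(tmp_path, [("chr1", 101, "+", 3, 7, "CG"),
                                    ("chr1", 50, "+", 5, 5, "CHG"),
                                    ("chr1", 60, "+", 5, 5, "CHH")])
        assert len(read_cpg_report(p)) == 1

    def test_zero_coverage_site_retained(self, tmp_path):
        p = self._report(tmp_path, [("chr1", 101, "+", 0, 0, "CG")])
        cpgs = read_cpg_report(p)
        assert len(cpgs) == 1 and cpgs.table.iloc[0]["total"] == 0

    def test_negative_counts_rejected(self, tmp_path):
        p = self._report(tmp_path, [("chr1", 101, "+", -1, 5, "CG")])
        with pytest.raises(ValueError, match="negative"):
            read_cpg_report(p)

    def test_destrand_is_idempotent(self, tmp_path, rng):
        rows = []
        for i in range(30):
            pos = 10 + 10 * i
            rows.append(("chr1", pos + 1, "+", int(rng.integers(0, 5)), 5, "CG"))
            rows.append(("chr1", pos + 2, "-", int(rng.integers(0, 5)), 5, "CG"))
        p = self._report(tmp_path, rows)
        once = read_cpg_report(p)
        twice = destrand(once)
        assert twice.table.equals(once.table)

    def test_report_round_trip(self, tmp_path):
        t = pd.DataFrame({"chrom": ["chr1", "chr1"], "pos": [100, 200],
                          "strand": ["+", "+"], "meth": [3, 9], "total": [10, 10]})
        cpgs = CpGSiteTable(t, destranded=True)
        p = tmp_path / "out.txt"
        write_cpg_report(cpgs, p)
        back = read_cpg_report(p)
        assert back.table[["chrom", "pos", "meth", "total"]].equals(
            t[["chrom", "pos", "meth", "total"]])

    def test_meth_exceeding_total_rejected(self):
        t = pd.DataFrame({"chrom": ["chr1"], "pos": [1], "strand": ["+"],
                          "meth": [5], "total": [3]})
        with pytest.raises(ValueError):
            CpGSiteTable(t)
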