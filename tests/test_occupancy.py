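"""Bespoke occupancy statistics: OR, TE enrichment, methylation tiling,
GC profiles, spacing/periodicity, intensity groups, compartments."""

import numpy as np
import pandas as pd
import pytest

from axispeaks.genome_io import CpGSiteTable, GeneModel, GenomeSequence, RepeatAnnotation
from axispeaks.intervals import ChromSizes, GenomicInterval, PeakSet
from axispeaks.occupancy import (
    compare_or,
    gc_profile,
    group_by_intensity,
    occupancy_by_methylation,
    occupancy_ratio,
    score_peaks,
    sex_autosome_comparison,
    spacing_periodicity,
    te_enrichment,
    te_family_signal,
    tile_methylome,
)
from axispeaks.tracks import coverage_from_fragments
from conftest import make_peaks
from test_tracks import uniform_track


def repeat_annotation(rows):
    return RepeatAnnotation(pd.DataFrame(
        rows, columns=["chrom", "start", "end", "strand", "element", "family",
                       "te_class"]))


GENES = [GeneModel("g1", "chr1", "+", 5000, 9000),
         GeneModel("g2", "chr1", "-", 11_000, 17_000),
         GeneModel("g3", "chr2", "+", 2000, 2800)]  # too short for a body


class TestOccupancyRatio:
    def test_uniform_track_gives_exactly_one(self, sizes):
        results = occupancy_ratio(uniform_track(sizes, 4.2), GENES)
        eligible = [r for r in results if r.eligible]
        assert len(eligible) == 2
        assert all(r.or_value == 1.0 for r in eligible)
        short = next(r for r in results if r.gene_id == "g3")
        assert not short.eligible and "1 kb" in short.reason

    def test_promoter_three_times_body(self, sizes):
        track = uniform_track(sizes, 1.0)
        g = GENES[0]
        prom = g.promoter()
        track.values["chr1"][prom.start // 50: prom.end // 50] = 3.0
        r = occupancy_ratio(track, [g])[0]
        assert r.or_value == pytest.approx(3.0)

    def test_zero_body_ineligible_without_pseudocount(self, sizes):
        track = uniform_track(sizes, 0.0)
        g = GENES[0]
        prom = g.promoter()
        track.values["chr1"][prom.start // 50: prom.end // 50] = 2.0
        r = occupancy_ratio(track, [g])[0]
        assert not r.eligible and r.reason == "zero body density"
        r2 = occupancy_ratio(track, [g], pseudocount=0.1)[0]
        assert r2.eligible and r2.or_value > 1

    def test_scale_invariance(self, sizes, rng):
        track = uniform_track(sizes, 0.0)
        track.values["chr1"][:] = rng.random(track.n_bins("chr1")) + 0.1
        base = occupancy_ratio(track, GENES[:2])
        scaled = occupancy_ratio(track.scaled(7.3), GENES[:2])
        for a, b in zip(base, scaled):
            assert a.or_value == pytest.approx(b.or_value)

    def test_discrete_fragments_match_per_base_oracle(self, sizes, rng):
        # per-base track (bin 1) against direct per-base fragment counting
        frags = [GenomicInterval("chr1", int(s), int(s) + 150)
                 for s in rng.integers(0, 19_000, size=300)]
        track = coverage_from_fragments(frags, sizes, bin_size=1)
        g = GENES[0]
        results = occupancy_ratio(track, [g])[0]
        cov = np.zeros(20_000)
        for f in frags:
            cov[f.start:f.end] += 1
        prom, body = g.promoter(), g.body()
        expected = cov[prom.start:prom.end].mean() / cov[body.start:body.end].mean()
        assert results.or_value == pytest.approx(expected)

    def test_empty_gene_set_rejected(self, sizes):
        with pytest.raises(ValueError):
            occupancy_ratio(uniform_track(sizes, 1.0), [])


class TestCompareOr:
    def _results(self, track, genes):
        return occupancy_ratio(track, genes)

    def test_identical_inputs_null(self, sizes, rng):
        track = uniform_track(sizes, 0.0)
        track.values["chr1"][:] = rng.random(track.n_bins("chr1")) + 0.5
        res = self._results(track, GENES[:2])
        shift = compare_or(res, res)
        assert shift["median_log2_shift"] == 0
        assert shift["p_value"] > 0.9

    def test_halved_body_doubles_or(self, sizes):
        genes = [GeneModel(f"g{i}", "chr1", "+", 1000 + i * 900, 1000 + i * 900 + 800)
                 for i in range(0)]  # placeholder, real genes below
        genes = [GeneModel(f"g{i}", "chr1", "+", s, s + 4000)
                 for i, s in enumerate(range(1000, 15_000, 5000))]
        before = uniform_track(sizes, 1.0)
        after = uniform_track(sizes, 1.0)
        for g in genes:
            body = g.body()
            after.values["chr1"][body.start // 50: body.end // 50] = 0.5
        shift = compare_or(self._results(before, genes), self._results(after, genes))
        assert np.allclose(shift["or_after"] / shift["or_before"], 2.0)
        assert shift["median_log2_shift"] == pytest.approx(1.0)
        assert shift["direction"] == "up"

    def test_no_shared_genes_rejected(self, sizes):
        track = uniform_track(sizes, 1.0)
        a = self._results(track, [GENES[0]])
        b = self._results(track, [GENES[1]])
        with pytest.raises(ValueError):
            compare_or(a, b)


class TestTEEnrichment:
    def test_definition_arithmetic(self):
        # genome 1e6; family covers 1e5; peaks 1e4 of which 5e3 in family -> 5.0
        sizes = ChromSizes({"chr1": 1_000_000})
        rep = repeat_annotation([("chr1", 0, 100_000, "+", "A_1", "Alu", "SINE")])
        peaks = make_peaks([("chr1", 95_000, 100_000), ("chr1", 500_000, 505_000)])
        enr = te_enrichment(peaks, rep, sizes)["Alu"]
        assert enr.bp_in_peaks == 5000
        assert enr.total_peak_width == 10_000
        assert enr.enrichment == pytest.approx(5.0)

    def test_family_absent_from_genome_undefined(self):
        sizes = ChromSizes({"chr1": 1_000_000})
        rep = repeat_annotation([("chr1", 0, 100, "+", "A_1", "Alu", "SINE")])
        rep.table = rep.table.iloc[:0]  # empty annotation for this family
        peaks = make_peaks([("chr1", 0, 1000)])
        out = te_enrichment(peaks, rep, sizes)
        assert out == {}

    def test_whole_genome_peaks_give_exactly_one(self):
        sizes = ChromSizes({"chr1": 100_000, "chr2": 50_000})
        rep = repeat_annotation([("chr1", 1000, 5000, "+", "A_1", "Alu", "SINE"),
                                 ("chr2", 0, 2000, "-", "A_2", "Alu", "SINE")])
        peaks = make_peaks([("chr1", 0, 100_000), ("chr2", 0, 50_000)])
        assert te_enrichment(peaks, rep, sizes)["Alu"].enrichment == pytest.approx(1.0)

    def test_class_level_pools_families(self):
        sizes = ChromSizes({"chr1": 100_000})
        rep = repeat_annotation([("chr1", 0, 1000, "+", "A_1", "Alu", "SINE"),
                                 ("chr1", 5000, 6000, "+", "B_1", "B1", "SINE")])
        peaks = make_peaks([("chr1", 0, 1000)])
        out = te_enrichment(peaks, rep, sizes, level="class")
        assert set(out) == {"SINE"}
        assert out["SINE"].bp_in_genome == 2000

    def test_empty_peaks_rejected(self):
        sizes = ChromSizes({"chr1": 1000})
        rep = repeat_annotation([("chr1", 0, 100, "+", "A", "Alu", "SINE")])
        with pytest.raises(ValueError):
            te_enrichment(PeakSet("x"), rep, sizes)


class TestTEFamilySignal:
    def test_uniform_track_scores_c(self, sizes):
        rep = repeat_annotation([("chr1", 0, 400, "+", "A_1", "Alu", "SINE"),
                                 ("chr2", 100, 600, "-", "L_1", "L1", "LINE")])
        out = te_family_signal(uniform_track(sizes, 2.5), rep)
        assert out == {"Alu": pytest.approx(2.5), "L1": pytest.approx(2.5)}

    def test_two_transcripts_length_weighting(self, sizes):
        track = uniform_track(sizes, 0.0)
        track.values["chr1"][0:2] = 4.0  # bases 0..100 density 4
        rep = repeat_annotation([("chr1", 0, 100, "+", "A_1", "Alu", "SINE"),
                                 ("chr1", 5000, 5300, "+", "A_2", "Alu", "SINE")])
        # (4*100 + 0*300) / 400 = 1.0
        assert te_family_signal(track, rep)["Alu"] == pytest.approx(1.0)

    def test_matches_per_base_oracle(self, sizes, rng):
        track = uniform_track(sizes, 0.0)
        per_base = {c: np.repeat(rng.random(400), 50) for c in sizes}
        for c in sizes:
            track.values[c][:] = per_base[c][::50]
        rows = []
        for k in range(12):
            c = "chr1" if k % 2 else "chr2"
            s = int(rng.integers(0, 19_000))
            rows.append((c, s, s + int(rng.integers(50, 900)), "+",
                         f"E_{k}", "Fam", "SINE"))
        rep = repeat_annotation(rows)
        got = te_family_signal(track, rep)["Fam"]
        num = sum(per_base[c][s:e].sum() for c, s, e, *_ in rows)
        den = sum(e - s for c, s, e, *_ in rows)
        assert got == pytest.approx(num / den)

    def test_consistency_with_footprint_density_for_disjoint_transcripts(self, sizes, rng):
        from axispeaks.tracks import region_mean_density
        track = uniform_track(sizes, 0.0)
        track.values["chr1"][:] = rng.random(400)
        rep = repeat_annotation([("chr1", 1000, 1500, "+", "A_1", "Alu", "SINE")])
        sig = te_family_signal(track, rep)["Alu"]
        fp = rep.family_footprint("Alu")
        assert sig == pytest.approx(region_mean_density(track, fp.intervals[0]))


class TestTileMethylome:
    def _cpgs(self, rows):
        t = pd.DataFrame(rows, columns=["chrom", "pos", "strand", "meth", "total"])
        return CpGSiteTable(t, destranded=True)

    def test_hand_built_report_classes_and_mincov(self, sizes):
        # 12 CpGs across 6 windows; window 5 has only a low-coverage site
        cpgs = self._cpgs([
            ("chr1", 100, "+", 3, 10), ("chr1", 200, "+", 2, 10),    # 5/20 = 0.25
            ("chr1", 1100, "+", 9, 10), ("chr1", 1200, "+", 6, 10),  # 15/20 = 0.75
            ("chr1", 2100, "+", 1, 10), ("chr1", 2200, "+", 1, 10),  # 0.10 hypo
            ("chr1", 3100, "+", 9, 10), ("chr1", 3200, "+", 9, 10),  # 0.90 hyper
            ("chr1", 4100, "+", 1, 2),                               # below mincov
            ("chr1", 4200, "+", 5, 10),                              # 0.50 alone
            ("chr1", 4300, "+", 0, 0),                               # zero coverage
            ("chr1", 5100, "+", 2, 2),                               # below mincov
        ])
        tiles = tile_methylome(cpgs, sizes, win=1000, step=1000, mincov=3)
        by_start = {t.window.start: t for t in tiles}
        assert sorted(by_start) == [0, 1000, 2000, 3000, 4000]  # window 5 omitted
        assert by_start[0].level == pytest.approx(0.25)
        assert by_start[0].klass == "intermediate"      # boundary: not < 0.25
        assert by_start[1000].level == pytest.approx(0.75)
        assert by_start[1000].klass == "intermediate"   # boundary: not > 0.75
        assert by_start[2000].klass == "hypo"
        assert by_start[3000].klass == "hyper"
        assert by_start[4000].n_sites == 1 and by_start[4000].klass == "intermediate"

    @pytest.mark.parametrize("level,klass", [(0.10, "hypo"), (0.50, "intermediate"),
                                             (0.90, "hyper")])
    def test_threshold_classes(self, sizes, level, klass):
        cpgs = self._cpgs([("chr1", 10, "+", int(level * 100), 100)])
        tiles = tile_methylome(cpgs, sizes)
        assert tiles[0].klass == klass

    def test_overlapping_tiling_unsupported(self, sizes):
        with pytest.raises(ValueError):
            tile_methylome(self._cpgs([("chr1", 10, "+", 1, 10)]), sizes,
                           win=1000, step=500)


class TestOccupancyByMethylation:
    def _tiles(self, sizes):
        cpgs = CpGSiteTable(pd.DataFrame({
            "chrom": ["chr1"] * 6,
            "pos": [100, 1100, 2100, 3100, 4100, 5100],
            "strand": ["+"] * 6,
            "meth": [0, 1, 0, 9, 10, 9],
            "total": [10, 10, 10, 10, 10, 10]}), destranded=True)
        return tile_methylome(cpgs, sizes)

    def test_identical_density_p_near_one(self, sizes):
        out = occupancy_by_methylation(uniform_track(sizes, 2.0), self._tiles(sizes))
        assert out["p_value"] > 0.9

    def test_planted_hypo_enrichment_detected(self, sizes):
        track = uniform_track(sizes, 1.0)
        track.values["chr1"][0:60] = 10.0  # covers the hypo tiles (0-3000)
        out = occupancy_by_methylation(track, self._tiles(sizes))
        assert out["medians"]["hypo"] > out["medians"]["hyper"]
        assert out["statistic"] > 0

    def test_planted_direction_recovered_across_replicates(self, sizes):
        # 20 seeded replicates with noisy tracks: sign always correct
        for rep in range(20):
            rng = np.random.default_rng(1000 + rep)
            track = uniform_track(sizes, 0.0)
            track.values["chr1"][:] = rng.random(400)
            track.values["chr1"][0:70] += 3.0
            out = occupancy_by_methylation(track, self._tiles(sizes))
            assert out["medians"]["hypo"] > out["medians"]["hyper"]

    def test_empty_class_rejected(self, sizes):
        cpgs = CpGSiteTable(pd.DataFrame({
            "chrom": ["chr1"], "pos": [100], "strand": ["+"],
            "meth": [0], "total": [10]}), destranded=True)
        tiles = tile_methylome(cpgs, sizes)
        with pytest.raises(ValueError):
            occupancy_by_methylation(uniform_track(sizes, 1.0), tiles)


class TestGcProfile:
    def test_all_g_genome_is_one_everywhere(self):
        g = GenomeSequence({"chr1": "G" * 20_000})
        peaks = make_peaks([("chr1", 5000, 5400), ("chr1", 9000, 9200)])
        prof = gc_profile(g, peaks)
        assert np.allclose(prof["mean_gc"], 1.0)

    def test_acgt_periodic_genome_is_half(self):
        g = GenomeSequence({"chr1": "ACGT" * 5000})
        peaks = make_peaks([("chr1", 5000, 5400)])
        prof = gc_profile(g, peaks, window=100)
        assert np.allclose(prof["mean_gc"], 0.5)

    def test_matches_direct_counting_oracle(self, rng):
        from oracles import gc_window_oracle
        seq = "".join(rng.choice(list("ACGTN"), size=30_000, p=[.3, .2, .2, .25, .05]))
        g = GenomeSequence({"chr1": seq})
        peaks = make_peaks([("chr1", 4000, 4500), ("chr1", 12_000, 12_800)])
        prof = gc_profile(g, peaks, flank=500, window=100, step=50)
        for _, row in prof.iterrows():
            per_peak = [gc_window_oracle(seq, iv.center + int(row["offset"]), 100)
                        for iv in peaks]
            per_peak = [x for x in per_peak if x is not None]
            assert row["mean_gc"] == pytest.approx(np.mean(per_peak))

    def test_n_bases_excluded(self):
        g = GenomeSequence({"chr1": "G" * 10_000 + "N" * 100 + "G" * 9_900})
        peaks = make_peaks([("chr1", 9950, 10_150)])  # center at the N block edge
        prof = gc_profile(g, peaks, flank=200, window=100, step=10)
        assert np.allclose(prof["mean_gc"].dropna(), 1.0)


class TestSpacingPeriodicity:
    def test_perfect_comb_detected(self):
        peaks = make_peaks([("chr1", c - 50, c + 50) for c in range(5000, 105_000, 1000)])
        res = spacing_periodicity(peaks, bin=100, max_lag=5000, n_perm=500, seed=7)
        assert res.p_value < 0.05
        assert res.period_estimate is not None
        assert abs(res.period_estimate - 1000) <= 100  # within one bin

    def test_two_peaks_rejected(self):
        with pytest.raises(ValueError):
            spacing_periodicity(make_peaks([("chr1", 0, 100), ("chr1", 500, 600)]),
                                seed=1)

    def test_seed_mandatory(self):
        peaks = make_peaks([("chr1", i * 1000, i * 1000 + 100) for i in range(20)])
        with pytest.raises(ValueError, match="seed"):
            spacing_periodicity(peaks)

    def test_poisson_placement_usually_not_significant(self):
        rng = np.random.default_rng(42)
        hits = 0
        n_rep = 30
        for _ in range(n_rep):
            starts = np.sort(rng.integers(0, 295_000, size=60))
            peaks = make_peaks([("chr1", int(s), int(s) + 100) for s in starts])
            res = spacing_periodicity(peaks, bin=100, max_lag=5000, n_perm=200,
                                      seed=int(rng.integers(0, 2**31)))
            hits += res.p_value < 0.05
            assert res.period_estimate is None or res.p_value < 0.05
        # type-I control: alpha + 2*SE bound at this replicate count
        assert hits / n_rep <= 0.05 + 2 * np.sqrt(0.05 * 0.95 / n_rep)

    def test_gap_shuffle_null_available(self):
        starts = np.sort(np.random.default_rng(5).integers(0, 95_000, size=40))
        peaks = make_peaks([("chr1", int(s), int(s) + 100) for s in starts])
        res = spacing_periodicity(peaks, bin=100, max_lag=3000, n_perm=100, seed=3,
                                  null="shuffle_gaps")
        assert 0 < res.p_value <= 1


class TestGroupByIntensity:
    def _scored(self, scores):
        ivs = [GenomicInterval("chr1", i * 1000, i * 1000 + 100, score=float(s))
               for i, s in enumerate(scores)]
        return PeakSet("p", ivs).sorted()

    def test_nine_peaks_equal_groups(self):
        groups = group_by_intensity(self._scored(range(9)))
        assert [len(groups[k]) for k in ("high", "intermediate", "low")] == [3, 3, 3]
        assert all(iv.score >= 6 for iv in groups["high"])
        assert all(iv.score <= 2 for iv in groups["low"])

    def test_ten_peaks_remainder_to_top(self):
        groups = group_by_intensity(self._scored(range(10)))
        assert [len(groups[k]) for k in ("high", "intermediate", "low")] == [4, 3, 3]

    def test_unscored_rejected(self):
        ps = make_peaks([("chr1", 0, 100), ("chr1", 500, 600), ("chr1", 900, 999)])
        with pytest.raises(ValueError, match="scored"):
            group_by_intensity(ps)

    def test_planted_construction_recovered(self, sizes):
        track = uniform_track(sizes, 0.0)
        spans, expect = [], {}
        for i, (lo, label) in enumerate([(100, "high"), (10, "intermediate"),
                                         (1, "low")]):
            for j in range(4):
                s = (i * 4 + j) * 1200
                track.values["chr1"][s // 50: (s + 600) // 50] = lo + i * 4 + j
                spans.append(("chr1", s, s + 600))
                expect[(s, s + 600)] = label
        peaks = score_peaks(track, make_peaks(spans))
        groups = group_by_intensity(peaks)
        for label, ps in groups.items():
            for iv in ps:
                assert expect[(iv.start, iv.end)] == label


class TestSexAutosome:
    def test_all_autosomal(self, sizes):
        track = uniform_track(sizes, 1.0)
        with pytest.warns(UserWarning, match="compartment"):
            out = sex_autosome_comparison(track, make_peaks([("chr1", 0, 100)]),
                                          ["chr2"])
        assert out["sex_fraction"] == 0.0
        assert np.isnan(out["p_value"])

    def test_fraction_exact(self, sizes):
        spans = [("chr1", i * 150, i * 150 + 100) for i in range(98)]
        spans += [("chr2", 0, 100), ("chr2", 500, 600)]
        out = sex_autosome_comparison(uniform_track(sizes, 1.0),
                                      make_peaks(spans), ["chr2"])
        assert out["n_sex"] == 2 and out["n_total"] == 100
        assert out["sex_fraction"] == pytest.approx(0.02)

    def test_planted_boost_direction_recovered(self, sizes, rng):
        track = uniform_track(sizes, 0.0)
        track.values["chr1"][:] = rng.random(400) + 1
        track.values["chr2"][:] = (rng.random(400) + 1) * 2
        spans = [("chr1", i * 500, i * 500 + 200) for i in range(30)]
        spans += [("chr2", i * 500, i * 500 + 200) for i in range(30)]
        out = sex_autosome_comparison(track, make_peaks(spans), ["chr2"])
        assert out["median_sex"] > out["median_autosome"]
        assert out["p_value"] < 0.05

    def test_unknown_sex_chrom_rejected(self, sizes):
        with pytest.raises(ValueError):
            sex_autosome_comparison(uniform_track(sizes, 1.0),
                                    make_peaks([("chr1", 0, 100)]), ["chrY"])
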