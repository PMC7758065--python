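import numpy as np
import pandas as pd
import pytest

from _oracles import count_window_overlaps_bruteforce, shared_flags_bruteforce
from ambint.atac import (
    PeakSet,
    ReadSet,
    annotate_peaks_to_genes,
    classify_accessibility,
    peak_set_compare,
    read_peaks,
    read_reads_bed,
    relative_accessibility,
    select_tissue_enriched,
    tss_metaprofile,
    tss_window_rpkm,
    write_peaks,
    write_reads_bed,
)
from ambint.expr_io import GeneModel, GeneModelSet, ValidationError
from ambint.markers import GeneSet


def _reads(intervals, library_size=None):
    df = pd.DataFrame(intervals, columns=["chrom", "start", "end"])
    return ReadSet(df, library_size=library_size)


def _gene(gid, tss, strand="+", chrom="c"):
    if strand == "+":
        return GeneModel(gid, chrom, "+", tss, tss + 1000, ((tss, tss + 1000),))
    return GeneModel(gid, chrom, "-", tss - 1000, tss, ((tss - 1000, tss),))


class TestTssWindowRpkm:
    def test_closed_form(self):
        reads = _reads([("c", 9900, 9950)] * 10, library_size=1_000_000)
        models = GeneModelSet([_gene("g", 10_000)])
        t = tss_window_rpkm(reads, models, halfwidth=250)
        assert t.loc["g", "read_count"] == 10
        assert t.loc["g", "rpkm"] == pytest.approx(20.0)

    def test_zero_reads(self):
        reads = _reads([("c", 0, 50)], library_size=1_000_000)
        models = GeneModelSet([_gene("g", 10_000)])
        assert tss_window_rpkm(reads, models).loc["g", "rpkm"] == 0.0

    def test_absent_chromosome_counts_zero(self):
        reads = _reads([("other", 0, 50)])
        models = GeneModelSet([_gene("g", 10_000)])
        assert tss_window_rpkm(reads, models).loc["g", "read_count"] == 0

    def test_counts_match_bruteforce(self, rng):
        intervals = [
            ("c", int(s), int(s) + int(l))
            for s, l in zip(rng.integers(0, 50_000, 500), rng.integers(1, 300, 500))
        ]
        reads = _reads(intervals)
        models = GeneModelSet(
            [_gene(f"g{i}", int(t)) for i, t in
             enumerate(rng.integers(1000, 49_000, 50))]
        )
        t = tss_window_rpkm(reads, models, halfwidth=250)
        for g in models:
            expected = count_window_overlaps_bruteforce(
                intervals, "c", g.tss - 250, g.tss + 250
            )
            assert t.loc[g.gene_id, "read_count"] == expected

    def test_rpkm_scales_inversely_with_library(self):
        intervals = [("c", 9900, 9950)] * 8
        models = GeneModelSet([_gene("g", 10_000)])
        full = tss_window_rpkm(_reads(intervals, library_size=2_000_000), models)
        half = tss_window_rpkm(_reads(intervals, library_size=1_000_000), models)
        assert half.loc["g", "rpkm"] == pytest.approx(2 * full.loc["g", "rpkm"])


class TestClassifyAccessibility:
    def _table(self, rpkms):
        return pd.DataFrame(
            {"rpkm": rpkms, "label": pd.NA},
            index=[f"g{i}" for i in range(len(rpkms))],
        )

    @pytest.mark.parametrize(
        "rpkm,label",
        [(1.2, "closed"), (5.0, "open"), (2.0, "indeterminate"),
         (1.5, "indeterminate"), (3.0, "indeterminate")],
    )
    def test_thresholds(self, rpkm, label):
        t = classify_accessibility(self._table([rpkm]))
        assert t["label"].iloc[0] == label

    def test_log2_scale(self):
        t = classify_accessibility(
            self._table([16.0, 1.0]), closed_max=3.0, open_min=3.5, scale="log2_rpkm"
        )
        assert list(t["label"]) == ["open", "closed"]

    def test_threshold_inversion_rejected(self):
        with pytest.raises(ValidationError):
            classify_accessibility(self._table([1.0]), closed_max=3.0, open_min=1.5)


class TestMetaprofile:
    def test_spike_at_tss(self):
        models = GeneModelSet([_gene("g", 10_000)])
        reads = _reads([("c", 10_000, 10_050)] * 5, library_size=1_000_000)
        prof = tss_metaprofile(reads, GeneSet(("g",)), models)
        spike = prof[prof["mean_signal"] > 0]
        assert len(spike) == 1
        assert spike["bin_offset"].iloc[0] == 0

    def test_minus_strand_flipped(self):
        models = GeneModelSet([_gene("g", 10_000, strand="-")])
        # reads 100 bp genomically left of the TSS = downstream for '-'
        reads = _reads([("c", 9900, 9950)] * 3, library_size=1_000_000)
        prof = tss_metaprofile(reads, GeneSet(("g",)), models)
        spike = prof[prof["mean_signal"] > 0]
        assert spike["bin_offset"].iloc[0] == 100

    def test_uniform_reads_flat(self, rng):
        models = GeneModelSet([_gene("g", 50_000)])
        n = 40_000
        starts = rng.integers(0, 100_000, size=n)
        reads = _reads([("c", int(s), int(s) + 50) for s in starts])
        prof = tss_metaprofile(reads, GeneSet(("g",)), models, flank=2000, binsize=50)
        # Poisson expectation per bin: n * 50 / 100000 = 20 raw counts
        raw = prof["mean_signal"] * (reads.library_size / 1e6)
        lam = n * 50 / 100_000
        assert (np.abs(raw - lam) < 4 * np.sqrt(lam)).all()

    def test_pooled_equals_weighted_mean(self, rng):
        models = GeneModelSet([_gene("g", 10_000)])
        gs = GeneSet(("g",))
        i1 = [("c", int(s), int(s) + 50) for s in rng.integers(8000, 12_000, 200)]
        i2 = [("c", int(s), int(s) + 50) for s in rng.integers(8000, 12_000, 600)]
        p1 = tss_metaprofile(_reads(i1), gs, models)
        p2 = tss_metaprofile(_reads(i2), gs, models)
        pooled = tss_metaprofile(_reads(i1 + i2), gs, models)
        w1, w2 = len(i1), len(i2)
        # per-million scaling makes the pooled profile the read-count-weighted mean
        expected = (p1["mean_signal"] * w1 + p2["mean_signal"] * w2) / (w1 + w2)
        np.testing.assert_allclose(pooled["mean_signal"], expected, rtol=1e-9)

    def test_empty_gene_set_rejected(self):
        models = GeneModelSet([_gene("g", 10_000)])
        with pytest.raises(ValidationError):
            tss_metaprofile(_reads([("c", 0, 50)]), GeneSet(()), models)


class TestRelativeAccessibility:
    def _table(self, d):
        return pd.DataFrame({"rpkm": pd.Series(d)})

    def test_geometric_mean(self):
        t = self._table({"g": 8.0, "hk1": 4.0, "hk2": 16.0})
        assert relative_accessibility(t, "g", GeneSet(("hk1", "hk2"))) == pytest.approx(1.0)

    def test_zero_gene(self):
        t = self._table({"g": 0.0, "hk1": 2.0})
        assert relative_accessibility(t, "g", GeneSet(("hk1",))) == 0.0

    def test_zero_housekeeping_rejected(self):
        t = self._table({"g": 1.0, "hk1": 0.0})
        with pytest.raises(ValidationError, match="hk1"):
            relative_accessibility(t, "g", GeneSet(("hk1",)))

    def test_matches_direct_recomputation(self, rng):
        vals = {f"g{i}": float(v) for i, v in enumerate(rng.random(20) * 10 + 0.1)}
        t = self._table(vals)
        hk = GeneSet(("g0", "g1", "g2"))
        got = relative_accessibility(t, "g7", hk)
        expected = vals["g7"] / (vals["g0"] * vals["g1"] * vals["g2"]) ** (1 / 3)
        assert got == pytest.approx(expected, rel=1e-12)


class TestSelectTissueEnriched:
    def _expr(self, rows):
        return pd.DataFrame(rows, columns=["heart", "brain", "lung"],
                            index=[f"g{i}" for i in range(len(rows))])

    def test_enriched_selected(self):
        gs = select_tissue_enriched(self._expr([[20, 5, 8]]), "heart", ["brain", "lung"])
        assert list(gs) == ["g0"]

    def test_fold_rule_excludes(self):
        gs = select_tissue_enriched(self._expr([[20, 15, 1]]), "heart", ["brain", "lung"])
        assert len(gs) == 0

    def test_baseline_rule_excludes(self):
        gs = select_tissue_enriched(self._expr([[9, 1, 1]]), "heart", ["brain", "lung"])
        assert len(gs) == 0

    def test_empty_others_rejected(self):
        with pytest.raises(ValidationError):
            select_tissue_enriched(self._expr([[20, 5, 8]]), "heart", [])


class TestPeakSetCompare:
    def _peaks(self, intervals):
        return PeakSet(pd.DataFrame(intervals, columns=["chrom", "start", "end"]))

    def test_overlapping_shared(self):
        res = peak_set_compare(self._peaks([("c", 0, 100)]), self._peaks([("c", 50, 150)]))
        assert len(res["shared_a"]) == 1 and len(res["shared_b"]) == 1
        assert len(res["unique_a"]) == 0 and len(res["unique_b"]) == 0

    def test_disjoint_unique(self):
        res = peak_set_compare(self._peaks([("c", 0, 100)]), self._peaks([("c", 200, 300)]))
        assert len(res["unique_a"]) == 1 and len(res["unique_b"]) == 1

    def test_partition_and_bruteforce(self, rng):
        def random_peaks(n):
            rows = []
            for _ in range(n):
                chrom = str(rng.choice(["c1", "c2"]))
                s = int(rng.integers(0, 20_000))
                rows.append((chrom, s, s + int(rng.integers(50, 400))))
            return rows

        ia, ib = random_peaks(500), random_peaks(500)
        res = peak_set_compare(self._peaks(ia), self._peaks(ib))
        flags_a = shared_flags_bruteforce(ia, ib)
        flags_b = shared_flags_bruteforce(ib, ia)
        assert len(res["shared_a"]) == sum(flags_a)
        assert len(res["unique_a"]) == 500 - sum(flags_a)
        assert len(res["shared_b"]) == sum(flags_b)
        got_shared = set(map(tuple, res["shared_a"].peaks.to_numpy()))
        expected_shared = {tuple(p) for p, f in zip(ia, flags_a) if f}
        assert got_shared == expected_shared

    def test_symmetry(self, rng):
        ia = [("c", int(s), int(s) + 100) for s in rng.integers(0, 5000, 50)]
        ib = [("c", int(s), int(s) + 100) for s in rng.integers(0, 5000, 50)]
        ab = peak_set_compare(self._peaks(ia), self._peaks(ib))
        ba = peak_set_compare(self._peaks(ib), self._peaks(ia))
        pd.testing.assert_frame_equal(ab["unique_a"].peaks, ba["unique_b"].peaks)
        pd.testing.assert_frame_equal(ab["shared_b"].peaks, ba["shared_a"].peaks)


class TestAnnotatePeaks:
    def test_tss_inside_peak(self):
        models = GeneModelSet([_gene("g", 1100)])
        p = PeakSet(pd.DataFrame([("c", 1000, 1200)], columns=["chrom", "start", "end"]))
        res = annotate_peaks_to_genes(p, models)
        assert list(res["gene_id"]) == ["g"]
        assert res["distance"].iloc[0] == 0

    def test_too_far_not_assigned(self):
        models = GeneModelSet([_gene("g", 3300)])
        p = PeakSet(pd.DataFrame([("c", 1000, 1200)], columns=["chrom", "start", "end"]))
        assert len(annotate_peaks_to_genes(p, models, max_dist=2000)) == 0

    def test_matches_bruteforce(self, rng):
        models = GeneModelSet(
            [_gene(f"g{i}", int(t)) for i, t in enumerate(rng.integers(2000, 50_000, 40))]
        )
        rows = []
        for s in rng.integers(0, 50_000, 60):
            rows.append(("c", int(s), int(s) + int(rng.integers(100, 500))))
        p = PeakSet(pd.DataFrame(rows, columns=["chrom", "start", "end"]))
        res = annotate_peaks_to_genes(p, models, max_dist=2000)
        got = {(r["peak_index"], r["gene_id"]) for _, r in res.iterrows()}
        expected = set()
        for i, (c, s, e) in enumerate(rows):
            for g in models:
                dist = max(0, s - g.tss, g.tss - e)
                if dist <= 2000:
                    expected.add((i, g.gene_id))
        assert got == expected


class TestIO:
    def test_reads_bed_round_trip(self, tmp_path):
        reads = _reads([("c1", 0, 50), ("c2", 100, 150)], library_size=777)
        write_reads_bed(reads, tmp_path / "r.bed")
        back = read_reads_bed(tmp_path / "r.bed", library_size=777)
        pd.testing.assert_frame_equal(back.intervals, reads.intervals)
        assert back.library_size == 777

    def test_narrowpeak_round_trip(self, tmp_path):
        df = pd.DataFrame(
            [("c1", 100, 600, "peak1", 850, ".", 12.5, 9.1, 7.7, 250)],
            columns=["chrom", "start", "end", "name", "score", "strand",
                     "signal", "pvalue", "qvalue", "summit"],
        )
        write_peaks(PeakSet(df), tmp_path / "p.narrowPeak")
        back = read_peaks(tmp_path / "p.narrowPeak")
        assert back.peaks.loc[0, "summit"] == 250
        assert back.peaks.loc[0, "chrom"] == "c1"

    def test_inverted_interval_rejected(self):
        with pytest.raises(ValidationError):
            _reads([("c", 10, 10)])
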