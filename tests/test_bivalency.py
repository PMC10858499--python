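"""Reciprocal bivalency, confidence classes, promoters, feature flags."""

import numpy as np
import pandas as pd
import pytest

from rebivalent import bivalency as bv
from rebivalent.intervals import IntervalSet

from conftest import brute_force_overlaps, random_interval_set


def disjoint_intervals(n, width=500, gap=500, chrom="chr1") -> IntervalSet:
    step = width + gap
    return IntervalSet(pd.DataFrame({
        "chrom": chrom,
        "start": np.arange(n) * step,
        "end": np.arange(n) * step + width}))


class TestConsensus:
    def test_single_replicate_identity(self):
        a = disjoint_intervals(5)
        got = bv.consensus_peaks([a])
        pd.testing.assert_frame_equal(got.df, a.merge().df)

    def test_identical_and_disjoint_replicates(self):
        a = disjoint_intervals(5)
        pd.testing.assert_frame_equal(bv.consensus_peaks([a, a]).df,
                                      a.merge().df)
        b = IntervalSet(a.df.assign(start=a.df["start"] + 100_000,
                                    end=a.df["end"] + 100_000))
        assert len(bv.consensus_peaks([a, b])) == 0

    def test_three_replicates_match_fold_left_oracle(self):
        rng = np.random.default_rng(0)
        reps = [random_interval_set(rng, 30) for _ in range(3)]
        got = bv.consensus_peaks(reps)
        oracle = reps[0].intersect(reps[1]).intersect(reps[2]).merge()
        pd.testing.assert_frame_equal(got.df, oracle.df)


class TestReciprocal:
    def test_identical_inputs_all_shared(self):
        a = disjoint_intervals(10)
        rec = bv.reciprocal_bivalent(a, a)
        assert rec.n_shared == 10
        assert (rec.n_k4k27, rec.n_k27k4) == (10, 10)

    def test_empty_input_zero_shared(self):
        a = disjoint_intervals(10)
        assert bv.reciprocal_bivalent(a, IntervalSet()).n_shared == 0
        assert bv.reciprocal_bivalent(IntervalSet(), a).n_shared == 0

    def test_partial_overlap_matches_brute_force(self):
        rng = np.random.default_rng(1)
        a = random_interval_set(rng, 40)
        b = random_interval_set(rng, 40)
        rec = bv.reciprocal_bivalent(a, b)
        oracle = brute_force_overlaps(a, b)
        assert rec.n_shared == int(oracle.sum())
        # representative intervals are the supported K4-K27 peaks themselves
        pd.testing.assert_frame_equal(
            rec.bivalent.df[["chrom", "start", "end"]],
            a.df[oracle][["chrom", "start", "end"]].reset_index(drop=True))


class TestClassifyPeaks:
    def test_overlap_flag_table(self):
        biv = disjoint_intervals(4)
        k4 = IntervalSet(biv.df.iloc[[0, 1]])       # peaks 0,1 in total K4
        k27 = IntervalSet(biv.df.iloc[[0, 2]])      # peaks 0,2 in total K27
        got = bv.classify_peaks(biv, k4, k27)
        assert list(got.df["class"]) == ["HC", "K4B", "K27B", "LC"]
        assert got.tallies() == {"HC": 1, "K4B": 1, "K27B": 1, "LC": 1}

    def test_partition_property_on_random_sets(self):
        rng = np.random.default_rng(2)
        biv = random_interval_set(rng, 60)
        k4 = random_interval_set(rng, 25)
        k27 = random_interval_set(rng, 25)
        got = bv.classify_peaks(biv, k4, k27)
        assert sum(got.tallies().values()) == len(biv)
        assert set(got.df["class"]) <= set(bv.CLASSES)

    def test_inconsistent_flags_rejected(self):
        df = pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [10],
                           "overlaps_total_k4": [True],
                           "overlaps_total_k27": [True],
                           "class": ["LC"]})
        with pytest.raises(ValueError, match="inconsistent"):
            bv.ClassifiedPeakSet(df)


class TestInSilicoComparison:
    def test_accounting_identity(self):
        totals = disjoint_intervals(100)
        validated = IntervalSet(totals.df.iloc[:73])
        comp = bv.in_silico_comparison(totals, totals, validated)
        assert comp.n_insilico == 100
        assert comp.n_validated == 73
        assert comp.n_unvalidated == 27
        assert comp.fp_rate_percent == 27.0

    def test_disjoint_totals_undefined_rate(self):
        a = disjoint_intervals(5)
        b = IntervalSet(a.df.assign(start=a.df["start"] + 10_000,
                                    end=a.df["end"] + 10_000))
        comp = bv.in_silico_comparison(a, b, a)
        assert comp.n_insilico == 0
        assert comp.fp_rate_percent is None

    def test_bivalent_superset_gives_zero_rate(self):
        a = disjoint_intervals(5)
        comp = bv.in_silico_comparison(a, a, a)
        assert comp.fp_rate_percent == 0.0


class TestPromoterWindows:
    def _tss(self, rows):
        return IntervalSet(pd.DataFrame(
            rows, columns=["chrom", "start", "end", "name", "score",
                           "strand"]))

    def test_plus_strand_symmetric(self):
        w = bv.promoter_windows(self._tss([("chr1", 2000, 2001, "g", 0, "+")]))
        assert (int(w.df.iloc[0]["start"]), int(w.df.iloc[0]["end"])) \
            == (500, 3500)

    def test_clipping_at_chrom_start_and_end(self):
        w = bv.promoter_windows(self._tss([("chr1", 500, 501, "g", 0, "+")]))
        assert (int(w.df.iloc[0]["start"]), int(w.df.iloc[0]["end"])) \
            == (0, 2000)
        w = bv.promoter_windows(
            self._tss([("chr1", 9_900, 9_901, "g", 0, "+")]),
            chrom_sizes={"chr1": 10_000})
        assert int(w.df.iloc[0]["end"]) == 10_000

    def test_minus_strand_uses_end_minus_one(self):
        # gene body (1000, 5000) on minus strand: TSS base is 4999
        w = bv.promoter_windows(self._tss([("chr1", 4999, 5000, "g", 0, "-")]))
        assert (int(w.df.iloc[0]["start"]), int(w.df.iloc[0]["end"])) \
            == (3499, 6499)


class TestClassifyPromoters:
    def _classified(self, rows):
        df = pd.DataFrame(rows, columns=["chrom", "start", "end", "class"])
        df["overlaps_total_k4"] = df["class"].isin(["HC", "K4B"])
        df["overlaps_total_k27"] = df["class"].isin(["HC", "K27B"])
        return bv.ClassifiedPeakSet(df)

    def test_hierarchy_hc_wins(self):
        proms = IntervalSet(pd.DataFrame(
            {"chrom": ["chr1"], "start": [0], "end": [3000],
             "name": ["geneA"]}))
        classified = self._classified([("chr1", 100, 200, "K27B"),
                                       ("chr1", 400, 500, "HC")])
        got = bv.classify_promoters(proms, classified)
        assert got.iloc[0]["class"] == "HC"
        assert "HC:chr1:400-500" in got.iloc[0]["peaks"]

    def test_lc_only_and_none(self):
        proms = IntervalSet(pd.DataFrame(
            {"chrom": ["chr1", "chr1"], "start": [0, 10_000],
             "end": [3000, 13_000], "name": ["a", "b"]}))
        classified = self._classified([("chr1", 100, 200, "LC")])
        got = bv.classify_promoters(proms, classified)
        assert list(got["class"]) == ["LC", "none"]

    def test_order_independent_and_matches_priority_oracle(self):
        rng = np.random.default_rng(3)
        proms = IntervalSet(pd.DataFrame({
            "chrom": "chr1", "start": np.arange(20) * 4000,
            "end": np.arange(20) * 4000 + 3000,
            "name": [f"g{i}" for i in range(20)]}))
        starts = rng.integers(0, 80_000, 40)
        classes = rng.choice(bv.CLASSES, 40)
        rows = [("chr1", int(s), int(s) + 600, c)
                for s, c in zip(starts, classes)]
        got = bv.classify_promoters(proms, self._classified(rows))
        shuffled = [rows[i] for i in rng.permutation(40)]
        got2 = bv.classify_promoters(proms, self._classified(shuffled))
        pd.testing.assert_frame_equal(got, got2)
        # brute-force max-priority oracle
        prio = {c: i for i, c in enumerate(bv.CLASSES)}
        for _, prow in got.iterrows():
            hit = [c for (ch, s, e, c) in rows
                   if s < prow["end"] and prow["start"] < e]
            expect = min(hit, key=lambda c: prio[c]) if hit else "none"
            assert prow["class"] == expect


class TestComparePromoterSets:
    def _frame(self, genes, cls="HC"):
        return pd.DataFrame({"chrom": "chr1",
                             "start": np.arange(len(genes)) * 1000,
                             "end": np.arange(len(genes)) * 1000 + 500,
                             "gene": genes, "class": cls})

    def test_identical_sets(self):
        a = self._frame(["g1", "g2", "g3"])
        got = bv.compare_promoter_sets(a, a)
        assert got["pct_of_b_shared"] == 100

    def test_disjoint_sets(self):
        got = bv.compare_promoter_sets(self._frame(["g1"]),
                                       self._frame(["g2"]))
        assert got["n_shared"] == 0

    def test_unclassified_genes_excluded(self):
        a = self._frame(["g1", "g2"])
        a.loc[1, "class"] = "none"
        got = bv.compare_promoter_sets(a, self._frame(["g1", "g2"]))
        assert got["n_a"] == 1


class TestAnnotateFeatures:
    def test_no_features_and_full_overlap(self):
        peaks = disjoint_intervals(5)
        got = bv.annotate_features(peaks, {})
        assert list(got.columns) == ["chrom", "start", "end"]
        got = bv.annotate_features(
            peaks, {"cgi": IntervalSet(pd.DataFrame(
                {"chrom": ["chr1"], "start": [0], "end": [10_000]}))})
        assert got["cgi"].all()

    def test_flags_match_brute_force_and_tally(self):
        rng = np.random.default_rng(4)
        peaks = random_interval_set(rng, 30)
        feats = {"cgi": random_interval_set(rng, 10),
                 "ccre": random_interval_set(rng, 10)}
        got = bv.annotate_features(peaks, feats,
                                   classes=["HC"] * 15 + ["LC"] * 15)
        for name, f in feats.items():
            assert np.array_equal(got[name].to_numpy(),
                                  brute_force_overlaps(peaks, f))
        tallies = bv.feature_tallies(got, ["cgi", "ccre"])
        assert tallies.to_numpy().sum() == int(got[["cgi", "ccre"]].sum().sum())
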