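"""Signal matrices (reference-point and scale-regions), TSS window scoring
and ranking, k-means pattern clustering with elbow-based k selection,
nearest-gene annotation and profile aggregation."""

import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from demark.genomic_io import (
    BinnedTrack,
    ChromSizes,
    GenomicInterval,
    TranscriptModel,
    ValidationError,
)
from demark.regions import (
    aggregate_profile,
    annotate_to_genes,
    elbow_from_curve,
    elbow_select_k,
    kmeans_cluster,
    rank_and_select,
    reference_point_matrix,
    scale_regions_matrix,
    tss_window_scores,
    TSSResponse,
)
from demark.trackops import ComparisonTrack
from .conftest import make_track


def ramp_track(n_bins=1_000, bin_size=100, chrom="chr1"):
    sizes = ChromSizes({chrom: n_bins * bin_size})
    return BinnedTrack(sizes, bin_size,
                       {chrom: np.arange(n_bins, dtype=float)},
                       missing_policy="nan")


class TestReferencePointMatrix:
    def test_constant_track(self):
        sizes = ChromSizes({"chr1": 100_000})
        t = BinnedTrack(sizes, 100, {"chr1": np.full(1_000, 3.3)})
        anchors = [TranscriptModel("g", "t", "chr1", "+", 50_000, 60_000)]
        m = reference_point_matrix(t, anchors, 1_500, 1_500, 500)
        assert m.values.shape == (1, 6)
        np.testing.assert_allclose(m.values, 3.3)

    def test_minus_strand_row_is_reversed(self):
        t = ramp_track()
        plus = TranscriptModel("g", "t", "chr1", "+", 50_000, 60_000)
        minus = TranscriptModel("g", "t", "chr1", "-", 50_000, 40_000)
        mp = reference_point_matrix(t, [plus], 2_000, 2_000, 500)
        mm = reference_point_matrix(t, [minus], 2_000, 2_000, 500)
        np.testing.assert_allclose(mm.values[0], mp.values[0][::-1])

    def test_matches_direct_slicing_oracle(self, rng):
        t = ramp_track()
        # values per 100-bp bin are the bin index, so the mean over any
        # aligned 500-bp window is directly computable
        anchors = [
            TranscriptModel(f"g{i}", f"t{i}", "chr1", "+", int(p), int(p) + 5_000)
            for i, p in enumerate(rng.integers(30, 900, 10) * 100)
        ]
        m = reference_point_matrix(t, anchors, 1_500, 1_500, 500)
        for r, a in enumerate(anchors):
            for j in range(6):
                start = a.tss - 1_500 + j * 500
                expect = np.mean(t.values["chr1"][start // 100:
                                                  start // 100 + 5])
                assert m.values[r, j] == pytest.approx(expect)

    def test_out_of_chromosome_bins_nan(self):
        t = ramp_track(n_bins=50)
        a = TranscriptModel("g", "t", "chr1", "+", 500, 3_000)
        m = reference_point_matrix(t, [a], 1_500, 1_500, 500)
        assert np.isnan(m.values[0, 0]) and np.isnan(m.values[0, 1])
        assert np.isfinite(m.values[0, 2:]).all()

    def test_empty_anchor_list_rejected(self):
        with pytest.raises(ValidationError):
            reference_point_matrix(ramp_track(), [], 1_500, 1_500, 500)


class TestScaleRegionsMatrix:
    def test_constant_track_and_column_count(self):
        sizes = ChromSizes({"chr1": 200_000})
        t = BinnedTrack(sizes, 100, {"chr1": np.full(2_000, 1.7)})
        txs = [TranscriptModel("g", "t", "chr1", "+", 50_000, 62_000)]
        m = scale_regions_matrix(t, txs)  # defaults: 500 + 5000 + 500 at 500
        assert m.values.shape == (1, 12)
        np.testing.assert_allclose(m.values, 1.7)

    def test_matches_per_bp_resampling_oracle(self, rng):
        t = ramp_track(2_000)
        txs = []
        for i in range(8):
            start = int(rng.integers(50, 1_500)) * 100
            # body length a multiple of 10 output bins keeps the oracle exact
            length = int(rng.integers(1, 8)) * 10_000
            strand = "+" if i % 2 == 0 else "-"
            tss, tes = (start, start + length) if strand == "+" else \
                       (start + length, start)
            txs.append(TranscriptModel(f"g{i}", f"t{i}", "chr1", strand,
                                       tss, tes))
        m = scale_regions_matrix(t, txs, body_length=5_000, flank=500, bin=500)
        bp = np.repeat(t.values["chr1"], 100)  # per-bp expansion
        for r, tx in enumerate(txs):
            sgn = 1 if tx.strand == "+" else -1
            expect = []
            for j in range(1):
                a = tx.tss - sgn * 500
                expect.append(bp[min(a, a + sgn * 500): max(a, a + sgn * 500)].mean())
            L = tx.length
            for j in range(10):
                a = tx.tss + sgn * (L * j // 10)
                b = tx.tss + sgn * (L * (j + 1) // 10)
                expect.append(bp[min(a, b): max(a, b)].mean())
            a = tx.tes
            expect.append(bp[min(a, a + sgn * 500): max(a, a + sgn * 500)].mean())
            np.testing.assert_allclose(m.values[r], expect, atol=1e-9)

    def test_too_short_transcript_warned_nan(self):
        t = ramp_track()
        short = TranscriptModel("g", "t", "chr1", "+", 1_000, 1_300)
        with pytest.warns(UserWarning, match="shorter"):
            m = scale_regions_matrix(t, [short])
        assert np.isnan(m.values[0]).all()


class TestTSSScores:
    def _comparison(self, values, bin_size=100):
        sizes = ChromSizes({"chr1": len(values) * bin_size})
        tr = BinnedTrack(sizes, bin_size, {"chr1": np.asarray(values, float)},
                         missing_policy="nan")
        return ComparisonTrack(tr, 1.0, "a", "b")

    def test_zero_comparison_all_zero(self):
        cmp = self._comparison(np.zeros(1_000))
        txs = [TranscriptModel(f"g{i}", f"t{i}", "chr1", "+",
                               10_000 + 5_000 * i, 12_000 + 5_000 * i)
               for i in range(10)]
        resp = tss_window_scores(cmp, txs)
        assert all(r.kd_vs_ctrl == 0.0 for r in resp)

    def test_planted_shift_ranks_first(self):
        vals = np.zeros(9_000)
        txs, shifted = [], set()
        for i in range(200):
            tss = 5_000 + 4_000 * i
            txs.append(TranscriptModel(f"g{i:03d}", f"t{i:03d}", "chr1", "+",
                                       tss, tss + 1_000))
            if i % 4 == 0:  # 50 of 200 get a +0.5 shift over the window
                b0, b1 = (tss - 1_500) // 100, (tss + 1_500) // 100
                vals[b0:b1] = 0.5
                shifted.add(f"g{i:03d}")
        cmp = self._comparison(vals)
        resp = tss_window_scores(cmp, txs)
        pos = {r.gene_id for r in resp if r.kd_vs_ctrl > 0}
        assert pos == shifted
        top = rank_and_select(resp, 50)
        assert {r.gene_id for r in top} == shifted


class TestRankAndSelect:
    def _resp(self, scores):
        return [TSSResponse(f"t{i}", f"g{i}", "chr1", i * 1_000,
                            kd_vs_ctrl=s) for i, s in enumerate(scores)]

    def test_descending_order(self):
        out = rank_and_select(self._resp([3.0, 1.0, 2.0]))
        assert [r.kd_vs_ctrl for r in out] == [3.0, 2.0, 1.0]
        assert [r.rank for r in out] == [1, 2, 3]

    def test_tie_break_deterministic(self):
        out = rank_and_select(self._resp([1.0, 1.0, 1.0]))
        assert [r.transcript_id for r in out] == ["t0", "t1", "t2"]

    def test_invariant_to_input_order(self, rng):
        scores = list(rng.normal(size=100))
        base = self._resp(scores)
        ref = [r.transcript_id for r in rank_and_select(list(base))]
        top_ref = {r.transcript_id for r in rank_and_select(list(base), 10)}
        for _ in range(5):
            perm = [base[i] for i in rng.permutation(100)]
            assert [r.transcript_id for r in rank_and_select(perm)] == ref
            assert {r.transcript_id
                    for r in rank_and_select(perm, 10)} == top_ref
        # full-sort oracle for the top-n set
        order = np.argsort(-np.asarray(scores), kind="stable")
        assert top_ref == {f"t{i}" for i in order[:10]}

    def test_overlong_request_warns(self):
        with pytest.warns(UserWarning):
            out = rank_and_select(self._resp([1.0, 2.0]), 5)
        assert len(out) == 2


class TestKMeans:
    def test_planted_blobs_recovered(self, rng):
        centers = np.array([[5.0, 0, 0], [0, 5.0, 0], [0, 0, 5.0]])
        labels_true = rng.integers(0, 3, 300)
        X = centers[labels_true] + rng.normal(0, 0.1, (300, 3))
        res = kmeans_cluster(X, k=3, seed=17)
        assert adjusted_rand_score(labels_true, res.labels) == 1.0

    def test_k1_total_ss(self, rng):
        X = rng.normal(size=(50, 4))
        res = kmeans_cluster(X, k=1, seed=0)
        assert res.wcss_by_k[1] == pytest.approx(((X - X.mean(0)) ** 2).sum())
        assert set(res.labels) == {0}

    def test_duplicated_rows_same_centroids(self, rng):
        X = rng.normal(size=(60, 3)) + np.repeat(np.eye(3) * 6, 20, axis=0)
        r1 = kmeans_cluster(X, k=3, seed=17)
        r2 = kmeans_cluster(np.vstack([X, X]), k=3, seed=17)
        np.testing.assert_allclose(
            np.sort(r1.centroids, axis=0), np.sort(r2.centroids, axis=0),
            atol=1e-8)

    def test_nan_rows_dropped_and_reported(self, rng):
        X = rng.normal(size=(20, 3))
        X[4, 1] = np.nan
        res = kmeans_cluster(X, k=2, seed=0)
        assert res.dropped_rows == [4]
        assert len(res.labels) == 19

    def test_relabeling_by_first_feature(self, rng):
        X = np.vstack([np.full((30, 3), 5.0), np.zeros((30, 3))])
        X += rng.normal(0, 0.01, X.shape)
        res = kmeans_cluster(X, k=2, seed=17)
        assert (res.labels[:30] == 0).all() and (res.labels[30:] == 1).all()

    def test_too_few_rows_rejected(self):
        with pytest.raises(ValidationError):
            kmeans_cluster(np.zeros((2, 2)), k=3)


class TestElbow:
    def test_three_blobs_select_three(self, rng):
        centers = np.array([[0.0, 0], [8.0, 0], [0, 8.0]])
        X = centers[rng.integers(0, 3, 240)] + rng.normal(0, 0.3, (240, 2))
        k, wcss, strength = elbow_select_k(X, range(1, 9), seed=17)
        assert k == 3
        ks = sorted(wcss)
        assert all(wcss[a] >= wcss[b] - 1e-6
                   for a, b in zip(ks, ks[1:]))  # WCSS non-increasing

    def test_pure_noise_low_strength(self, rng):
        X = rng.normal(size=(300, 3))
        k, wcss, strength = elbow_select_k(X, range(1, 9), seed=17)
        assert k in range(2, 8)
        assert strength < 0.2

    def test_curve_arithmetic(self):
        curve = {1: 100.0, 2: 30.0, 3: 28.0, 4: 27.0, 5: 26.0}
        assert elbow_from_curve(curve) == 2

    def test_short_range_rejected(self, rng):
        with pytest.raises(ValidationError):
            elbow_select_k(rng.normal(size=(50, 2)), [2, 3])


class TestAnnotateToGenes:
    TXS = [
        TranscriptModel("gA", "t1", "chr1", "+", 10_000, 15_000),
        TranscriptModel("gB", "t2", "chr1", "+", 30_000, 35_000),
        TranscriptModel("gC", "t3", "chr2", "-", 20_000, 12_000),
    ]

    def test_tss_rows_map_to_own_gene(self):
        rows = [TSSResponse("t2", "gB", "chr1", 30_000)]
        assert annotate_to_genes(rows, self.TXS) == ["gB"]

    def test_equidistant_tie_smaller_gene_id(self):
        iv = GenomicInterval("chr1", 19_000, 21_000)  # midpoint 20,000
        assert annotate_to_genes([iv], self.TXS) == ["gA"]

    def test_matches_exhaustive_nearest_tss(self, rng):
        ivs = [GenomicInterval("chr1", int(p), int(p) + 100)
               for p in rng.integers(0, 50_000, 50)]
        got = annotate_to_genes(ivs, self.TXS)
        for iv, g in zip(ivs, got):
            cands = [(abs(t.tss - iv.midpoint), t.gene_id)
                     for t in self.TXS if t.chrom == iv.chrom]
            assert g == min(cands)[1]

    def test_empty_transcripts_rejected(self):
        with pytest.raises(ValidationError):
            annotate_to_genes([], [])


class TestAggregateProfile:
    def _matrix(self, values):
        anchors = [GenomicInterval("chr1", i * 10 + 1, i * 10 + 2)
                   for i in range(values.shape[0])]
        from demark.regions import SignalMatrix
        return SignalMatrix(anchors, "reference-point", 500, 500, 500, values)

    def test_constant_matrix(self):
        m = self._matrix(np.full((10, 4), 2.5))
        mean, sem = aggregate_profile(m, range(10))
        np.testing.assert_allclose(mean, 2.5)
        np.testing.assert_allclose(sem, 0.0)

    def test_singleton_subset_is_that_row(self, rng):
        vals = rng.normal(size=(6, 5))
        m = self._matrix(vals)
        mean, sem = aggregate_profile(m, [3])
        np.testing.assert_allclose(mean, vals[3])
        assert np.isnan(sem).all()

    def test_matches_column_mean_oracle(self, rng):
        vals = rng.normal(size=(30, 8))
        vals[rng.random(vals.shape) < 0.1] = np.nan
        m = self._matrix(vals)
        subset = list(rng.choice(30, 12, replace=False))
        mean, _ = aggregate_profile(m, subset)
        np.testing.assert_allclose(mean, np.nanmean(vals[subset], axis=0),
                                   equal_nan=True)

    def test_empty_subset_rejected(self, rng):
        with pytest.raises(ValidationError):
            aggregate_profile(self._matrix(rng.normal(size=(4, 3))), [])


class TestStrandConsistency:
    def test_reversing_strand_reverses_row(self):
        t = ramp_track()
        plus = GenomicInterval("chr1", 40_000, 50_000, strand="+")
        minus = GenomicInterval("chr1", 40_000, 50_000, strand="-")
        mp = reference_point_matrix(t, [plus], 2_000, 2_000, 500)
        mm = reference_point_matrix(t, [minus], 2_000, 2_000, 500)
        np.testing.assert_allclose(mm.values[0], mp.values[0][::-1])
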