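"""LAD-centered matrices, LAD clustering with the extreme-cluster removal
rule, lamin B1 center extraction and the Mann-Whitney comparison."""

import itertools
import math

import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from demark.genomic_io import BinnedTrack, ChromSizes, GenomicInterval, ValidationError
from demark.lads import (
    BoxSummary,
    LADRecord,
    cluster_lads,
    compare_lad_clusters,
    flag_outlier_clusters,
    lad_signal_matrix,
    lamin_center_values,
    mann_whitney_u,
    significance_stars,
)
from demark.regions import SignalMatrix
from .conftest import make_track


def exact_mw_p(x, y):
    """Brute-force permutation enumeration oracle for the two-sided
    Mann-Whitney p-value (tie-free data)."""
    pooled = list(x) + list(y)
    n1 = len(x)

    def u_stat(xs, ys):
        return sum(1 for a in xs for b in ys if a > b)

    u_obs = u_stat(x, y)
    mu = n1 * len(y) / 2
    count = total = 0
    for combo in itertools.combinations(range(len(pooled)), n1):
        xs = [pooled[i] for i in combo]
        ys = [pooled[i] for i in range(len(pooled)) if i not in combo]
        u = u_stat(xs, ys)
        total += 1
        if abs(u - mu) >= abs(u_obs - mu) - 1e-12:
            count += 1
    return count / total


class TestMannWhitney:
    def test_identical_multisets_p_one(self):
        res = mann_whitney_u([1, 2, 3, 4], [1, 2, 3, 4])
        assert res.p_value == pytest.approx(1.0)

    def test_hand_enumeration_example(self):
        res = mann_whitney_u([1, 2], [3, 4])
        assert res.U == 0
        assert res.p_value == pytest.approx(2 / 6)
        assert res.method == "exact"

    def test_matches_enumeration_oracle_all_small_cases(self, rng):
        for n1 in range(1, 7):
            for n2 in range(1, 7):
                vals = rng.permutation(np.arange(1.0, n1 + n2 + 1))
                x, y = vals[:n1], vals[n1:]
                res = mann_whitney_u(x, y)
                assert res.method == "exact"
                assert res.p_value == pytest.approx(exact_mw_p(x, y))

    def test_u_sum_identity(self, rng):
        for _ in range(20):
            x = rng.normal(size=int(rng.integers(1, 30)))
            y = rng.normal(size=int(rng.integers(1, 30)))
            a, b = mann_whitney_u(x, y), mann_whitney_u(y, x)
            assert a.U + b.U == pytest.approx(len(x) * len(y))
            assert 0 <= a.U <= len(x) * len(y)
            assert 0 < a.p_value <= 1

    def test_ties_use_corrected_normal_approximation(self):
        res = mann_whitney_u([1, 1, 2, 2], [2, 2, 3, 3])
        assert res.method == "normal-approximation-with-tie-correction"
        assert 0 < res.p_value <= 1

    def test_single_identical_values_p_one(self):
        res = mann_whitney_u([2.0], [2.0])
        assert res.p_value == pytest.approx(1.0)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValidationError):
            mann_whitney_u([], [1.0])

    def test_stars_convention(self):
        assert significance_stars(0.001) == "***"
        assert significance_stars(0.02) == "*"
        assert significance_stars(0.2) == "NS"


class TestLADMatrix:
    def test_default_geometry_100_columns(self, sizes, rng):
        track = make_track(sizes, 10_000, rng)
        lads = [GenomicInterval("chr1", 600_000, 800_000)]
        m = lad_signal_matrix(track, lads)
        assert m.values.shape == (1, 100)

    def test_constant_track(self, sizes):
        t = BinnedTrack(sizes, 10_000,
                        {c: np.full(sizes.n_bins(c, 10_000), 2.0)
                         for c in sizes})
        m = lad_signal_matrix(t, [GenomicInterval("chr1", 600_000, 800_000)])
        np.testing.assert_allclose(m.values, 2.0)

    def test_matches_slicing_oracle(self, sizes, rng):
        track = make_track(sizes, 10_000, rng)
        # keep every +/-0.5 Mb window inside the 2-Mb chromosome
        lads = [GenomicInterval("chr1", int(s), int(s) + 200_000)
                for s in rng.integers(60, 130, 5) * 10_000]
        m = lad_signal_matrix(track, lads, flank=500_000, bin=10_000)
        for r, lad in enumerate(lads):
            mid_bin = lad.midpoint // 10_000
            expect = track.values["chr1"][mid_bin - 50: mid_bin + 50]
            np.testing.assert_allclose(m.values[r], expect)


def synthetic_lad_features(rng, n1=100, n2=95, n_out=5, sep=(1.0, 3.0, 8.0),
                           sd=0.05, n_features=6):
    X = np.vstack([
        rng.normal(sep[0], sd, (n1, n_features)),
        rng.normal(sep[1], sd, (n2, n_features)),
        rng.normal(sep[2], sd, (n_out, n_features)),
    ])
    labels = np.array([0] * n1 + [1] * n2 + [2] * n_out)
    perm = rng.permutation(len(labels))
    return X[perm], labels[perm]


def matrices_from_features(X):
    """Wrap a feature matrix as one single-column SignalMatrix per
    'condition' so cluster_lads sees the intended features."""
    anchors = [GenomicInterval("chr1", 1_000 * i + 1, 1_000 * i + 2)
               for i in range(X.shape[0])]
    return {
        f"cond{j}": SignalMatrix(anchors, "reference-point", 500, 500, 1_000,
                                 X[:, [j]])
        for j in range(X.shape[1])
    }


class TestClusterLads:
    def test_two_groups_plus_extremes_elbow_three_and_isolated(self, rng):
        # extremes about 3x farther out than the group gap: both splits
        # remove comparable variance, so the WCSS curvature peaks at k=3
        X, labels = synthetic_lad_features(rng, sep=(1.0, 2.0, 5.2))
        result, feats = cluster_lads(matrices_from_features(X), k=None,
                                     seed=17)
        assert result.k == 3
        assert adjusted_rand_score(labels, result.labels) == 1.0
        # the 5 extreme rows sit alone in the top-signal cluster
        extreme_cluster = result.labels[labels == 2]
        assert len(set(extreme_cluster)) == 1
        assert (result.labels == extreme_cluster[0]).sum() == 5

    def test_planted_threefold_offset_recovered(self, rng):
        X, labels = synthetic_lad_features(rng, sep=(1.0, 3.0, 9.0), sd=0.2)
        result, _ = cluster_lads(matrices_from_features(X), k=3, seed=17)
        assert adjusted_rand_score(labels, result.labels) >= 0.9

    def test_identical_rows_degenerate_error(self):
        X = np.ones((20, 4))
        with pytest.raises(ValidationError, match="degenerate"):
            cluster_lads(matrices_from_features(X), k=3)

    def test_partition_invariant_under_row_permutation(self, rng):
        X, labels = synthetic_lad_features(rng)
        r1, _ = cluster_lads(matrices_from_features(X), k=3, seed=17)
        perm = rng.permutation(len(labels))
        r2, _ = cluster_lads(matrices_from_features(X[perm]), k=3, seed=17)
        assert adjusted_rand_score(r1.labels[perm], r2.labels) == 1.0

    def test_row_mismatch_rejected(self, rng):
        X, _ = synthetic_lad_features(rng)
        mats = matrices_from_features(X)
        short = matrices_from_features(X[:-1])
        mats["cond0"] = short["cond0"]
        with pytest.raises(ValidationError):
            cluster_lads(mats, k=3)


class TestOutlierRule:
    def test_high_small_cluster_flagged(self, rng):
        X, labels = synthetic_lad_features(rng, n1=834, n2=1_182, n_out=5,
                                           sep=(1.2, 1.0, 30.0), sd=0.02)
        result, feats = cluster_lads(matrices_from_features(X), k=3, seed=17)
        outliers, keep, relabeled = flag_outlier_clusters(result, feats,
                                                          fold=20,
                                                          max_frac=0.01)
        assert keep.sum() == 2_016
        assert set(np.nonzero(~keep)[0]) == set(np.nonzero(labels == 2)[0])
        # survivors relabeled by descending mean: 0 = the 1.2 group
        assert (relabeled[labels == 0] == 0).all()
        assert (relabeled[labels == 1] == 1).all()
        assert (relabeled[labels == 2] == -1).all()

    def test_nothing_removed_when_fold_not_exceeded(self, rng):
        X, _ = synthetic_lad_features(rng, sep=(1.0, 2.0, 5.0), sd=0.05)
        result, feats = cluster_lads(matrices_from_features(X), k=3, seed=17)
        outliers, keep, _ = flag_outlier_clusters(result, feats, fold=20,
                                                  max_frac=0.05)
        assert outliers == [] and keep.all()

    def test_large_high_cluster_protected_by_size_condition(self, rng):
        # a high-signal cluster holding half the rows is never deleted
        X, _ = synthetic_lad_features(rng, n1=100, n2=10, n_out=100,
                                      sep=(1.0, 1.1, 40.0), sd=0.01)
        result, feats = cluster_lads(matrices_from_features(X), k=3, seed=17)
        outliers, keep, _ = flag_outlier_clusters(result, feats, fold=20,
                                                  max_frac=0.01)
        assert outliers == [] and keep.all()


class TestLaminCenters:
    def test_midpoint_bin_indexing(self):
        sizes = ChromSizes({"chr1": 1_000_000})
        vals = np.arange(100, dtype=float)
        t = BinnedTrack(sizes, 10_000, {"chr1": vals}, missing_policy="nan")
        lads = [GenomicInterval("chr1", 0, 200_000)]  # midpoint 100,000
        c0, c9 = lamin_center_values(t, t, lads)
        assert c0[0] == 10.0

    def test_constant_track(self, sizes):
        t = BinnedTrack(sizes, 10_000,
                        {c: np.full(sizes.n_bins(c, 10_000), -0.25)
                         for c in sizes}, missing_policy="nan")
        lads = [GenomicInterval("chr1", 100_000, 340_000),
                GenomicInterval("chr2", 0, 70_000)]
        c0, _ = lamin_center_values(t, t, lads)
        np.testing.assert_allclose(c0, -0.25)

    def test_matches_direct_lookup_oracle(self, sizes, rng):
        t0 = make_track(sizes, 10_000, rng, missing_policy="nan")
        t9 = make_track(sizes, 10_000, rng, missing_policy="nan")
        lads = [GenomicInterval("chr1", int(s), int(s + rng.integers(2, 30) * 10_000))
                for s in rng.integers(0, 150, 20) * 10_000]
        c0, c9 = lamin_center_values(t0, t9, lads)
        for i, lad in enumerate(lads):
            mid = lad.start + (lad.end - lad.start) // 2
            assert c0[i] == t0.values["chr1"][mid // 10_000]
            assert c9[i] == t9.values["chr1"][mid // 10_000]


class TestCompareClusters:
    def _records(self, rng, shift0=0.3, shift9=0.0, n1=80, n2=120, sd=0.2):
        recs = []
        for i in range(n1 + n2):
            grp = "B1-like" if i < n1 else "B2-like"
            mu0 = 0.7 + (shift0 if grp == "B1-like" else 0.0)
            mu9 = 0.2 + (shift9 if grp == "B1-like" else 0.0)
            iv = GenomicInterval("chr1", 1_000 * i + 1, 1_000 * i + 2)
            recs.append(LADRecord(iv, grp,
                                  rng.normal(mu0, sd), rng.normal(mu9, sd)))
        return recs

    def test_planted_day0_shift_highly_significant(self, rng):
        recs = self._records(rng)
        res, boxes = compare_lad_clusters(recs, "day0")
        assert res.p_value < 0.005
        assert boxes["B1-like"].median > boxes["B2-like"].median

    def test_equal_day9_distributions_ns(self, rng):
        recs = self._records(rng)
        res, _ = compare_lad_clusters(recs, "day9")
        assert res.p_value > 0.05

    def test_single_value_clusters_p_one(self):
        iv = GenomicInterval("chr1", 0, 10)
        recs = [LADRecord(iv, "B1-like", 0.5, 0.5),
                LADRecord(iv, "B2-like", 0.5, 0.5)]
        res, _ = compare_lad_clusters(recs, "day0")
        assert res.p_value == pytest.approx(1.0)

    def test_empty_cluster_rejected(self):
        iv = GenomicInterval("chr1", 0, 10)
        with pytest.raises(ValidationError):
            compare_lad_clusters([LADRecord(iv, "B1-like", 0.1, 0.1)], "day0")

    def test_box_summary_minmax_whiskers_and_iqr_outliers(self):
        vals = [1.0, 2.0, 3.0, 4.0, 100.0]
        box = BoxSummary.from_values(vals)
        assert box.whisker_high == 100.0 and box.whisker_low == 1.0
        assert box.outliers == [100.0]
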