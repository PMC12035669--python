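"""Lamina-associated domain (LAD) analysis: LAD-centered signal matrices,
k-means grouping with elbow-based k, removal of extreme-signal outlier
clusters, lamin B1 levels at LAD centers, and the two-group Mann-Whitney
comparison.

The outlier rule mirrors the situation where a handful of regions carry an
order of magnitude more repressive-mark signal than everything else: a
cluster is discarded only when its mean signal exceeds ``fold`` times the
mean of the other clusters' means AND it holds at most ``max_frac`` of the
regions — both conditions, so a genuinely large high-signal cluster is
never deleted.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
from scipy import stats

from .genomic_io import BinnedTrack, GenomicInterval, ValidationError
from .regions import ClusterResult, SignalMatrix, elbow_from_curve, kmeans_cluster, reference_point_matrix
from .trackops import ComparisonTrack

__all__ = [
    "LADRecord",
    "TestResult",
    "BoxSummary",
    "lad_signal_matrix",
    "cluster_lads",
    "flag_outlier_clusters",
    "lamin_center_values",
    "mann_whitney_u",
    "compare_lad_clusters",
]


@dataclass
class LADRecord:
    interval: GenomicInterval
    cluster_label: str                 # 'B1-like' | 'B2-like' | 'outlier'
    center_laminB1_day0: float = float("nan")
    center_laminB1_day9: float = float("nan")


@dataclass
class TestResult:
    U: float
    p_value: float
    n1: int
    n2: int
    method: str      # 'exact' | 'normal-approximation-with-tie-correction'


@dataclass
class BoxSummary:
    """Box-plot statistics: whiskers span the full data range; points
    outside 1.5 IQR are additionally reported as outliers."""

    median: float
    q1: float
    q3: float
    whisker_low: float
    whisker_high: float
    outliers: List[float]
    n: int

    @classmethod
    def from_values(cls, values: Sequence[float]) -> "BoxSummary":
        v = np.asarray([x for x in values if np.isfinite(x)], dtype=float)
        if v.size == 0:
            raise ValidationError("no finite values to summarize")
        q1, med, q3 = np.percentile(v, [25, 50, 75])
        iqr = q3 - q1
        out = v[(v < q1 - 1.5 * iqr) | (v > q3 + 1.5 * iqr)]
        return cls(float(med), float(q1), float(q3),
                   float(v.min()), float(v.max()), [float(x) for x in out], int(v.size))


def lad_signal_matrix(
    signal: Union[BinnedTrack, ComparisonTrack],
    lads: Sequence[GenomicInterval],
    flank: int = 500_000,
    bin: int = 10_000,
) -> SignalMatrix:
    """Reference-point matrix anchored at LAD midpoints (strand ignored;
    100 columns at the defaults)."""
    if len(lads) == 0:
        raise ValidationError("empty LAD list")
    anchors = [
        GenomicInterval(l.chrom, l.start, l.end, name=l.name, strand=".")
        for l in lads
    ]
    return reference_point_matrix(signal, anchors, upstream=flank,
                                  downstream=flank, bin=bin)


def cluster_lads(
    matrices: Dict[str, SignalMatrix],
    k: Optional[int] = None,
    seed: int = 17,
    n_init: int = 10,
    k_range: Sequence[int] = range(1, 9),
    features: str = "row-means",
) -> Tuple[ClusterResult, np.ndarray]:
    """Cluster LADs on their signal across conditions/timepoints.

    ``matrices`` maps a condition label to a LAD-centered SignalMatrix (all
    sharing row order). Features are per-condition row means over the
    window (default) or the full concatenated rows (``features="full"``).
    When ``k`` is None it is chosen by the elbow method over ``k_range``.
    Returns the ClusterResult and the feature matrix used.
    """
    if not matrices:
        raise ValidationError("no matrices given")
    n_rows = {len(m.regions) for m in matrices.values()}
    if len(n_rows) != 1:
        raise ValidationError("matrices must share row order/length")
    cols = []
    for label in sorted(matrices):
        m = matrices[label].values
        if features == "row-means":
            with np.errstate(invalid="ignore"):
                cols.append(np.nanmean(m, axis=1)[:, None])
        elif features == "full":
            cols.append(m)
        else:
            raise ValidationError(f"unknown feature mode {features!r}")
    X = np.hstack(cols)
    finite = X[np.isfinite(X).all(axis=1)]
    if finite.shape[0] >= 2 and np.allclose(finite, finite[0]):
        raise ValidationError("degenerate input: all LAD feature rows identical")
    if k is None:
        wcss: Dict[int, float] = {}
        for kk in sorted(k_range):
            wcss[kk] = kmeans_cluster(X, k=kk, seed=seed, n_init=n_init).wcss_by_k[kk]
        k = elbow_from_curve(wcss)
        result = kmeans_cluster(X, k=k, seed=seed, n_init=n_init)
        result.wcss_by_k = wcss
    else:
        result = kmeans_cluster(X, k=k, seed=seed, n_init=n_init)
    return result, X


def flag_outlier_clusters(
    result: ClusterResult,
    feature_matrix: np.ndarray,
    fold: float = 20.0,
    max_frac: float = 0.01,
) -> Tuple[List[int], np.ndarray, np.ndarray]:
    """Flag extreme-signal clusters and relabel the survivors.

    A cluster is an outlier when its mean feature signal exceeds ``fold``
    times the mean of the other clusters' means and it contains at most
    ``max_frac`` of the rows. Returns ``(outlier_cluster_ids, keep_mask,
    relabeled)`` where ``relabeled`` assigns surviving clusters 0, 1, ...
    by descending mean signal (0 = highest, the 'B1-like' group) and -1 to
    removed rows. Masks/labels are aligned to the finite rows used by the
    clustering (``result.row_index``).
    """
    k = result.k
    if k < 2:
        raise ValidationError("need at least 2 clusters")
    X = np.asarray(feature_matrix, dtype=float)
    X = X[np.isfinite(X).all(axis=1)]
    means = np.array([X[result.labels == c].mean() for c in range(k)])
    sizes = np.array([(result.labels == c).sum() for c in range(k)])
    total = sizes.sum()
    outliers = [
        c for c in range(k)
        if means[c] > fold * np.mean(np.delete(means, c))
        and sizes[c] <= max_frac * total
    ]
    if len(outliers) == k:
        raise ValidationError("all clusters flagged as outliers")
    keep_clusters = [c for c in range(k) if c not in outliers]
    order = sorted(keep_clusters, key=lambda c: -means[c])
    relabel = {c: i for i, c in enumerate(order)}
    keep_mask = ~np.isin(result.labels, outliers)
    relabeled = np.array([relabel.get(l, -1) for l in result.labels])
    return outliers, keep_mask, relabeled


def lamin_center_values(
    track_day0: BinnedTrack,
    track_day9: BinnedTrack,
    lads: Sequence[GenomicInterval],
) -> Tuple[np.ndarray, np.ndarray]:
    """Lamin B1 log-ratio at the bin containing each LAD midpoint, for both
    timepoints. Midpoints in NaN bins yield NaN."""
    def centers(track: BinnedTrack) -> np.ndarray:
        out = np.empty(len(lads))
        for i, lad in enumerate(lads):
            b = lad.midpoint // track.bin_size
            out[i] = track.values[lad.chrom][b]
        return out

    return centers(track_day0), centers(track_day9)


def mann_whitney_u(
    x: Sequence[float],
    y: Sequence[float],
    alternative: str = "two-sided",
) -> TestResult:
    """Mann-Whitney U test for a location difference between two samples.

    The p-value is the exact enumeration value when both samples have at
    most 8 observations and there are no ties; otherwise the normal
    approximation with tie and continuity correction is used. U is
    reported for ``x``.
    """
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValidationError("both samples must be non-empty")
    no_ties = len(np.unique(np.concatenate([x, y]))) == x.size + y.size
    if x.size <= 8 and y.size <= 8 and no_ties:
        method = "exact"
        res = stats.mannwhitneyu(x, y, alternative=alternative, method="exact")
    else:
        method = "normal-approximation-with-tie-correction"
        res = stats.mannwhitneyu(
            x, y, alternative=alternative, method="asymptotic", use_continuity=True
        )
    p = min(1.0, float(res.pvalue))
    return TestResult(float(res.statistic), max(p, np.finfo(float).tiny),
                      int(x.size), int(y.size), method)


def compare_lad_clusters(
    records: Sequence[LADRecord], timepoint: str = "day0"
) -> Tuple[TestResult, Dict[str, BoxSummary]]:
    """Mann-Whitney comparison of lamin B1 center levels between the
    B1-like and B2-like clusters at one timepoint, plus box-plot summaries.
    NaN centers are excluded (counts visible via the summaries)."""
    attr = {"day0": "center_laminB1_day0", "day9": "center_laminB1_day9"}[timepoint]
    g1 = [getattr(r, attr) for r in records if r.cluster_label == "B1-like"]
    g2 = [getattr(r, attr) for r in records if r.cluster_label == "B2-like"]
    g1 = [v for v in g1 if np.isfinite(v)]
    g2 = [v for v in g2 if np.isfinite(v)]
    if not g1 or not g2:
        raise ValidationError("a cluster is empty after NaN exclusion")
    test = mann_whitney_u(g1, g2)
    return test, {
        "B1-like": BoxSummary.from_values(g1),
        "B2-like": BoxSummary.from_values(g2),
    }


def significance_stars(p: float) -> str:
    """Two-level convention: '*' p < 0.05, '***' p < 0.005, else 'NS'."""
    if p < 0.005:
        return "***"
    if p < 0.05:
        return "*"
    return "NS"
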