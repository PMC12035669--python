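"""Region-by-bin signal matrices and the TSS-level analyses built on them:
window scoring and ranking of TSS responses, k-means clustering of
response patterns across comparisons (with elbow-based k selection),
nearest-gene annotation, and profile aggregation.

Matrices follow the two standard meta-profile geometries: *reference-point*
(fixed window around an anchor, e.g. TSS +/- 1.5 kb) and *scale-regions*
(gene body rescaled to a common length, defaults 500 + 5000 + 500 bp at
500-bp bins, i.e. 12 columns). Minus-strand rows are reported 5'->3'.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
from sklearn.cluster import KMeans

from .compartments import _window_mean
from .genomic_io import (
    BinnedTrack,
    GenomicInterval,
    TranscriptModel,
    ValidationError,
)
from .trackops import ComparisonTrack

__all__ = [
    "SignalMatrix",
    "TSSResponse",
    "ClusterResult",
    "reference_point_matrix",
    "scale_regions_matrix",
    "tss_window_scores",
    "rank_and_select",
    "kmeans_cluster",
    "elbow_select_k",
    "annotate_to_genes",
    "aggregate_profile",
]

Anchor = Union[GenomicInterval, TranscriptModel]


def _as_track(signal: Union[BinnedTrack, ComparisonTrack]) -> BinnedTrack:
    return signal.track if isinstance(signal, ComparisonTrack) else signal


def _anchor_point(a: Anchor) -> Tuple[str, int, str]:
    if isinstance(a, TranscriptModel):
        return a.chrom, a.tss, a.strand
    return a.chrom, a.midpoint, a.strand if a.strand in {"+", "-"} else "+"


@dataclass
class SignalMatrix:
    regions: List[Anchor]
    mode: str                      # 'reference-point' | 'scale-regions'
    upstream: int
    downstream: int
    bin: int
    values: np.ndarray             # regions x bins, NaN allowed
    body_length: Optional[int] = None

    def __post_init__(self):
        if self.values.shape[0] != len(self.regions):
            raise ValidationError("matrix rows must match regions")

    @property
    def n_bins(self) -> int:
        return self.values.shape[1]

    def offsets(self) -> np.ndarray:
        """Bin-center offsets in bp relative to the anchor (reference-point
        mode only)."""
        if self.mode != "reference-point":
            raise ValidationError("offsets defined for reference-point matrices")
        return np.arange(-self.upstream, self.downstream, self.bin) + self.bin // 2


@dataclass
class TSSResponse:
    transcript_id: str
    gene_id: str
    chrom: str
    tss: int
    kd_vs_ctrl: float = float("nan")
    wt_vs_lacz: float = float("nan")
    mut_vs_wt: float = float("nan")
    rank: Optional[int] = None

    def scores(self) -> Tuple[float, float, float]:
        return (self.kd_vs_ctrl, self.wt_vs_lacz, self.mut_vs_wt)


@dataclass
class ClusterResult:
    labels: np.ndarray
    k: int
    centroids: np.ndarray
    wcss_by_k: Dict[int, float]
    seed: int
    dropped_rows: List[int] = field(default_factory=list)
    row_index: Optional[np.ndarray] = None  # indices of kept rows in the input


# ---------------------------------------------------------------------------
# matrices
# ---------------------------------------------------------------------------

def reference_point_matrix(
    signal: Union[BinnedTrack, ComparisonTrack],
    anchors: Sequence[Anchor],
    upstream: int = 1500,
    downstream: int = 1500,
    bin: int = 500,
) -> SignalMatrix:
    """Mean signal in fixed bins around each anchor point, strand-oriented.

    TranscriptModel anchors use the TSS; interval anchors use the midpoint.
    Out-of-chromosome bins are NaN.
    """
    if len(anchors) == 0:
        raise ValidationError("empty anchor list")
    if upstream % bin or downstream % bin:
        raise ValidationError("upstream/downstream must be multiples of bin")
    track = _as_track(signal)
    n = (upstream + downstream) // bin
    rows = np.empty((len(anchors), n))
    for r, a in enumerate(anchors):
        chrom, point, strand = _anchor_point(a)
        if strand == "+":
            start = point - upstream
            row = [
                _window_mean(track, chrom, start + j * bin, start + (j + 1) * bin)
                for j in range(n)
            ]
        else:
            # a minus-strand row is the reversed window [point-downstream,
            # point+upstream), so column 0 is still 5' of the anchor
            start = point - downstream
            row = [
                _window_mean(track, chrom, start + j * bin, start + (j + 1) * bin)
                for j in range(n)
            ][::-1]
        rows[r] = row
    return SignalMatrix(list(anchors), "reference-point", upstream, downstream, bin, rows)


def scale_regions_matrix(
    signal: Union[BinnedTrack, ComparisonTrack],
    transcripts: Sequence[TranscriptModel],
    body_length: int = 5000,
    flank: int = 500,
    bin: int = 500,
) -> SignalMatrix:
    """Gene-body matrix with the body rescaled to ``body_length`` and
    unscaled flanks, strand-oriented (TSS on the left).

    Body bins are length-weighted means over equal fractions of the actual
    gene body. Transcripts shorter than one bin give a NaN row (warned).
    """
    if len(transcripts) == 0:
        raise ValidationError("empty transcript list")
    if body_length % bin or flank % bin:
        raise ValidationError("body_length and flank must be multiples of bin")
    track = _as_track(signal)
    nf = flank // bin
    nb = body_length // bin
    ncol = 2 * nf + nb
    rows = np.full((len(transcripts), ncol), np.nan)
    short = 0
    for r, tx in enumerate(transcripts):
        if tx.length < bin:
            short += 1
            continue
        chrom = tx.chrom
        sgn = 1 if tx.strand == "+" else -1
        cols: List[float] = []
        # upstream flank (5' of TSS), unscaled
        for j in range(nf):
            a = tx.tss + sgn * (-(flank) + j * bin)
            b = a + sgn * bin
            cols.append(_window_mean(track, chrom, min(a, b), max(a, b)))
        # body, rescaled: nb equal fractions of the real body
        L = tx.length
        for j in range(nb):
            a = tx.tss + sgn * (L * j / nb)
            b = tx.tss + sgn * (L * (j + 1) / nb)
            cols.append(_window_mean(track, chrom, min(a, b), max(a, b)))
        # downstream flank (3' of TES), unscaled
        for j in range(nf):
            a = tx.tes + sgn * (j * bin)
            b = a + sgn * bin
            cols.append(_window_mean(track, chrom, min(a, b), max(a, b)))
        rows[r] = cols
    if short:
        warnings.warn(f"{short} transcripts shorter than one bin -> NaN rows")
    return SignalMatrix(
        list(transcripts), "scale-regions", flank, flank, bin, rows,
        body_length=body_length,
    )


# ---------------------------------------------------------------------------
# TSS scoring / ranking
# ---------------------------------------------------------------------------

def tss_window_scores(
    comparison: ComparisonTrack,
    transcripts: Sequence[TranscriptModel],
    halfwidth: int = 1500,
    which: str = "kd_vs_ctrl",
) -> List[TSSResponse]:
    """Mean log2FC over [tss - halfwidth, tss + halfwidth) per transcript.

    Fills the ``which`` slot of each TSSResponse; call repeatedly (via
    :func:`fill_tss_scores`) for the three comparisons. NaN scores are kept
    in the list but excluded from ranking.
    """
    out = []
    for tx in transcripts:
        score = _window_mean(
            comparison.track, tx.chrom, tx.tss - halfwidth, tx.tss + halfwidth
        )
        resp = TSSResponse(tx.transcript_id, tx.gene_id, tx.chrom, tx.tss)
        setattr(resp, which, score)
        out.append(resp)
    return out


def fill_tss_scores(
    responses: Sequence[TSSResponse],
    comparison: ComparisonTrack,
    transcripts: Sequence[TranscriptModel],
    halfwidth: int = 1500,
    which: str = "wt_vs_lacz",
) -> None:
    """Fill another comparison's window scores into existing responses
    (matched by transcript order)."""
    for resp, tx in zip(responses, transcripts):
        setattr(
            resp, which,
            _window_mean(comparison.track, tx.chrom, tx.tss - halfwidth, tx.tss + halfwidth),
        )


def n_positive(responses: Sequence[TSSResponse], which: str = "kd_vs_ctrl") -> int:
    return sum(1 for r in responses if np.isfinite(getattr(r, which)) and getattr(r, which) > 0)


def rank_and_select(
    responses: Sequence[TSSResponse], n: Optional[int] = None
) -> List[TSSResponse]:
    """Stable descending sort by the KD-vs-control score; ties broken by
    (chrom, tss, transcript_id). NaN scores are excluded (warned). Ranks
    (1-based) are written onto the returned records."""
    finite = [r for r in responses if np.isfinite(r.kd_vs_ctrl)]
    if len(finite) < len(responses):
        warnings.warn(f"{len(responses) - len(finite)} all-NaN TSS windows excluded")
    ordered = sorted(
        finite, key=lambda r: (-r.kd_vs_ctrl, r.chrom, r.tss, r.transcript_id)
    )
    for i, r in enumerate(ordered, 1):
        r.rank = i
    if n is None:
        return ordered
    if n > len(ordered):
        warnings.warn(f"requested top {n} of {len(ordered)}; returning all")
        n = len(ordered)
    return ordered[:n]


# ---------------------------------------------------------------------------
# clustering
# ---------------------------------------------------------------------------

def _wcss(X: np.ndarray, labels: np.ndarray, centroids: np.ndarray) -> float:
    return float(((X - centroids[labels]) ** 2).sum())


def kmeans_cluster(
    matrix: np.ndarray,
    k: int = 3,
    seed: int = 17,
    n_init: int = 10,
    standardize: bool = False,
) -> ClusterResult:
    """k-means with k-means++ restarts; deterministic given ``seed``.

    Rows containing NaN are dropped (recorded in ``dropped_rows``). Cluster
    indices are relabeled by descending centroid mean of the first feature,
    so cluster 0 is the one with the largest first-comparison increase.
    """
    X = np.asarray(matrix, dtype=float)
    if X.ndim != 2:
        raise ValidationError("matrix must be 2-D")
    keep = np.isfinite(X).all(axis=1)
    dropped = list(np.nonzero(~keep)[0])
    X = X[keep]
    if X.shape[0] < k:
        raise ValidationError(f"{X.shape[0]} finite rows < k={k}")
    if standardize:
        sd = X.std(axis=0)
        sd[sd == 0] = 1.0
        X = (X - X.mean(axis=0)) / sd
    if k == 1:
        centroid = X.mean(axis=0, keepdims=True)
        labels = np.zeros(X.shape[0], dtype=int)
        wcss = _wcss(X, labels, centroid)
        return ClusterResult(labels, 1, centroid, {1: wcss}, seed,
                             dropped, np.nonzero(keep)[0])
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed).fit(X)
    order = np.argsort(-km.cluster_centers_[:, 0])  # descending first feature
    relabel = np.empty(k, dtype=int)
    relabel[order] = np.arange(k)
    labels = relabel[km.labels_]
    centroids = km.cluster_centers_[order]
    return ClusterResult(
        labels, k, centroids, {k: float(km.inertia_)}, seed,
        dropped, np.nonzero(keep)[0],
    )


def elbow_select_k(
    matrix: np.ndarray,
    k_range: Sequence[int] = range(1, 9),
    seed: int = 17,
    n_init: int = 10,
) -> Tuple[int, Dict[int, float], float]:
    """Choose k by the elbow of the WCSS curve.

    The elbow is the interior k maximising the discrete second difference
    WCSS(k-1) - 2 WCSS(k) + WCSS(k+1). Returns ``(k, wcss_by_k,
    elbow_strength)`` where the strength is the winning second difference
    normalised by WCSS(k_min) (near zero for structureless data).
    """
    ks = sorted(k_range)
    if len(ks) < 3:
        raise ValidationError("k_range must contain at least 3 values")
    X = np.asarray(matrix, dtype=float)
    X = X[np.isfinite(X).all(axis=1)]
    wcss: Dict[int, float] = {}
    for k in ks:
        wcss[k] = kmeans_cluster(X, k=k, seed=seed, n_init=n_init).wcss_by_k[k]
    best_k, best_d2 = None, -np.inf
    for i in range(1, len(ks) - 1):
        d2 = wcss[ks[i - 1]] - 2 * wcss[ks[i]] + wcss[ks[i + 1]]
        if d2 > best_d2:
            best_k, best_d2 = ks[i], d2
    strength = best_d2 / wcss[ks[0]] if wcss[ks[0]] > 0 else 0.0
    return best_k, wcss, float(strength)


def elbow_from_curve(wcss_by_k: Dict[int, float]) -> int:
    """Elbow k from an already-computed WCSS curve (second-difference rule)."""
    ks = sorted(wcss_by_k)
    if len(ks) < 3:
        raise ValidationError("need at least 3 curve points")
    best_k, best_d2 = None, -np.inf
    for i in range(1, len(ks) - 1):
        d2 = wcss_by_k[ks[i - 1]] - 2 * wcss_by_k[ks[i]] + wcss_by_k[ks[i + 1]]
        if d2 > best_d2:
            best_k, best_d2 = ks[i], d2
    return best_k


# ---------------------------------------------------------------------------
# annotation / profiles
# ---------------------------------------------------------------------------

def annotate_to_genes(
    items: Sequence[Union[TSSResponse, GenomicInterval]],
    transcripts: Sequence[TranscriptModel],
) -> List[str]:
    """Map each row to a gene: TSS rows to their own gene, generic intervals
    to the gene whose TSS is nearest the interval midpoint (ties -> smaller
    gene_id)."""
    if len(transcripts) == 0:
        raise ValidationError("empty transcript set")
    by_chrom: Dict[str, List[Tuple[int, str]]] = {}
    for tx in transcripts:
        by_chrom.setdefault(tx.chrom, []).append((tx.tss, tx.gene_id))
    for lst in by_chrom.values():
        lst.sort()
    out = []
    for it in items:
        if isinstance(it, TSSResponse):
            out.append(it.gene_id)
            continue
        mid = it.midpoint
        cands = by_chrom.get(it.chrom, [])
        if not cands:
            # fall back to any chromosome is meaningless; report no gene
            out.append("")
            continue
        best = min(cands, key=lambda t: (abs(t[0] - mid), t[1]))
        out.append(best[1])
    return out


def aggregate_profile(
    matrix: SignalMatrix, row_subset: Optional[Sequence[int]] = None
) -> Tuple[np.ndarray, np.ndarray]:
    """NaN-ignoring column means and standard errors for a row subset
    (all rows when ``row_subset`` is None)."""
    vals = matrix.values
    if row_subset is not None:
        idx = np.asarray(list(row_subset), dtype=int)
        if idx.size == 0:
            raise ValidationError("empty row subset")
        vals = vals[idx]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(vals, axis=0)
        n = np.isfinite(vals).sum(axis=0)
        sd = np.nanstd(vals, axis=0, ddof=1)
    sem = np.where(n > 1, sd / np.sqrt(np.maximum(n, 1)), np.nan)
    return mean, sem
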