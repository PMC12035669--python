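"""Arithmetic on binned tracks: CPM normalization, replicate averaging,
pseudocounted log2 fold change, genome-wide Pearson correlation and
replicate PCA.

The pseudocount used in log2 ratios is the single most result-sensitive
constant in the whole pipeline; it defaults to 1.0 applied on the CPM scale
and is recorded on every :class:`ComparisonTrack`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Sequence

import numpy as np
import pandas as pd

from .genomic_io import BinnedTrack, ValidationError

__all__ = [
    "ComparisonTrack",
    "CorrelationMatrix",
    "PCAResult",
    "cpm_normalize",
    "average_tracks",
    "log2fc_track",
    "correlation_matrix",
    "pca_scores",
]


@dataclass
class ComparisonTrack:
    """log2((numerator + c) / (denominator + c)) per bin, with provenance."""

    track: BinnedTrack
    pseudocount: float
    numerator_label: str
    denominator_label: str

    @property
    def bin_size(self) -> int:
        return self.track.bin_size

    @property
    def values(self) -> Dict[str, np.ndarray]:
        return self.track.values


@dataclass
class CorrelationMatrix:
    labels: List[str]
    matrix: np.ndarray
    bin_size: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.labels, columns=self.labels)


@dataclass
class PCAResult:
    labels: List[str]
    scores: np.ndarray          # samples x components
    variance_explained: np.ndarray  # fraction per component


def cpm_normalize(track: BinnedTrack) -> BinnedTrack:
    """Counts-per-million scaling: value_i * 1e6 / sum(values).

    All finite bin values must be non-negative and their sum positive.
    """
    flat = track.flat()
    if np.nanmin(flat) < 0:
        raise ValidationError("CPM requires non-negative counts")
    total = float(np.nansum(flat))
    if total == 0:
        raise ValidationError("CPM undefined for an all-zero track")
    scaled = {c: v * 1e6 / total for c, v in track.values.items()}
    out = track.copy_with(scaled, normalized=True)
    out.raw_total = total  # type: ignore[attr-defined]
    return out


def average_tracks(tracks: Sequence[BinnedTrack]) -> BinnedTrack:
    """Bin-wise arithmetic mean over replicates (NaN propagates)."""
    if len(tracks) == 0:
        raise ValidationError("need at least one track")
    first = tracks[0]
    for t in tracks[1:]:
        if not first.same_grid(t):
            raise ValidationError("tracks are on different bin grids")
    values = {
        c: np.mean([t.values[c] for t in tracks], axis=0) for c in first.chrom_sizes
    }
    return first.copy_with(values)


def log2fc_track(
    a: BinnedTrack,
    b: BinnedTrack,
    pseudocount: float = 1.0,
    numerator_label: str = "a",
    denominator_label: str = "b",
) -> ComparisonTrack:
    """Per-bin log2((a_i + c) / (b_i + c)); both inputs on the same grid.

    Intended for CPM-scaled inputs (deepTools bigwigCompare semantics);
    the pseudocount c (default 1.0) guards zero bins.
    """
    if pseudocount <= 0:
        raise ValidationError(f"pseudocount must be > 0, got {pseudocount}")
    if not a.same_grid(b):
        raise ValidationError("tracks are on different bin grids")
    values = {
        c: np.log2((a.values[c] + pseudocount) / (b.values[c] + pseudocount))
        for c in a.chrom_sizes
    }
    track = a.copy_with(values, normalized=False, missing_policy="nan")
    return ComparisonTrack(track, pseudocount, numerator_label, denominator_label)


def correlation_matrix(
    tracks: Sequence[BinnedTrack],
    labels: Sequence[str],
    bin_size: int = 100_000,
) -> CorrelationMatrix:
    """Pairwise Pearson r between tracks mean-pooled to ``bin_size`` bins.

    Bins with NaN are excluded pairwise-complete. Pairs with fewer than two
    shared finite bins get NaN (with a warning).
    """
    if len(tracks) != len(labels):
        raise ValidationError("one label per track required")
    cols = {lab: t.rebin(bin_size).flat() for lab, t in zip(labels, tracks)}
    df = pd.DataFrame(cols)
    mat = df.corr(method="pearson", min_periods=2).to_numpy()
    np.fill_diagonal(mat, 1.0)
    if np.isnan(mat).any():
        warnings.warn("some track pairs share < 2 finite bins; NaN entries emitted")
    # pandas corr is symmetric by construction; enforce exactly
    mat = (mat + mat.T) / 2
    return CorrelationMatrix(list(labels), mat, bin_size)


def pca_scores(
    tracks: Sequence[BinnedTrack],
    labels: Sequence[str],
    bin_size: int = 10_000,
    n_components: int = 2,
) -> PCAResult:
    """PCA of samples over genome bins (bins = features).

    Rows with any NaN across samples are dropped; features (bins) are
    mean-centered. Deterministic up to sign; the sign is fixed so that the
    loading with the largest absolute value is positive.
    """
    if len(tracks) < 2:
        raise ValidationError("PCA needs at least 2 samples")
    X = np.column_stack([t.rebin(bin_size).flat() for t in tracks])  # bins x samples
    X = X[np.isfinite(X).all(axis=1)]
    if X.shape[0] < 2:
        raise ValidationError("fewer than 2 finite bins shared by all samples")
    Xc = (X - X.mean(axis=1, keepdims=True)).T  # samples x bins, bin-centered
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    k = min(n_components, len(S))
    scores = U[:, :k] * S[:k]
    for j in range(k):  # sign convention: dominant loading positive
        i = np.argmax(np.abs(Vt[j]))
        if Vt[j, i] < 0:
            scores[:, j] *= -1
            Vt[j] *= -1
    total = float((S ** 2).sum())
    var = (S[:k] ** 2) / total if total > 0 else np.zeros(k)
    return PCAResult(list(labels), scores, var)
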