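"""A/B compartment calls and compartment-boundary analysis from a Hi-C PC1
track.

A bin is A when PC1 > 0 and B when PC1 < 0; a boundary sits on the edge
between two adjacent bins of opposite sign. Zero or missing PC1 bins
inherit the previous non-missing sign (leading gaps take the first
non-missing sign), so a zero never produces a spurious double flip.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np

from .genomic_io import BinnedTrack, GenomicInterval, ValidationError
from .trackops import ComparisonTrack

__all__ = [
    "CompartmentCall",
    "Boundary",
    "classify_bins",
    "detect_boundaries",
    "boundary_aggregation",
    "boundaries_to_bed",
]


@dataclass
class CompartmentCall:
    """Per-bin labels aligned to a PC1 track: 'A', 'B' or 'U' (undefined)."""

    bin_size: int
    labels: Dict[str, np.ndarray]  # arrays of 'A'/'B'/'U'

    def counts(self) -> Dict[str, int]:
        flat = np.concatenate(list(self.labels.values()))
        return {lab: int((flat == lab).sum()) for lab in ("A", "B", "U")}


@dataclass(frozen=True)
class Boundary:
    chrom: str
    position: int          # bp of the edge between the two flanking bins
    orientation: str       # 'B->A' or 'A->B', read along increasing coordinate

    def __post_init__(self):
        if self.orientation not in {"B->A", "A->B"}:
            raise ValidationError(f"bad orientation {self.orientation!r}")


def classify_bins(pc1: BinnedTrack) -> CompartmentCall:
    """Sign-based A/B calls; NaN -> undefined, exact zero -> undefined.

    (Zeros are resolved by inheritance only for boundary detection; as a
    plain per-bin call a zero carries no compartment information.)
    """
    labels = {}
    for chrom, vals in pc1.values.items():
        lab = np.full(len(vals), "U", dtype="<U1")
        with np.errstate(invalid="ignore"):
            lab[vals > 0] = "A"
            lab[vals < 0] = "B"
        labels[chrom] = lab
    return CompartmentCall(pc1.bin_size, labels)


def _filled_signs(vals: np.ndarray) -> np.ndarray:
    """+1/-1 per bin; zeros and NaNs inherit the previous non-missing sign,
    leading ones the first non-missing sign. All-missing -> all zeros."""
    sign = np.zeros(len(vals), dtype=int)
    with np.errstate(invalid="ignore"):
        sign[vals > 0] = 1
        sign[vals < 0] = -1
    nz = np.nonzero(sign)[0]
    if len(nz) == 0:
        return sign
    out = sign.copy()
    # forward fill, then back-fill the leading stretch
    last = sign[nz[0]]
    for i in range(len(out)):
        if out[i] == 0:
            out[i] = last
        else:
            last = out[i]
    return out


def detect_boundaries(pc1: BinnedTrack, min_run: int = 1) -> List[Boundary]:
    """Boundaries at every edge where the filled sign sequence flips.

    With ``min_run`` > 1 a flip is only reported where both flanking
    same-sign runs span at least ``min_run`` bins, suppressing flicker in
    noisy PC1 tracks; ``min_run=1`` is the literal sign-change rule.
    """
    if min_run < 1:
        raise ValidationError(f"min_run must be >= 1, got {min_run}")
    out: List[Boundary] = []
    for chrom, vals in pc1.values.items():
        signs = _filled_signs(vals)
        if not signs.any():
            continue
        # run-length encode
        runs: List[Tuple[int, int]] = []  # (sign, length)
        for s in signs:
            if runs and runs[-1][0] == s:
                runs[-1] = (s, runs[-1][1] + 1)
            else:
                runs.append((s, 1))
        pos = 0
        for i in range(len(runs) - 1):
            pos += runs[i][1]
            if runs[i][1] >= min_run and runs[i + 1][1] >= min_run:
                orientation = "B->A" if runs[i][0] < 0 else "A->B"
                out.append(Boundary(chrom, pos * pc1.bin_size, orientation))
    return out


def _prefix(track: BinnedTrack, chrom: str):
    """Cached prefix integrals of a track along one chromosome: value
    integral and finite-coverage integral in bp, enabling O(1) window
    means. Invalidated implicitly because tracks are treated as
    immutable after construction."""
    cache = getattr(track, "_prefix_cache", None)
    if cache is None:
        cache = {}
        track._prefix_cache = cache  # type: ignore[attr-defined]
    if chrom not in cache:
        vals = track.values[chrom]
        bs = track.bin_size
        n = len(vals)
        widths = np.full(n, float(bs))
        widths[-1] = track.chrom_sizes[chrom] - (n - 1) * bs
        fin = np.isfinite(vals)
        v0 = np.where(fin, vals, 0.0)
        cumv = np.concatenate(([0.0], np.cumsum(v0 * widths)))
        cumw = np.concatenate(([0.0], np.cumsum(fin * widths)))
        cache[chrom] = (cumv, cumw, widths, v0, fin)
    return cache[chrom]


def _integrals(track: BinnedTrack, chrom: str, x: float):
    """(value, finite-coverage) integrals of the track over [0, x)."""
    cumv, cumw, widths, v0, fin = _prefix(track, chrom)
    bs = track.bin_size
    x = min(max(x, 0.0), float(track.chrom_sizes[chrom]))
    b = int(x // bs)
    if b >= len(v0):
        return cumv[-1], cumw[-1]
    frac = min(x - b * bs, widths[b])
    V = cumv[b] + v0[b] * frac
    W = cumw[b] + (frac if fin[b] else 0.0)
    return V, W


def _window_mean(
    track: BinnedTrack, chrom: str, start: float, end: float
) -> float:
    """Length-weighted NaN-ignoring mean of a track over [start, end).

    Portions outside the chromosome and NaN bins are excluded from the
    weights; a fully missing window is NaN. Fractional coordinates are
    supported (used by scale-regions resampling).
    """
    if end <= start:
        return float("nan")
    v1, w1 = _integrals(track, chrom, start)
    v2, w2 = _integrals(track, chrom, end)
    w = w2 - w1
    return (v2 - v1) / w if w > 0 else float("nan")


def boundary_aggregation(
    signal: Union[BinnedTrack, ComparisonTrack],
    boundaries: Sequence[Boundary],
    flank: int = 1_000_000,
    bin: int = 50_000,
    mirror: bool = True,
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Mean signal profile across compartment boundaries.

    Each boundary contributes a window of 2*flank/bin bins centred on the
    boundary edge, oriented B->A left-to-right (A->B boundaries are
    mirrored when ``mirror`` is true, else skipped). Returns
    ``(offsets_bp, mean_profile, per_boundary_matrix)``; the mean is
    NaN-ignoring and windows running off a chromosome are NaN-padded.
    """
    if isinstance(signal, ComparisonTrack):
        signal = signal.track
    if len(boundaries) == 0:
        raise ValidationError("need at least one boundary")
    if flank % bin != 0:
        raise ValidationError("flank must be a multiple of bin")
    n = 2 * flank // bin
    rows = []
    for b in boundaries:
        if b.orientation == "A->B" and not mirror:
            continue
        row = np.array([
            _window_mean(signal, b.chrom, b.position - flank + j * bin,
                         b.position - flank + (j + 1) * bin)
            for j in range(n)
        ])
        if b.orientation == "A->B":
            row = row[::-1]
        rows.append(row)
    if not rows:
        raise ValidationError("no boundaries usable under mirror=False")
    mat = np.vstack(rows)
    import warnings as _warnings
    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(mat, axis=0)
    offsets = np.arange(-flank, flank, bin) + bin // 2
    return offsets, mean, mat


def boundaries_to_bed(boundaries: Sequence[Boundary]) -> List[GenomicInterval]:
    """One 1-bp interval per boundary, name = orientation."""
    return [
        GenomicInterval(b.chrom, b.position, b.position + 1, name=b.orientation)
        for b in boundaries
    ]
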