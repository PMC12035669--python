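"""Genomic file formats and fixed-bin track containers.

Everything downstream of this module works on two in-memory shapes:
:class:`BinnedTrack` (a fixed-bin-size numeric signal per chromosome,
holding CPM coverage, Hi-C PC1 or DamID log-ratios alike) and lists of
:class:`GenomicInterval` / :class:`TranscriptModel`.

Coordinates are 0-based half-open (BED convention) everywhere internally;
GTF's 1-based inclusive coordinates are converted on read.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Optional, Sequence

import numpy as np

__all__ = [
    "ChromSizes",
    "GenomicInterval",
    "BinnedTrack",
    "TranscriptModel",
    "read_chrom_sizes",
    "write_chrom_sizes",
    "read_bed",
    "write_bed",
    "read_bedgraph_to_track",
    "write_track",
    "read_transcripts",
    "longest_transcript_per_gene",
]

_STRANDS = {"+", "-", "."}


class ParseError(ValueError):
    """A malformed record in a genomic text file (carries the line number)."""


class ValidationError(ValueError):
    """A record that parses but violates coordinate bounds."""


class ChromSizes(dict):
    """Ordered map chromosome name -> length in bp.

    A thin dict subclass so callers can use plain mapping syntax; insertion
    order defines chromosome order throughout the pipeline.
    """

    def __init__(self, items=()):
        super().__init__()
        for name, length in dict(items).items():
            length = int(length)
            if length < 1:
                raise ValidationError(f"chromosome {name!r} has length {length} < 1")
            self[name] = length

    def n_bins(self, chrom: str, bin_size: int) -> int:
        return math.ceil(self[chrom] / bin_size)


@dataclass(frozen=True)
class GenomicInterval:
    chrom: str
    start: int
    end: int
    name: Optional[str] = None
    score: Optional[float] = None
    strand: str = "."

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"interval {self.chrom}:{self.start}-{self.end} is empty or negative"
            )
        if self.strand not in _STRANDS:
            raise ValidationError(f"bad strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        # even-length intervals: midpoint = start + floor(length/2)
        return self.start + self.length // 2

    def validate(self, chrom_sizes: ChromSizes) -> "GenomicInterval":
        if self.chrom not in chrom_sizes:
            raise ValidationError(f"unknown chromosome {self.chrom!r}")
        if self.end > chrom_sizes[self.chrom]:
            raise ValidationError(
                f"interval {self.chrom}:{self.start}-{self.end} exceeds "
                f"chromosome length {chrom_sizes[self.chrom]}"
            )
        return self


@dataclass(frozen=True)
class TranscriptModel:
    """One transcript; tss/tes are strand-aware (minus strand: tss > tes)."""

    gene_id: str
    transcript_id: str
    chrom: str
    strand: str
    tss: int
    tes: int

    def __post_init__(self):
        if self.strand not in {"+", "-"}:
            raise ValidationError(f"transcript strand must be +/-, got {self.strand!r}")
        if self.tss == self.tes:
            raise ValidationError(f"{self.transcript_id}: tss == tes")
        if self.strand == "+" and not self.tss < self.tes:
            raise ValidationError(f"{self.transcript_id}: + strand requires tss < tes")
        if self.strand == "-" and not self.tss > self.tes:
            raise ValidationError(f"{self.transcript_id}: - strand requires tss > tes")

    @property
    def length(self) -> int:
        return abs(self.tes - self.tss)

    @property
    def start(self) -> int:
        return min(self.tss, self.tes)

    @property
    def end(self) -> int:
        return max(self.tss, self.tes)


@dataclass
class BinnedTrack:
    """Fixed-bin-size numeric signal per chromosome.

    ``values[chrom]`` has length ceil(len/bin_size); the last bin may cover a
    partial tail of the chromosome (its shorter effective width is honoured
    by the weighted-mean readers). ``missing_policy`` records how uncovered
    bins were filled: ``"zero"`` for count-derived tracks (zero coverage is
    meaningful) or ``"nan"`` for PC1/DamID-style tracks (absent is absent).
    """

    chrom_sizes: ChromSizes
    bin_size: int
    values: Dict[str, np.ndarray]
    missing_policy: str = "zero"
    normalized: bool = False

    def __post_init__(self):
        if self.bin_size < 1:
            raise ValidationError(f"bin_size must be >= 1, got {self.bin_size}")
        if self.missing_policy not in {"zero", "nan"}:
            raise ValidationError(f"bad missing_policy {self.missing_policy!r}")
        for chrom in self.chrom_sizes:
            expected = self.chrom_sizes.n_bins(chrom, self.bin_size)
            arr = np.asarray(self.values.get(chrom, None), dtype=float)
            if arr.ndim != 1 or arr.shape[0] != expected:
                raise ValidationError(
                    f"{chrom}: expected {expected} bins, got "
                    f"{None if chrom not in self.values else arr.shape}"
                )
            self.values[chrom] = arr

    # -- convenience -------------------------------------------------------
    def copy_with(self, values: Dict[str, np.ndarray], **kw) -> "BinnedTrack":
        return replace(self, values={c: np.asarray(v, float) for c, v in values.items()}, **kw)

    def flat(self) -> np.ndarray:
        """All bins concatenated in chromosome order."""
        return np.concatenate([self.values[c] for c in self.chrom_sizes])

    def total(self) -> float:
        return float(np.nansum(self.flat()))

    def bin_width(self, chrom: str, i: int) -> int:
        """Effective width of bin i (the terminal bin may be partial)."""
        return min(self.bin_size, self.chrom_sizes[chrom] - i * self.bin_size)

    def same_grid(self, other: "BinnedTrack") -> bool:
        return (
            self.bin_size == other.bin_size
            and dict(self.chrom_sizes) == dict(other.chrom_sizes)
        )

    def rebin(self, bin_size: int) -> "BinnedTrack":
        """Mean-pool to a coarser grid (NaN-ignoring, width-weighted)."""
        if bin_size % self.bin_size != 0:
            raise ValidationError(
                f"target bin {bin_size} not a multiple of {self.bin_size}"
            )
        if bin_size == self.bin_size:
            return self
        out = {}
        for chrom, vals in self.values.items():
            n_out = self.chrom_sizes.n_bins(chrom, bin_size)
            widths = np.array(
                [self.bin_width(chrom, i) for i in range(len(vals))], dtype=float
            )
            res = np.full(n_out, np.nan)
            ratio = bin_size // self.bin_size
            for j in range(n_out):
                sl = slice(j * ratio, min((j + 1) * ratio, len(vals)))
                v, w = vals[sl], widths[sl]
                ok = np.isfinite(v)
                if ok.any():
                    res[j] = np.average(v[ok], weights=w[ok])
            out[chrom] = res
        return BinnedTrack(
            self.chrom_sizes, bin_size, out,
            missing_policy=self.missing_policy, normalized=self.normalized,
        )


# ---------------------------------------------------------------------------
# chrom.sizes
# ---------------------------------------------------------------------------

def read_chrom_sizes(path) -> ChromSizes:
    sizes = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ParseError(f"{path}:{lineno}: expected two columns")
            sizes[parts[0]] = int(parts[1])
    return ChromSizes(sizes)


def write_chrom_sizes(sizes: ChromSizes, path) -> None:
    with open(path, "w") as fh:
        for name, length in sizes.items():
            fh.write(f"{name}\t{length}\n")


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------

def read_bed(path, chrom_sizes: Optional[ChromSizes] = None) -> List[GenomicInterval]:
    """Read a 3-6 column BED file, preserving input order.

    Intervals are bound-checked against ``chrom_sizes`` when given.
    """
    out: List[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith(("track", "browser", "#")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError(f"{path}:{lineno}: fewer than 3 BED columns")
            try:
                iv = GenomicInterval(
                    chrom=parts[0],
                    start=int(parts[1]),
                    end=int(parts[2]),
                    name=parts[3] if len(parts) > 3 and parts[3] != "." else None,
                    score=float(parts[4]) if len(parts) > 4 and parts[4] != "." else None,
                    strand=parts[5] if len(parts) > 5 else ".",
                )
            except ValidationError:
                raise
            except ValueError as e:
                raise ParseError(f"{path}:{lineno}: {e}") from e
            if chrom_sizes is not None:
                iv.validate(chrom_sizes)
            out.append(iv)
    return out


def write_bed(intervals: Sequence[GenomicInterval], path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fields = [iv.chrom, str(iv.start), str(iv.end)]
            if iv.name is not None or iv.score is not None or iv.strand != ".":
                fields.append(iv.name if iv.name is not None else ".")
                fields.append(f"{iv.score:.6g}" if iv.score is not None else ".")
                fields.append(iv.strand)
            fh.write("\t".join(fields) + "\n")


# ---------------------------------------------------------------------------
# bedGraph <-> BinnedTrack
# ---------------------------------------------------------------------------

def read_bedgraph_to_track(
    path,
    chrom_sizes: ChromSizes,
    bin_size: int,
    missing_policy: str = "zero",
    normalized: bool = False,
) -> BinnedTrack:
    """Bin a bedGraph into a fixed grid.

    Each output bin is the coverage-length-weighted mean of the record
    values overlapping it; uncovered stretches contribute 0 under the
    ``"zero"`` policy and are excluded (NaN if nothing covers the bin)
    under ``"nan"``. Records must be non-overlapping per chromosome.
    """
    if bin_size < 1:
        raise ValidationError(f"bin_size must be >= 1, got {bin_size}")
    weighted = {c: np.zeros(chrom_sizes.n_bins(c, bin_size)) for c in chrom_sizes}
    covered = {c: np.zeros(chrom_sizes.n_bins(c, bin_size)) for c in chrom_sizes}
    last_end: Dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith(("track", "browser", "#")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ParseError(f"{path}:{lineno}: fewer than 4 bedGraph columns")
            try:
                chrom, start, end, value = parts[0], int(parts[1]), int(parts[2]), float(parts[3])
            except ValueError as e:
                raise ParseError(f"{path}:{lineno}: {e}") from e
            GenomicInterval(chrom, start, end).validate(chrom_sizes)
            if start < last_end.get(chrom, 0):
                raise ValidationError(
                    f"{path}:{lineno}: overlapping records on {chrom} "
                    f"(start {start} < previous end {last_end[chrom]})"
                )
            last_end[chrom] = end
            b0, b1 = start // bin_size, (end - 1) // bin_size
            for b in range(b0, b1 + 1):
                lo = max(start, b * bin_size)
                hi = min(end, (b + 1) * bin_size)
                weighted[chrom][b] += value * (hi - lo)
                covered[chrom][b] += hi - lo
    values = {}
    for chrom in chrom_sizes:
        w, c = weighted[chrom], covered[chrom]
        if missing_policy == "zero":
            # uncovered bp count as zero signal across the full bin width
            widths = np.array(
                [min(bin_size, chrom_sizes[chrom] - i * bin_size) for i in range(len(w))],
                dtype=float,
            )
            values[chrom] = w / widths
        else:
            with np.errstate(invalid="ignore", divide="ignore"):
                values[chrom] = np.where(c > 0, w / np.maximum(c, 1e-300), np.nan)
    return BinnedTrack(chrom_sizes, bin_size, values,
                       missing_policy=missing_policy, normalized=normalized)


def write_track(track: BinnedTrack, path) -> None:
    """Write a BinnedTrack as bedGraph (one record per finite bin)."""
    with open(path, "w") as fh:
        for chrom in track.chrom_sizes:
            vals = track.values[chrom]
            for i, v in enumerate(vals):
                if not np.isfinite(v):
                    continue
                start = i * track.bin_size
                end = min(start + track.bin_size, track.chrom_sizes[chrom])
                fh.write(f"{chrom}\t{start}\t{end}\t{v:.6g}\n")


# ---------------------------------------------------------------------------
# transcripts (GTF subset or simplified TSV)
# ---------------------------------------------------------------------------

def _gtf_attr(attr_field: str, key: str, path, lineno: int) -> str:
    for chunk in attr_field.rstrip(";").split(";"):
        chunk = chunk.strip()
        if chunk.startswith(key + " "):
            return chunk[len(key):].strip().strip('"')
    raise ParseError(f"{path}:{lineno}: missing mandatory attribute {key!r}")


def read_transcripts(path) -> List[TranscriptModel]:
    """Read transcript models from GTF (transcript features) or 6-column TSV.

    The TSV dialect is ``gene_id  transcript_id  chrom  strand  start  end``
    with 0-based half-open genomic start/end; TSS/TES are derived from the
    strand. GTF is detected by a 9th attribute column.
    """
    out: List[TranscriptModel] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) >= 9:  # GTF
                if parts[2] != "transcript":
                    continue
                chrom, start1, end1, strand = parts[0], int(parts[3]), int(parts[4]), parts[6]
                start, end = start1 - 1, end1  # GTF is 1-based inclusive
                gene_id = _gtf_attr(parts[8], "gene_id", path, lineno)
                tx_id = _gtf_attr(parts[8], "transcript_id", path, lineno)
            elif len(parts) == 6:
                if lineno == 1 and parts[0].lower() in {"gene_id", "gene"}:
                    continue
                gene_id, tx_id, chrom, strand = parts[0], parts[1], parts[2], parts[3]
                start, end = int(parts[4]), int(parts[5])
            else:
                raise ParseError(
                    f"{path}:{lineno}: expected GTF (9 cols) or transcript TSV (6 cols)"
                )
            tss, tes = (start, end) if strand == "+" else (end, start)
            out.append(TranscriptModel(gene_id, tx_id, chrom, strand, tss, tes))
    return out


def longest_transcript_per_gene(
    transcripts: Iterable[TranscriptModel],
) -> List[TranscriptModel]:
    """Keep one transcript per gene: the longest, ties broken by the
    lexicographically smallest transcript_id. Deterministic under any input
    order; output sorted by gene_id."""
    best: Dict[str, TranscriptModel] = {}
    for tx in transcripts:
        cur = best.get(tx.gene_id)
        if (
            cur is None
            or tx.length > cur.length
            or (tx.length == cur.length and tx.transcript_id < cur.transcript_id)
        ):
            best[tx.gene_id] = tx
    return [best[g] for g in sorted(best)]
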