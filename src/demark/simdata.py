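"""Seeded synthetic-epigenome generator.

Plants every structure the pipeline is meant to infer and emits both
standard-format inputs (chrom.sizes, bedGraph tracks, transcript TSV,
count TSV, LAD BED) and machine-readable ground truth, so recovery can be
scored exactly:

* alternating A/B compartment segments with a PC1-like track,
* H3K9me2-style count tracks for a knockdown / rescue / iron-chelator
  condition panel, where demethylation effects are restricted to the A
  compartment (diffuse) and to planted TSS windows (focal),
* negative-binomial expression counts with planted iron-dependent genes
  and single-condition decoys,
* preadipocyte-specific LADs in two signal groups plus a few extreme
  outliers, with lamin B1 levels that fall from day 0 to day 9.

All randomness flows from one seed through ``numpy.random.SeedSequence``;
a fixed seed reproduces byte-identical files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .genomic_io import (
    BinnedTrack,
    ChromSizes,
    GenomicInterval,
    TranscriptModel,
    ValidationError,
)
from .targets import CountMatrix

__all__ = [
    "SimConfig",
    "SimTruth",
    "simulate_genome",
    "simulate_chromatin_tracks",
    "simulate_expression_counts",
    "simulate_lads",
    "simulate_all",
    "simulate_null_counts",
    "CHROMATIN_CONDITIONS",
    "DEMETHYLATING",
]

# condition panel: (condition, day); demethylation is active in the
# conditions listed in DEMETHYLATING (endogenous enzyme present, wild-type
# rescue, or iron available)
CHROMATIN_CONDITIONS: List[Tuple[str, int]] = (
    [("sh-Empty", d) for d in (0, 2, 8)]
    + [("sh-Jmjd1a", d) for d in (0, 2, 8)]
    + [("KD+LacZ", 2), ("KD+WT", 2), ("KD+H1122A", 2), ("vehicle", 2), ("DFO", 2)]
)
DEMETHYLATING = {"sh-Empty", "KD+WT", "vehicle"}

TSS_CLASSES = ("demethylated", "unchanged", "opposite")


@dataclass
class SimConfig:
    seed: int = 0
    # genome / compartments
    chrom_lengths: Dict[str, int] = field(
        default_factory=lambda: {"chr1": 40_000_000, "chr2": 40_000_000}
    )
    # overall segment length range is 2-8 Mb; B segments are drawn from the
    # upper part so the B compartment reliably hosts the full LAD demand
    segment_range_A: Tuple[int, int] = (2_000_000, 4_000_000)
    segment_range_B: Tuple[int, int] = (6_000_000, 8_000_000)
    pc1_bin: int = 100_000
    pc1_amplitude: float = 1.0
    pc1_noise_sd: float = 0.2
    # chromatin tracks
    track_bin: int = 1_000
    base_mean_A: float = 30.0        # expected counts per bin, A compartment
    base_mean_B: float = 60.0        # repressive mark enriched in B
    bin_lognorm_sd: float = 0.3      # fixed per-bin biological variability
    n_replicates: int = 2
    # genes / TSS classes
    n_genes: int = 2_000
    frac_genes_in_A: float = 0.6     # for the 'unchanged' class
    tss_class_props: Tuple[float, float, float] = (0.15, 0.70, 0.15)
    delta: float = 0.5               # focal TSS/gene-body effect, log2 units
    diffuse_delta: float = 0.4       # diffuse A-compartment effect, log2 units
    gene_length_min: int = 5_000
    gene_length_max: int = 10_000
    gene_spacing: int = 14_000
    # expression
    expr_replicates: int = 3
    expr_mean_range: Tuple[float, float] = (50.0, 500.0)
    expr_dispersion: float = 0.1
    de_fold: float = 4.0
    n_iron_genes: int = 100
    iron_in_demeth_cluster: int = 60  # iron genes drawn from the demethylated class
    n_decoys_per_type: int = 30
    # LADs / lamin B1
    n_lads: int = 200
    lad_len_min: int = 110_000
    lad_len_max: int = 130_000
    lad_margin: int = 500_000   # LAD analysis windows stay inside B segments
    lad_gap: int = 20_000
    lad_group_props: Tuple[float, float] = (0.4, 0.6)  # B1-like, B2-like
    lad_high_fold: float = 1.8   # regional elevation of high-H3K9me2 segments
    lad_enrichment: float = 1.5  # in-LAD enrichment, group-independent
    outlier_count: int = 5
    outlier_fold: float = 50.0
    outlier_halfwidth: int = 480_000  # extreme signal spans most of the analysis window
    lamin_bin: int = 10_000
    lamin_background: float = -0.5
    lamin_day0_b2: float = 0.7
    lamin_day0_shift: float = 0.3    # B1-like above B2-like at day 0
    lamin_day9: float = 0.2          # both groups, after differentiation
    lamin_noise_sd: float = 0.2

    def __post_init__(self):
        if abs(sum(self.tss_class_props) - 1.0) > 1e-9:
            raise ValidationError("tss_class_props must sum to 1")
        if abs(sum(self.lad_group_props) - 1.0) > 1e-9:
            raise ValidationError("lad_group_props must sum to 1")
        for name in ("pc1_noise_sd", "bin_lognorm_sd", "lamin_noise_sd"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        for rng_ in (self.segment_range_A, self.segment_range_B):
            if rng_[1] > min(self.chrom_lengths.values()):
                raise ValidationError("segment range exceeds a chromosome length")
            if rng_[0] % self.pc1_bin or rng_[1] % self.pc1_bin:
                raise ValidationError("segment bounds must be multiples of pc1_bin")


@dataclass
class SimTruth:
    """Planted ground truth, sufficient to score every recovery test."""

    segments: List[GenomicInterval]            # name = 'A' or 'B'
    boundaries: List[Tuple[str, int, str]]     # (chrom, position, orientation)
    tss_class: Dict[str, str]                  # gene_id -> class
    gene_compartment: Dict[str, str]           # gene_id -> 'A'/'B'
    de_truth: Dict[str, Dict[str, bool]]       # gene_id -> three contrast flags
    iron_genes: List[str]
    demeth_driven_genes: List[str]             # iron genes in the demethylated class
    lad_group: List[str]                       # per LAD: 'B1-like'/'B2-like'/'outlier'
    lamin_day0_means: Dict[str, float]
    lamin_day9_mean: float
    high_segments: List[GenomicInterval] = field(default_factory=list)

    def compartment_of(self, chrom: str, pos: int) -> str:
        for seg in self.segments:
            if seg.chrom == chrom and seg.start <= pos < seg.end:
                return seg.name
        return "U"

    def to_json(self, path) -> None:
        payload = {
            "segments": [
                [s.chrom, s.start, s.end, s.name] for s in self.segments
            ],
            "boundaries": [list(b) for b in self.boundaries],
            "tss_class": self.tss_class,
            "gene_compartment": self.gene_compartment,
            "de_truth": self.de_truth,
            "iron_genes": self.iron_genes,
            "demeth_driven_genes": self.demeth_driven_genes,
            "lad_group": self.lad_group,
            "lamin_day0_means": self.lamin_day0_means,
            "lamin_day9_mean": self.lamin_day9_mean,
            "high_segments": [
                [s.chrom, s.start, s.end] for s in self.high_segments
            ],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "SimTruth":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            segments=[GenomicInterval(c, s, e, name=n) for c, s, e, n in d["segments"]],
            boundaries=[tuple(b) for b in d["boundaries"]],
            tss_class=d["tss_class"],
            gene_compartment=d["gene_compartment"],
            de_truth=d["de_truth"],
            iron_genes=d["iron_genes"],
            demeth_driven_genes=d["demeth_driven_genes"],
            lad_group=d["lad_group"],
            lamin_day0_means=d["lamin_day0_means"],
            lamin_day9_mean=d["lamin_day9_mean"],
            high_segments=[
                GenomicInterval(c, s, e) for c, s, e in d.get("high_segments", [])
            ],
        )


@dataclass
class SimGenome:
    chrom_sizes: ChromSizes
    segments: List[GenomicInterval]
    pc1: BinnedTrack
    truth: SimTruth
    transcripts: List[TranscriptModel] = field(default_factory=list)
    lads: List[GenomicInterval] = field(default_factory=list)


def _rngs(seed: int, n: int) -> List[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


# ---------------------------------------------------------------------------
# genome / compartments
# ---------------------------------------------------------------------------

def simulate_genome(cfg: SimConfig) -> SimGenome:
    """Alternating A/B segments plus a noisy PC1 track at 100-kb bins.

    Segment edges are multiples of the PC1 bin, so the planted boundaries
    are exactly recoverable from a noiseless track.
    """
    rng = _rngs(cfg.seed, 8)[0]
    sizes = ChromSizes(cfg.chrom_lengths)
    segments: List[GenomicInterval] = []
    boundaries: List[Tuple[str, int, str]] = []
    for chrom, length in sizes.items():
        label = "A" if rng.random() < 0.5 else "B"
        pos = 0
        while pos < length:
            lo, hi = (cfg.segment_range_A if label == "A" else cfg.segment_range_B)
            n_bins = rng.integers(lo // cfg.pc1_bin, hi // cfg.pc1_bin + 1)
            end = min(pos + int(n_bins) * cfg.pc1_bin, length)
            segments.append(GenomicInterval(chrom, pos, end, name=label))
            if end < length:
                orientation = "A->B" if label == "A" else "B->A"
                boundaries.append((chrom, end, orientation))
            pos = end
            label = "B" if label == "A" else "A"

    values: Dict[str, np.ndarray] = {}
    for chrom in sizes:
        n = sizes.n_bins(chrom, cfg.pc1_bin)
        vals = np.empty(n)
        for seg in segments:
            if seg.chrom != chrom:
                continue
            b0, b1 = seg.start // cfg.pc1_bin, -(-seg.end // cfg.pc1_bin)
            vals[b0:b1] = cfg.pc1_amplitude if seg.name == "A" else -cfg.pc1_amplitude
        vals += rng.normal(0, cfg.pc1_noise_sd, n)
        values[chrom] = vals
    pc1 = BinnedTrack(sizes, cfg.pc1_bin, values, missing_policy="nan")

    truth = SimTruth(
        segments=segments,
        boundaries=boundaries,
        tss_class={},
        gene_compartment={},
        de_truth={},
        iron_genes=[],
        demeth_driven_genes=[],
        lad_group=[],
        lamin_day0_means={
            "B1-like": cfg.lamin_day0_b2 + cfg.lamin_day0_shift,
            "B2-like": cfg.lamin_day0_b2,
            "outlier": cfg.lamin_day0_b2,
        },
        lamin_day9_mean=cfg.lamin_day9,
    )
    genome = SimGenome(sizes, segments, pc1, truth)
    _place_genes(cfg, genome)
    return genome


def _place_genes(cfg: SimConfig, genome: SimGenome) -> None:
    """Assign genes to compartment-internal slots and plant TSS classes.

    Demethylation-responsive classes ('demethylated' and 'opposite') are
    placed only in the A compartment, matching the restriction of the
    planted chromatin effects; 'unchanged' genes go to A with probability
    ``frac_genes_in_A`` and otherwise to B.
    """
    rng = _rngs(cfg.seed, 8)[1]
    margin = 2_000
    slots = {"A": [], "B": []}
    for seg in genome.segments:
        lo = seg.start + cfg.gene_spacing // 2
        hi = seg.end - cfg.gene_length_max - margin
        for p in range(lo, hi, cfg.gene_spacing):
            slots[seg.name].append((seg.chrom, p))
    for lst in slots.values():
        rng.shuffle(lst)

    props = cfg.tss_class_props
    n_dem = int(round(props[0] * cfg.n_genes))
    n_opp = int(round(props[2] * cfg.n_genes))
    n_unc = cfg.n_genes - n_dem - n_opp
    classes = (["demethylated"] * n_dem + ["opposite"] * n_opp
               + ["unchanged"] * n_unc)
    compartments = ["A"] * (n_dem + n_opp) + [
        "A" if rng.random() < cfg.frac_genes_in_A else "B" for _ in range(n_unc)
    ]
    if n_dem + n_opp > len(slots["A"]) or cfg.n_genes > len(slots["A"]) + len(slots["B"]):
        raise ValidationError("gene demand exceeds compartment slot capacity")

    order = rng.permutation(cfg.n_genes)
    transcripts: List[TranscriptModel] = []
    ia = ib = 0
    for rank, gi in enumerate(order):
        gene_id = f"gene{gi:04d}"
        klass, comp = classes[rank], compartments[rank]
        # 'unchanged' genes are compartment-agnostic: spill to the other
        # compartment when the preferred one runs out of slots
        if klass == "unchanged":
            if comp == "A" and ia >= len(slots["A"]):
                comp = "B"
            elif comp == "B" and ib >= len(slots["B"]):
                comp = "A"
        if comp == "A":
            chrom, pos = slots["A"][ia]; ia += 1
        else:
            chrom, pos = slots["B"][ib]; ib += 1
        length = int(rng.integers(cfg.gene_length_min // 1000,
                                  cfg.gene_length_max // 1000 + 1)) * 1000
        strand = "+" if rng.random() < 0.5 else "-"
        if strand == "+":
            tss, tes = pos, pos + length
        else:
            tss, tes = pos + length, pos
        transcripts.append(
            TranscriptModel(gene_id, f"tx{gi:04d}", chrom, strand, tss, tes)
        )
        genome.truth.tss_class[gene_id] = klass
        genome.truth.gene_compartment[gene_id] = comp
    transcripts.sort(key=lambda t: t.gene_id)
    genome.transcripts = transcripts


# ---------------------------------------------------------------------------
# chromatin tracks
# ---------------------------------------------------------------------------

def _base_log2_means(cfg: SimConfig, genome: SimGenome,
                     rng: np.random.Generator) -> Dict[str, np.ndarray]:
    """Condition-independent per-bin log2 mean counts.

    Compartment baseline, fixed lognormal bin variability, regional
    elevation of the high-H3K9me2 B segments (the B1-like LAD context), a
    group-independent in-LAD enrichment, and saturated constant-level
    blocks around the planted outlier LADs."""
    out = {}
    for chrom in genome.chrom_sizes:
        n = genome.chrom_sizes.n_bins(chrom, cfg.track_bin)
        base = np.full(n, np.log2(cfg.base_mean_A))
        for seg in genome.segments:
            if seg.chrom != chrom or seg.name != "B":
                continue
            b0, b1 = seg.start // cfg.track_bin, -(-seg.end // cfg.track_bin)
            base[b0:b1] = np.log2(cfg.base_mean_B)
        base += rng.normal(0, cfg.bin_lognorm_sd, n) / np.log(2)
        out[chrom] = base
    for seg in genome.truth.high_segments:
        b0, b1 = seg.start // cfg.track_bin, -(-seg.end // cfg.track_bin)
        out[seg.chrom][b0:b1] += np.log2(cfg.lad_high_fold)
    for lad, group in zip(genome.lads, genome.truth.lad_group):
        if group == "outlier":
            # extreme regions are saturated blocks at a constant level over
            # most of the analysis window, mutually near-identical, so they
            # form one tight cluster rather than several singletons
            lo = lad.midpoint - cfg.outlier_halfwidth
            hi = lad.midpoint + cfg.outlier_halfwidth
            b0 = max(0, lo // cfg.track_bin)
            b1 = min(len(out[lad.chrom]), -(-hi // cfg.track_bin))
            out[lad.chrom][b0:b1] = np.log2(cfg.base_mean_B * cfg.outlier_fold)
            continue
        b0 = max(0, lad.start // cfg.track_bin)
        b1 = min(len(out[lad.chrom]), -(-lad.end // cfg.track_bin))
        out[lad.chrom][b0:b1] += np.log2(cfg.lad_enrichment)
    return out


def _effect_bins(cfg: SimConfig, genome: SimGenome) -> Dict[str, np.ndarray]:
    """Per-bin demethylation effect (log2 units) applied to demethylating
    conditions as a *decrease*: +delta at planted-responsive gene regions
    (sign flipped for the 'opposite' class), +diffuse_delta elsewhere in A,
    0 in B."""
    eff = {}
    for chrom in genome.chrom_sizes:
        n = genome.chrom_sizes.n_bins(chrom, cfg.track_bin)
        e = np.zeros(n)
        for seg in genome.segments:
            if seg.chrom != chrom or seg.name != "A":
                continue
            b0, b1 = seg.start // cfg.track_bin, -(-seg.end // cfg.track_bin)
            e[b0:b1] = cfg.diffuse_delta
        eff[chrom] = e
    for tx in genome.transcripts:
        klass = genome.truth.tss_class[tx.gene_id]
        if klass == "unchanged":
            # the TSS window carries the class signature exactly: an
            # unchanged TSS is pinned at zero, not at the diffuse level
            lo, hi = tx.tss - 1500, tx.tss + 1500
            level = 0.0
        else:
            sign = 1.0 if klass == "demethylated" else -1.0
            lo = min(tx.tss, tx.tes) - 1500
            hi = max(tx.tss, tx.tes) + 1500
            level = sign * cfg.delta
        b0 = max(0, lo // cfg.track_bin)
        b1 = min(len(eff[tx.chrom]), -(-hi // cfg.track_bin))
        eff[tx.chrom][b0:b1] = level
    return eff


def simulate_chromatin_tracks(
    cfg: SimConfig,
    genome: SimGenome,
    conditions: Optional[Sequence[Tuple[str, int]]] = None,
) -> Dict[Tuple[str, int], List[BinnedTrack]]:
    """Poisson count tracks per (condition, day) and replicate.

    Demethylating conditions (endogenous enzyme, WT rescue, vehicle) have
    their bin means divided by 2**effect relative to the demethylation-
    deficient conditions (knockdown, LacZ, catalytic mutant, iron
    chelation); the effect field is A-compartment-restricted.
    """
    rngs = _rngs(cfg.seed, 8)
    base = _base_log2_means(cfg, genome, rngs[2])
    effect = _effect_bins(cfg, genome)
    draw = rngs[3]
    wanted = CHROMATIN_CONDITIONS if conditions is None else list(conditions)
    out: Dict[Tuple[str, int], List[BinnedTrack]] = {}
    for cond, day in wanted:
        demethylating = cond in DEMETHYLATING
        reps = []
        for _ in range(cfg.n_replicates):
            values = {}
            for chrom in genome.chrom_sizes:
                mean = 2.0 ** (
                    base[chrom] - (effect[chrom] if demethylating else 0.0)
                )
                values[chrom] = draw.poisson(mean).astype(float)
            reps.append(
                BinnedTrack(genome.chrom_sizes, cfg.track_bin, values,
                            missing_policy="zero")
            )
        out[(cond, day)] = reps
    return out


def simulate_lamin_tracks(
    cfg: SimConfig, genome: SimGenome
) -> Tuple[BinnedTrack, BinnedTrack]:
    """Lamin B1 log-ratio tracks (day 0, day 9) at 10-kb bins.

    LADs sit above background at day 0 with a planted B1-like > B2-like
    shift; by day 9 both groups decay to the same lower level, so lamin B1
    falls in every group regardless of its chromatin signal."""
    rng = _rngs(cfg.seed, 8)[4]
    day0, day9 = {}, {}
    for chrom in genome.chrom_sizes:
        n = genome.chrom_sizes.n_bins(chrom, cfg.lamin_bin)
        day0[chrom] = np.full(n, cfg.lamin_background)
        day9[chrom] = np.full(n, cfg.lamin_background)
    for lad, group in zip(genome.lads, genome.truth.lad_group):
        b0 = lad.start // cfg.lamin_bin
        b1 = -(-lad.end // cfg.lamin_bin)
        day0[lad.chrom][b0:b1] = genome.truth.lamin_day0_means[group]
        day9[lad.chrom][b0:b1] = cfg.lamin_day9
    for chrom in genome.chrom_sizes:
        day0[chrom] = day0[chrom] + rng.normal(0, cfg.lamin_noise_sd, len(day0[chrom]))
        day9[chrom] = day9[chrom] + rng.normal(0, cfg.lamin_noise_sd, len(day9[chrom]))
    t0 = BinnedTrack(genome.chrom_sizes, cfg.lamin_bin, day0, missing_policy="nan")
    t9 = BinnedTrack(genome.chrom_sizes, cfg.lamin_bin, day9, missing_policy="nan")
    return t0, t9


# ---------------------------------------------------------------------------
# LADs
# ---------------------------------------------------------------------------

def simulate_lads(cfg: SimConfig, genome: SimGenome) -> List[GenomicInterval]:
    """Place non-overlapping LADs inside B segments and assign groups.

    Groups: 'B1-like' (high chromatin signal), 'B2-like' (low), and
    ``outlier_count`` extreme LADs whose surrounding window carries
    ``outlier_fold`` times the background signal."""
    rng = _rngs(cfg.seed, 8)[5]
    b_segments = [s for s in genome.segments if s.name == "B"]
    slots: List[Tuple[str, int, int]] = []
    for seg in b_segments:
        pos = seg.start + cfg.lad_margin
        while pos + cfg.lad_len_max + cfg.lad_margin <= seg.end:
            length = int(rng.integers(cfg.lad_len_min // 10_000,
                                      cfg.lad_len_max // 10_000 + 1)) * 10_000
            slots.append((seg.chrom, pos, pos + length))
            pos += cfg.lad_len_max + cfg.lad_gap
    # extreme LADs first, mutually distant and clear of every other LAD's
    # analysis window (their saturated domain must not leak into it)
    radius = cfg.outlier_halfwidth + 500_000
    order = list(rng.permutation(len(slots)))
    outlier_slots: List[int] = []
    for i in order:
        mid_i = (slots[i][1] + slots[i][2]) // 2
        if all(
            slots[j][0] != slots[i][0]
            or abs((slots[j][1] + slots[j][2]) // 2 - mid_i) >= 2 * radius
            for j in outlier_slots
        ):
            outlier_slots.append(i)
        if len(outlier_slots) == cfg.outlier_count:
            break
    eligible = [
        i for i in range(len(slots))
        if i not in outlier_slots
        and all(
            slots[j][0] != slots[i][0]
            or abs((slots[j][1] + slots[j][2]) // 2
                   - (slots[i][1] + slots[i][2]) // 2) >= radius
            for j in outlier_slots
        )
    ]
    n_rest = cfg.n_lads - cfg.outlier_count
    if len(outlier_slots) < cfg.outlier_count or len(eligible) < n_rest:
        raise ValidationError(
            f"LAD demand ({cfg.n_lads}) exceeds B-segment capacity "
            f"({len(eligible)} + {len(outlier_slots)} usable slots)"
        )
    rest = list(rng.choice(eligible, size=n_rest, replace=False))

    # the B1-like / B2-like distinction is regional: whole B segments are
    # either high- or low-H3K9me2 and their LADs inherit the group
    def segment_of(slot: Tuple[str, int, int]) -> GenomicInterval:
        for seg in b_segments:
            if seg.chrom == slot[0] and seg.start <= slot[1] < seg.end:
                return seg
        raise AssertionError("slot outside every B segment")

    per_seg: Dict[Tuple[str, int], int] = {}
    for i in rest:
        seg = segment_of(slots[i])
        per_seg[(seg.chrom, seg.start)] = per_seg.get((seg.chrom, seg.start), 0) + 1
    seg_order = list(rng.permutation(len(b_segments)))
    target = cfg.lad_group_props[0] * n_rest
    high_keys, acc = set(), 0
    for si in seg_order:
        if acc >= target:
            break
        seg = b_segments[si]
        key = (seg.chrom, seg.start)
        if per_seg.get(key, 0) == 0:
            continue
        high_keys.add(key)
        acc += per_seg[key]
    genome.truth.high_segments = [
        s for s in b_segments if (s.chrom, s.start) in high_keys
    ]

    chosen = sorted(
        [(i, "outlier") for i in outlier_slots]
        + [
            (i, "B1-like" if (segment_of(slots[i]).chrom,
                              segment_of(slots[i]).start) in high_keys
             else "B2-like")
            for i in rest
        ]
    )
    lads = [GenomicInterval(*slots[i], name=f"LAD{j:04d}")
            for j, (i, _) in enumerate(chosen)]
    genome.lads = lads
    genome.truth.lad_group = [g for _, g in chosen]
    return lads


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------

def _nb_draw(rng: np.random.Generator, mean: np.ndarray, phi: float) -> np.ndarray:
    if phi <= 0:
        return rng.poisson(mean)
    r = 1.0 / phi
    p = r / (r + mean)
    return rng.negative_binomial(r, p)


def simulate_expression_counts(cfg: SimConfig, genome: SimGenome) -> CountMatrix:
    """NB gene counts for the five-condition rescue design.

    Planted iron-dependent genes are down in knockdown vs control, up in WT
    rescue vs LacZ, and down in the catalytic mutant vs WT; decoy genes
    violate exactly one of the three conditions to stress the set logic.
    A subset of the iron genes is drawn from the 'demethylated' TSS class
    (the planted demethylation-driven genes); the rest from 'unchanged'.
    """
    rng = _rngs(cfg.seed, 8)[6]
    genes = sorted(genome.truth.tss_class)
    demeth = [g for g in genes if genome.truth.tss_class[g] == "demethylated"]
    unchanged = [g for g in genes if genome.truth.tss_class[g] == "unchanged"]
    if cfg.iron_in_demeth_cluster > len(demeth):
        raise ValidationError("not enough demethylated-class genes for iron set")
    n_from_unch = cfg.n_iron_genes - cfg.iron_in_demeth_cluster
    iron = (list(rng.choice(demeth, cfg.iron_in_demeth_cluster, replace=False))
            + list(rng.choice(unchanged, n_from_unch, replace=False)))
    pool = [g for g in unchanged if g not in set(iron)]
    decoys = list(rng.choice(pool, 3 * cfg.n_decoys_per_type, replace=False))

    lo, hi = cfg.expr_mean_range
    mu = np.exp(rng.uniform(np.log(lo), np.log(hi), len(genes)))
    mu_by_gene = dict(zip(genes, mu))

    de_truth: Dict[str, Dict[str, bool]] = {}
    for g in genes:
        de_truth[g] = {"down_in_KD": False, "up_in_WT_rescue": False,
                       "down_in_mutant_vs_WT": False}
    for g in iron:
        de_truth[g] = {"down_in_KD": True, "up_in_WT_rescue": True,
                       "down_in_mutant_vs_WT": True}
    flag_names = ("down_in_KD", "up_in_WT_rescue", "down_in_mutant_vs_WT")
    for t in range(3):
        for g in decoys[t * cfg.n_decoys_per_type:(t + 1) * cfg.n_decoys_per_type]:
            flags = {k: True for k in flag_names}
            flags[flag_names[t]] = False   # violate exactly this condition
            de_truth[g] = flags

    f = cfg.de_fold
    cond_means: Dict[str, np.ndarray] = {}
    for cond in ("sh-Empty", "sh-Jmjd1a", "KD+LacZ", "KD+WT", "KD+H1122A"):
        m = np.empty(len(genes))
        for i, g in enumerate(genes):
            base = mu_by_gene[g]
            flags = de_truth[g]
            if cond == "sh-Empty":
                m[i] = base
            elif cond == "sh-Jmjd1a":
                m[i] = base / f if flags["down_in_KD"] else base
            elif cond == "KD+WT":
                m[i] = base
            elif cond == "KD+LacZ":
                m[i] = base / f if flags["up_in_WT_rescue"] else base
            elif cond == "KD+H1122A":
                m[i] = base / f if flags["down_in_mutant_vs_WT"] else base
        cond_means[cond] = m

    columns, data, cond_of = [], [], {}
    for cond in cond_means:
        depth = rng.uniform(0.8, 1.2, cfg.expr_replicates)
        for rep in range(cfg.expr_replicates):
            name = f"{cond}_rep{rep + 1}"
            columns.append(name)
            cond_of[name] = cond
            data.append(_nb_draw(rng, cond_means[cond] * depth[rep],
                                 cfg.expr_dispersion))
    counts = pd.DataFrame(
        np.column_stack(data), index=pd.Index(genes, name="gene_id"),
        columns=columns,
    )
    genome.truth.de_truth = de_truth
    genome.truth.iron_genes = sorted(iron)
    genome.truth.demeth_driven_genes = sorted(
        g for g in iron if genome.truth.tss_class[g] == "demethylated"
    )
    return CountMatrix(counts, cond_of)


def simulate_null_counts(
    n_genes: int = 2_000,
    n_reps: int = 3,
    phi: float = 0.1,
    seed: int = 0,
    mean_range: Tuple[float, float] = (50.0, 500.0),
) -> CountMatrix:
    """Two equal-mean NB conditions, for type-I-error calibration."""
    rng = np.random.default_rng(seed)
    mu = np.exp(rng.uniform(np.log(mean_range[0]), np.log(mean_range[1]), n_genes))
    columns, data, cond_of = [], [], {}
    for cond in ("groupA", "groupB"):
        for rep in range(n_reps):
            name = f"{cond}_rep{rep + 1}"
            columns.append(name)
            cond_of[name] = cond
            data.append(_nb_draw(rng, mu, phi))
    counts = pd.DataFrame(
        np.column_stack(data),
        index=pd.Index([f"gene{i:04d}" for i in range(n_genes)], name="gene_id"),
        columns=columns,
    )
    return CountMatrix(counts, cond_of)


def simulate_tss_response_matrix(
    cfg: SimConfig,
    genome: SimGenome,
    noise_sd: float = 0.15,
    seed: Optional[int] = None,
) -> Tuple[np.ndarray, np.ndarray, List[str]]:
    """Three-comparison TSS score matrix straight from the planted classes.

    Rows follow ``sorted(gene_id)``; columns are (KD vs ctrl, WT rescue vs
    LacZ, mutant vs WT) log2FC scores: the planted class signature plus
    Gaussian noise. Returns (matrix, integer class labels, gene ids)."""
    rng = np.random.default_rng(cfg.seed + 101 if seed is None else seed)
    genes = sorted(genome.truth.tss_class)
    signatures = {
        "demethylated": np.array([cfg.delta, -cfg.delta, cfg.delta]),
        "unchanged": np.zeros(3),
        "opposite": np.array([-cfg.delta, cfg.delta, -cfg.delta]),
    }
    X = np.vstack([signatures[genome.truth.tss_class[g]] for g in genes])
    X = X + rng.normal(0, noise_sd, X.shape)
    labels = np.array([TSS_CLASSES.index(genome.truth.tss_class[g]) for g in genes])
    return X, labels, genes


# ---------------------------------------------------------------------------
# one-call driver
# ---------------------------------------------------------------------------

def simulate_all(cfg: SimConfig) -> Dict[str, object]:
    """Run all generators in dependency order; returns a dict with keys
    genome, chromatin (condition->replicate tracks), lamin (day0, day9),
    counts, lads, truth."""
    genome = simulate_genome(cfg)
    lads = simulate_lads(cfg, genome)
    chromatin = simulate_chromatin_tracks(cfg, genome)
    lamin = simulate_lamin_tracks(cfg, genome)
    counts = simulate_expression_counts(cfg, genome)
    return {
        "genome": genome,
        "chromatin": chromatin,
        "lamin": lamin,
        "counts": counts,
        "lads": lads,
        "truth": genome.truth,
    }
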