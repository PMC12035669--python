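"""Differential expression on count matrices and the set logic that calls
iron-dependent demethylase targets.

The differential test is a deliberately simple negative-binomial Wald test
with a single pooled (common) dispersion estimated by the method of
moments: the scientific weight here is carried by the three-contrast set
logic (down on knockdown, restored by wild-type rescue, not restored by the
catalytically dead iron-coordination mutant), not by the test itself.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .genomic_io import ValidationError

__all__ = [
    "CountMatrix",
    "DEGRecord",
    "TargetSet",
    "CONDITIONS",
    "nb_differential_test",
    "bh_adjust",
    "deg_sets",
    "intersect_targets",
    "demethylation_targets",
]

# the five expression conditions of the knockdown / rescue design
CONDITIONS = ("sh-Empty", "sh-Jmjd1a", "KD+LacZ", "KD+WT", "KD+H1122A")


@dataclass
class CountMatrix:
    """Genes x samples non-negative integer counts with a condition map."""

    counts: pd.DataFrame                    # index = gene_id, columns = sample ids
    condition_of: Dict[str, str]            # sample id -> condition

    def __post_init__(self):
        arr = self.counts.to_numpy()
        if (arr < 0).any():
            raise ValidationError("counts must be non-negative")
        if not np.allclose(arr, np.round(arr)):
            raise ValidationError("counts must be integral")
        missing = set(self.counts.columns) - set(self.condition_of)
        if missing:
            raise ValidationError(f"samples without condition: {sorted(missing)}")

    def samples_for(self, condition: str) -> List[str]:
        return [s for s in self.counts.columns if self.condition_of[s] == condition]

    @property
    def library_sizes(self) -> pd.Series:
        return self.counts.sum(axis=0)


@dataclass
class DEGRecord:
    gene_id: str
    contrast: Tuple[str, str]
    log2fc: float
    pvalue: float
    fdr: float = float("nan")
    direction: str = "ns"      # 'up' | 'down' | 'ns'


@dataclass
class TargetSet:
    """Genes with boolean provenance flags from the three-contrast logic."""

    flags: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(
        columns=["down_in_KD", "up_in_WT_rescue", "down_in_mutant_vs_WT",
                 "in_demethylation_cluster"], dtype=bool))

    @property
    def iron_dependent(self) -> Set[str]:
        f = self.flags
        m = f["down_in_KD"] & f["up_in_WT_rescue"] & f["down_in_mutant_vs_WT"]
        return set(f.index[m])

    @property
    def demethylation(self) -> Set[str]:
        f = self.flags
        m = (f["down_in_KD"] & f["up_in_WT_rescue"]
             & f["down_in_mutant_vs_WT"] & f["in_demethylation_cluster"])
        return set(f.index[m])


# ---------------------------------------------------------------------------
# NB Wald test with pooled MoM dispersion
# ---------------------------------------------------------------------------

def _common_dispersion(norm: np.ndarray, groups: Sequence[np.ndarray]) -> float:
    """Pooled method-of-moments dispersion phi from var = mu + phi mu^2.

    For every gene x group with >= 2 replicates, accumulate (s^2 - m) and
    m^2 of the library-size-normalized counts; phi is the ratio of the
    pooled sums, floored at 0.
    """
    num = den = 0.0
    for idx in groups:
        sub = norm[:, idx]
        if sub.shape[1] < 2:
            continue
        m = sub.mean(axis=1)
        v = sub.var(axis=1, ddof=1)
        ok = m > 0
        num += float((v[ok] - m[ok]).sum())
        den += float((m[ok] ** 2).sum())
    return max(0.0, num / den) if den > 0 else 0.0


def nb_differential_test(
    counts: CountMatrix,
    contrast: Tuple[str, str],
    pseudocount: float = 0.5,
) -> List[DEGRecord]:
    """Per-gene Wald test of condA vs condB on library-size-normalized
    negative-binomial counts.

    Counts are scaled to the mean library size; a common dispersion phi is
    estimated by pooled method of moments over both groups; the statistic is
    the log2 ratio of group means (pseudocounted) over its delta-method
    standard error, referred to a standard normal (two-sided). Genes with
    all-zero counts are removed. Records are returned sorted by p-value.
    """
    cond_a, cond_b = contrast
    samples_a = counts.samples_for(cond_a)
    samples_b = counts.samples_for(cond_b)
    if not samples_a or not samples_b:
        raise ValidationError(f"contrast condition absent: {contrast}")
    cols = samples_a + samples_b
    mat = counts.counts[cols]
    nonzero = mat.sum(axis=1) > 0
    mat = mat[nonzero]
    lib = counts.counts[cols].sum(axis=0)
    norm = (mat / lib * lib.mean()).to_numpy(dtype=float)
    na, nb = len(samples_a), len(samples_b)
    idx_a, idx_b = np.arange(na), np.arange(na, na + nb)
    phi = _common_dispersion(norm, [idx_a, idx_b])

    mu_a = norm[:, idx_a].mean(axis=1)
    mu_b = norm[:, idx_b].mean(axis=1)
    c = pseudocount
    log2fc = np.log2((mu_a + c) / (mu_b + c))
    # Var(mean) = (mu + phi mu^2)/n; delta method on log2(mu + c)
    var_a = (mu_a + phi * mu_a ** 2) / na
    var_b = (mu_b + phi * mu_b ** 2) / nb
    ln2 = np.log(2.0)
    se = np.sqrt(var_a / ((mu_a + c) * ln2) ** 2 + var_b / ((mu_b + c) * ln2) ** 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, log2fc / se, 0.0)
    pvals = 2 * stats.norm.sf(np.abs(z))
    pvals = np.clip(pvals, np.finfo(float).tiny, 1.0)

    records = [
        DEGRecord(g, contrast, float(fc), float(p))
        for g, fc, p in zip(mat.index, log2fc, pvals)
    ]
    records.sort(key=lambda r: (r.pvalue, r.gene_id))
    return records


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (monotonicity enforced)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def annotate_fdr(records: List[DEGRecord], fdr_threshold: float = 0.05) -> List[DEGRecord]:
    """Fill FDR (BH) and direction in place; direction is 'ns' unless the
    gene clears the FDR threshold with a non-zero fold change."""
    q = bh_adjust([r.pvalue for r in records])
    for r, qi in zip(records, q):
        r.fdr = float(qi)
        if qi < fdr_threshold and r.log2fc > 0:
            r.direction = "up"
        elif qi < fdr_threshold and r.log2fc < 0:
            r.direction = "down"
        else:
            r.direction = "ns"
    return records


# ---------------------------------------------------------------------------
# set logic
# ---------------------------------------------------------------------------

def deg_sets(
    records_by_contrast: Dict[str, List[DEGRecord]],
    fdr: float = 0.05,
) -> Tuple[Set[str], Set[str], Set[str]]:
    """The three directional DEG sets of the rescue design:

    Set1 = down in knockdown vs control, Set2 = up in WT rescue vs LacZ,
    Set3 = down in catalytic mutant vs WT — each at FDR < ``fdr``.

    ``records_by_contrast`` keys: 'kd_vs_ctrl', 'wt_vs_lacz', 'mut_vs_wt'.
    """
    required = ("kd_vs_ctrl", "wt_vs_lacz", "mut_vs_wt")
    for key in required:
        if key not in records_by_contrast:
            raise ValidationError(f"missing contrast {key!r}")

    def directional(key: str, sign: int) -> Set[str]:
        recs = annotate_fdr(list(records_by_contrast[key]), fdr)
        return {r.gene_id for r in recs
                if r.fdr < fdr and np.sign(r.log2fc) == sign}

    return (
        directional("kd_vs_ctrl", -1),
        directional("wt_vs_lacz", +1),
        directional("mut_vs_wt", -1),
    )


def intersect_targets(
    set1: Iterable[str], set2: Iterable[str], set3: Iterable[str]
) -> TargetSet:
    """Iron-dependent targets: genes in all three directional sets."""
    s1, s2, s3 = set(set1), set(set2), set(set3)
    genes = sorted(s1 | s2 | s3)
    flags = pd.DataFrame(
        {
            "down_in_KD": [g in s1 for g in genes],
            "up_in_WT_rescue": [g in s2 for g in genes],
            "down_in_mutant_vs_WT": [g in s3 for g in genes],
            "in_demethylation_cluster": [False] * len(genes),
        },
        index=pd.Index(genes, name="gene_id"),
    )
    return TargetSet(flags)


def demethylation_targets(
    targets: TargetSet, cluster_genes: Iterable[str]
) -> TargetSet:
    """Restrict the iron-dependent targets to those whose TSS falls in the
    demethylation-pattern cluster (the fourth provenance flag)."""
    cluster = set(cluster_genes)
    flags = targets.flags.copy()
    flags["in_demethylation_cluster"] = [g in cluster for g in flags.index]
    return TargetSet(flags)


def venn_cardinalities(
    set1: Set[str], set2: Set[str], set3: Set[str]
) -> Dict[str, int]:
    """All seven Venn cells for the three DEG sets (for the run report)."""
    return {
        "only_1": len(set1 - set2 - set3),
        "only_2": len(set2 - set1 - set3),
        "only_3": len(set3 - set1 - set2),
        "1_and_2": len((set1 & set2) - set3),
        "1_and_3": len((set1 & set3) - set2),
        "2_and_3": len((set2 & set3) - set1),
        "triple": len(set1 & set2 & set3),
    }
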