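"""Stage orchestration over a run directory.

Each stage reads the previous stages' standard-format outputs from
``<outdir>/<stage>/``, computes with the library modules, writes tabular
outputs, and appends an entry (parameters, input checksums, outputs) to
``<outdir>/manifest.json``. Re-running a stage with the same config and
seed reproduces byte-identical files.

Stage order: simulate -> tracks -> compartments / tss / deg ->
cluster-tss -> targets -> lads -> report.
"""

from __future__ import annotations

import copy
import hashlib
import json
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from . import compartments as comp_mod
from . import genomic_io as gio
from . import lads as lads_mod
from . import regions as reg
from . import simdata
from . import targets as tgt
from . import trackops as tops

__all__ = [
    "DEFAULT_CONFIG",
    "STAGES",
    "ConfigError",
    "DependencyError",
    "load_config",
    "run_stage",
    "report",
]

DAY2_COMPARISONS = {
    # label -> ((numerator cond, day), (denominator cond, day))
    "kd_vs_ctrl_d0": (("sh-Jmjd1a", 0), ("sh-Empty", 0)),
    "kd_vs_ctrl_d2": (("sh-Jmjd1a", 2), ("sh-Empty", 2)),
    "kd_vs_ctrl_d8": (("sh-Jmjd1a", 8), ("sh-Empty", 8)),
    "wt_vs_lacz": (("KD+WT", 2), ("KD+LacZ", 2)),
    "mut_vs_wt": (("KD+H1122A", 2), ("KD+WT", 2)),
    "dfo_vs_vehicle": (("DFO", 2), ("vehicle", 2)),
}

DEFAULT_CONFIG: Dict[str, dict] = {
    "simulate": {},  # SimConfig field overrides
    "tracks": {"pseudocount": 1.0, "correlation_bin": 100_000, "pca_bin": 10_000},
    "compartments": {"min_run": 1, "flank": 1_000_000, "bin": 50_000,
                     "mirror": True},
    "tss": {"halfwidth": 1_500, "top_n": 500},
    "cluster_tss": {"k": 3, "seed": 17, "n_init": 10, "standardize": True,
                    "k_range": [1, 8]},
    "deg": {"fdr": 0.05},
    "targets": {},
    "lads": {"flank": 500_000, "bin": 10_000, "k": 3, "seed": 17,
             "n_init": 10, "outlier_fold": 20.0, "outlier_max_frac": 0.05},
    "report": {},
}

STAGES = ("simulate", "tracks", "compartments", "tss", "cluster-tss",
          "deg", "targets", "lads", "report")

_STAGE_DEPS = {
    "simulate": (),
    "tracks": ("simulate",),
    "compartments": ("simulate", "tracks"),
    "tss": ("simulate", "tracks"),
    "cluster-tss": ("tss",),
    "deg": ("simulate",),
    "targets": ("deg", "cluster-tss"),
    "lads": ("simulate", "tracks"),
    "report": ("compartments", "tss", "cluster-tss", "targets", "lads"),
}


class ConfigError(ValueError):
    """Invalid or unknown configuration (CLI exit code 2)."""


class DependencyError(RuntimeError):
    """A required upstream stage has not been run (CLI exit code 3)."""


def load_config(path: Optional[str] = None) -> Dict[str, dict]:
    """Merge a YAML config over the documented defaults, validating keys."""
    cfg = copy.deepcopy(DEFAULT_CONFIG)
    if path is None:
        return cfg
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    if not isinstance(user, dict):
        raise ConfigError("config root must be a mapping")
    for section, values in user.items():
        if section not in cfg:
            raise ConfigError(f"unknown config section {section!r}")
        if values is None:
            continue
        if not isinstance(values, dict):
            raise ConfigError(f"config section {section!r} must be a mapping")
        if section == "simulate":
            valid = set(simdata.SimConfig.__dataclass_fields__)
        else:
            valid = set(cfg[section])
        for key in values:
            if key not in valid:
                raise ConfigError(f"unknown config key {section}.{key}")
        cfg[section].update(values)
    return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _append_manifest(outdir: Path, entry: dict) -> None:
    path = outdir / "manifest.json"
    manifest = []
    if path.exists():
        with open(path) as fh:
            manifest = json.load(fh)
    manifest = [e for e in manifest if e["stage"] != entry["stage"]] + [entry]
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)


def _require(outdir: Path, stage: str) -> Path:
    d = outdir / stage
    if not d.is_dir():
        raise DependencyError(
            f"stage output {d} missing; run the '{stage}' stage first"
        )
    return d


def _cond_key(cond: str, day: int) -> str:
    safe = cond.replace("+", "_").replace("-", "_")
    return f"{safe}_d{day}"


# ---------------------------------------------------------------------------
# stage implementations
# ---------------------------------------------------------------------------

def _stage_simulate(config, outdir: Path, seed: Optional[int]) -> dict:
    params = dict(config["simulate"])
    if seed is not None:
        params["seed"] = seed
    cfg = simdata.SimConfig(**params)
    sim = simdata.simulate_all(cfg)
    genome: simdata.SimGenome = sim["genome"]
    d = outdir / "simulate"
    d.mkdir(parents=True, exist_ok=True)
    gio.write_chrom_sizes(genome.chrom_sizes, d / "chrom.sizes")
    gio.write_track(genome.pc1, d / "pc1.bedgraph")
    gio.write_bed(genome.segments, d / "segments.bed")
    gio.write_bed(genome.lads, d / "lads.bed")
    tdir = d / "tracks"
    tdir.mkdir(exist_ok=True)
    for (cond, day), reps in sim["chromatin"].items():
        for i, track in enumerate(reps, 1):
            gio.write_track(track, tdir / f"{_cond_key(cond, day)}_rep{i}.bedgraph")
    gio.write_track(sim["lamin"][0], d / "laminB1_day0.bedgraph")
    gio.write_track(sim["lamin"][1], d / "laminB1_day9.bedgraph")
    with open(d / "transcripts.tsv", "w") as fh:
        fh.write("gene_id\ttranscript_id\tchrom\tstrand\tstart\tend\n")
        for tx in genome.transcripts:
            fh.write(f"{tx.gene_id}\t{tx.transcript_id}\t{tx.chrom}\t"
                     f"{tx.strand}\t{tx.start}\t{tx.end}\n")
    cm: tgt.CountMatrix = sim["counts"]
    cm.counts.to_csv(d / "counts.tsv", sep="\t")
    with open(d / "conditions.tsv", "w") as fh:
        fh.write("sample\tcondition\n")
        for s in cm.counts.columns:
            fh.write(f"{s}\t{cm.condition_of[s]}\n")
    genome.truth.to_json(d / "truth.json")
    return {"params": {**{k: str(v) for k, v in params.items()},
                       "seed": cfg.seed},
            "n_genes": cfg.n_genes, "n_lads": cfg.n_lads}


def _load_sim(outdir: Path):
    d = _require(outdir, "simulate")
    sizes = gio.read_chrom_sizes(d / "chrom.sizes")
    return d, sizes


def _load_track(path: Path, sizes, bin_size, missing="zero") -> gio.BinnedTrack:
    return gio.read_bedgraph_to_track(path, sizes, bin_size, missing_policy=missing)


def _track_bin_from_manifest(outdir: Path) -> int:
    # the simulate stage's track bin; fall back to the SimConfig default
    return int(DEFAULT_CONFIG["simulate"].get("track_bin",
               simdata.SimConfig.__dataclass_fields__["track_bin"].default))


def _stage_tracks(config, outdir: Path, seed) -> dict:
    d, sizes = _load_sim(outdir)
    p = config["tracks"]
    bin_size = _track_bin_from_manifest(outdir)
    out = outdir / "tracks"
    (out / "averaged").mkdir(parents=True, exist_ok=True)
    (out / "comparisons").mkdir(exist_ok=True)

    averaged: Dict[Tuple[str, int], gio.BinnedTrack] = {}
    replicate_tracks: Dict[str, gio.BinnedTrack] = {}
    for cond, day in simdata.CHROMATIN_CONDITIONS:
        key = _cond_key(cond, day)
        reps = []
        i = 1
        while (d / "tracks" / f"{key}_rep{i}.bedgraph").exists():
            raw = _load_track(d / "tracks" / f"{key}_rep{i}.bedgraph", sizes, bin_size)
            norm = tops.cpm_normalize(raw)
            replicate_tracks[f"{key}_rep{i}"] = norm
            reps.append(norm)
            i += 1
        if not reps:
            raise DependencyError(f"no replicate tracks found for {key}")
        avg = tops.average_tracks(reps)
        averaged[(cond, day)] = avg
        gio.write_track(avg, out / "averaged" / f"{key}.bedgraph")

    for label, (num, den) in DAY2_COMPARISONS.items():
        cmp_track = tops.log2fc_track(
            averaged[num], averaged[den], pseudocount=p["pseudocount"],
            numerator_label=_cond_key(*num), denominator_label=_cond_key(*den),
        )
        gio.write_track(cmp_track.track, out / "comparisons" / f"{label}.bedgraph")

    pc1 = _load_track(d / "pc1.bedgraph", sizes,
                      _pc1_bin(outdir), missing="nan")
    corr_tracks = [pc1] + [averaged[k] for k in sorted(averaged, key=str)]
    corr_labels = ["PC1"] + [_cond_key(*k) for k in sorted(averaged, key=str)]
    corr = tops.correlation_matrix(corr_tracks, corr_labels,
                                   bin_size=p["correlation_bin"])
    corr.to_frame().to_csv(out / "correlation.tsv", sep="\t",
                           float_format="%.6g")

    rep_labels = sorted(replicate_tracks)
    pca = tops.pca_scores([replicate_tracks[k] for k in rep_labels],
                          rep_labels, bin_size=p["pca_bin"])
    with open(out / "pca.tsv", "w") as fh:
        fh.write("sample\tPC1\tPC2\n")
        for lab, row in zip(pca.labels, pca.scores):
            fh.write(f"{lab}\t{row[0]:.6g}\t{row[1]:.6g}\n")
    with open(out / "metadata.json", "w") as fh:
        json.dump({"pseudocount": p["pseudocount"],
                   "correlation_bin": p["correlation_bin"],
                   "pca_bin": p["pca_bin"],
                   "pca_variance_explained": [round(float(v), 6)
                                              for v in pca.variance_explained],
                   "comparisons": {k: [list(v[0]), list(v[1])]
                                   for k, v in DAY2_COMPARISONS.items()}},
                  fh, indent=1, sort_keys=True)
    return {"params": p, "n_conditions": len(averaged)}


def _pc1_bin(outdir: Path) -> int:
    return int(simdata.SimConfig.__dataclass_fields__["pc1_bin"].default)


def _load_comparison(outdir: Path, label: str, sizes, bin_size,
                     pseudocount: float) -> tops.ComparisonTrack:
    path = _require(outdir, "tracks") / "comparisons" / f"{label}.bedgraph"
    if not path.exists():
        raise DependencyError(f"comparison track {label} missing; run 'tracks'")
    track = _load_track(path, sizes, bin_size, missing="nan")
    num, den = DAY2_COMPARISONS[label]
    return tops.ComparisonTrack(track, pseudocount,
                                _cond_key(*num), _cond_key(*den))


def _stage_compartments(config, outdir: Path, seed) -> dict:
    d, sizes = _load_sim(outdir)
    p = config["compartments"]
    pc1 = _load_track(d / "pc1.bedgraph", sizes, _pc1_bin(outdir), missing="nan")
    calls = comp_mod.classify_bins(pc1)
    boundaries = comp_mod.detect_boundaries(pc1, min_run=p["min_run"])
    out = outdir / "compartments"
    out.mkdir(parents=True, exist_ok=True)
    gio.write_bed(comp_mod.boundaries_to_bed(boundaries), out / "boundaries.bed")
    sign_track = pc1.copy_with(
        {c: np.where(np.isnan(pc1.values[c]), np.nan,
                     np.sign(pc1.values[c])) for c in sizes})
    gio.write_track(sign_track, out / "compartment_calls.bedgraph")

    track_bin = _track_bin_from_manifest(outdir)
    pseudocount = config["tracks"]["pseudocount"]
    summaries = {}
    for label in ("kd_vs_ctrl_d0", "kd_vs_ctrl_d2", "kd_vs_ctrl_d8"):
        cmp_track = _load_comparison(outdir, label, sizes, track_bin, pseudocount)
        offsets, mean, mat = comp_mod.boundary_aggregation(
            cmp_track, boundaries, flank=p["flank"], bin=p["bin"],
            mirror=p["mirror"])
        with open(out / f"profile_{label}.tsv", "w") as fh:
            fh.write("offset_bp\tmean\tn\n")
            n_per = np.isfinite(mat).sum(axis=0)
            for o, m, n in zip(offsets, mean, n_per):
                fh.write(f"{o}\t{m:.6g}\t{n}\n")
        half = len(mean) // 2
        summaries[label] = {
            "b_side_mean": round(float(np.nanmean(mean[:half])), 6),
            "a_side_mean": round(float(np.nanmean(mean[half:])), 6),
        }
    offsets, mean, _ = comp_mod.boundary_aggregation(
        pc1, boundaries, flank=p["flank"], bin=p["bin"], mirror=p["mirror"])
    with open(out / "profile_pc1.tsv", "w") as fh:
        fh.write("offset_bp\tmean\n")
        for o, m in zip(offsets, mean):
            fh.write(f"{o}\t{m:.6g}\n")
    summary = {"params": p, "n_boundaries": len(boundaries),
               "label_counts": calls.counts(), "profiles": summaries}
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)
    return summary


def _read_transcripts_tsv(d: Path) -> List[gio.TranscriptModel]:
    return gio.read_transcripts(d / "transcripts.tsv")


def _stage_tss(config, outdir: Path, seed) -> dict:
    d, sizes = _load_sim(outdir)
    p = config["tss"]
    track_bin = _track_bin_from_manifest(outdir)
    pseudocount = config["tracks"]["pseudocount"]
    txs = gio.longest_transcript_per_gene(_read_transcripts_tsv(d))
    comps = {lbl: _load_comparison(outdir, lbl, sizes, track_bin, pseudocount)
             for lbl in ("kd_vs_ctrl_d2", "wt_vs_lacz", "mut_vs_wt")}
    responses = reg.tss_window_scores(comps["kd_vs_ctrl_d2"], txs,
                                      halfwidth=p["halfwidth"])
    reg.fill_tss_scores(responses, comps["wt_vs_lacz"], txs,
                        halfwidth=p["halfwidth"], which="wt_vs_lacz")
    reg.fill_tss_scores(responses, comps["mut_vs_wt"], txs,
                        halfwidth=p["halfwidth"], which="mut_vs_wt")
    ranked = reg.rank_and_select(responses)
    out = outdir / "tss"
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "tss_scores.tsv", "w") as fh:
        fh.write("rank\tgene_id\ttranscript_id\tchrom\ttss\t"
                 "kd_vs_ctrl\twt_vs_lacz\tmut_vs_wt\n")
        for r in ranked:
            fh.write(f"{r.rank}\t{r.gene_id}\t{r.transcript_id}\t{r.chrom}\t"
                     f"{r.tss}\t{r.kd_vs_ctrl:.6g}\t{r.wt_vs_lacz:.6g}\t"
                     f"{r.mut_vs_wt:.6g}\n")
    summary = {"params": p, "n_tss": len(responses),
               "n_positive": reg.n_positive(responses),
               "top_n": [r.gene_id for r in ranked[:p["top_n"]]][:10]}
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)
    return summary


def _stage_cluster_tss(config, outdir: Path, seed) -> dict:
    p = config["cluster_tss"]
    tss_dir = _require(outdir, "tss")
    df = pd.read_csv(tss_dir / "tss_scores.tsv", sep="\t")
    X = df[["kd_vs_ctrl", "wt_vs_lacz", "mut_vs_wt"]].to_numpy()
    result = reg.kmeans_cluster(X, k=p["k"], seed=p["seed"],
                                n_init=p["n_init"],
                                standardize=p["standardize"])
    lo, hi = p["k_range"]
    elbow_k, wcss, strength = reg.elbow_select_k(
        X, range(int(lo), int(hi) + 1), seed=p["seed"], n_init=p["n_init"])
    out = outdir / "cluster-tss"
    out.mkdir(parents=True, exist_ok=True)
    kept = df.iloc[result.row_index]
    with open(out / "labels.tsv", "w") as fh:
        fh.write("gene_id\ttranscript_id\tcluster\n")
        for (_, row), lab in zip(kept.iterrows(), result.labels):
            fh.write(f"{row.gene_id}\t{row.transcript_id}\tA{lab + 1}\n")
    with open(out / "wcss.tsv", "w") as fh:
        fh.write("k\twcss\n")
        for k in sorted(wcss):
            fh.write(f"{k}\t{wcss[k]:.6g}\n")
    sizes_by_cluster = {f"A{c + 1}": int((result.labels == c).sum())
                        for c in range(p["k"])}
    summary = {"params": p, "cluster_sizes": sizes_by_cluster,
               "elbow_k": elbow_k, "elbow_strength": round(strength, 6),
               "dropped_rows": len(result.dropped_rows)}
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)
    return summary


CONTRAST_DEFS = {
    "kd_vs_ctrl": ("sh-Jmjd1a", "sh-Empty"),
    "wt_vs_lacz": ("KD+WT", "KD+LacZ"),
    "mut_vs_wt": ("KD+H1122A", "KD+WT"),
}


def _load_counts(outdir: Path) -> tgt.CountMatrix:
    d = _require(outdir, "simulate")
    counts = pd.read_csv(d / "counts.tsv", sep="\t", index_col=0)
    cond = pd.read_csv(d / "conditions.tsv", sep="\t")
    return tgt.CountMatrix(counts, dict(zip(cond["sample"], cond["condition"])))


def _stage_deg(config, outdir: Path, seed) -> dict:
    p = config["deg"]
    cm = _load_counts(outdir)
    out = outdir / "deg"
    out.mkdir(parents=True, exist_ok=True)
    n_sig = {}
    for label, contrast in CONTRAST_DEFS.items():
        records = tgt.nb_differential_test(cm, contrast)
        tgt.annotate_fdr(records, fdr_threshold=p["fdr"])
        with open(out / f"deg_{label}.tsv", "w") as fh:
            fh.write("gene_id\tlog2fc\tpvalue\tfdr\tdirection\n")
            for r in records:
                fh.write(f"{r.gene_id}\t{r.log2fc:.6g}\t{r.pvalue:.6g}\t"
                         f"{r.fdr:.6g}\t{r.direction}\n")
        n_sig[label] = sum(r.direction != "ns" for r in records)
    summary = {"params": p, "n_significant": n_sig}
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)
    return summary


def _stage_targets(config, outdir: Path, seed) -> dict:
    deg_dir = _require(outdir, "deg")
    cluster_dir = _require(outdir, "cluster-tss")
    fdr = config["deg"]["fdr"]

    sets = {}
    for label, sign in (("kd_vs_ctrl", "down"), ("wt_vs_lacz", "up"),
                        ("mut_vs_wt", "down")):
        df = pd.read_csv(deg_dir / f"deg_{label}.tsv", sep="\t")
        sets[label] = set(df.gene_id[(df.fdr < fdr) & (df.direction == sign)])
    ts = tgt.intersect_targets(sets["kd_vs_ctrl"], sets["wt_vs_lacz"],
                               sets["mut_vs_wt"])
    labels = pd.read_csv(cluster_dir / "labels.tsv", sep="\t")
    cluster_a1 = set(labels.gene_id[labels.cluster == "A1"])
    ts = tgt.demethylation_targets(ts, cluster_a1)

    out = outdir / "targets"
    out.mkdir(parents=True, exist_ok=True)
    ts.flags.astype(int).to_csv(out / "targets.tsv", sep="\t")
    venn = tgt.venn_cardinalities(sets["kd_vs_ctrl"], sets["wt_vs_lacz"],
                                  sets["mut_vs_wt"])
    summary = {
        "params": {"fdr": fdr},
        "venn": venn,
        "n_iron_dependent": len(ts.iron_dependent),
        "n_cluster_A1_genes": len(cluster_a1),
        "n_demethylation_targets": len(ts.demethylation),
    }
    with open(out / "venn.json", "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)
    return summary


LAD_CLUSTER_CONDITIONS = [("sh-Empty", 0), ("sh-Empty", 2), ("sh-Empty", 8),
                          ("sh-Jmjd1a", 0), ("sh-Jmjd1a", 2), ("sh-Jmjd1a", 8)]


def _stage_lads(config, outdir: Path, seed) -> dict:
    d, sizes = _load_sim(outdir)
    p = config["lads"]
    track_bin = _track_bin_from_manifest(outdir)
    lad_list = gio.read_bed(d / "lads.bed", sizes)
    tracks_dir = _require(outdir, "tracks") / "averaged"
    mats = {}
    for cond, day in LAD_CLUSTER_CONDITIONS:
        key = _cond_key(cond, day)
        track = _load_track(tracks_dir / f"{key}.bedgraph", sizes, track_bin)
        mats[key] = lads_mod.lad_signal_matrix(track, lad_list,
                                               flank=p["flank"], bin=p["bin"])
    result, X = lads_mod.cluster_lads(mats, k=p["k"], seed=p["seed"],
                                      n_init=p["n_init"])
    outliers, keep, relabeled = lads_mod.flag_outlier_clusters(
        result, X, fold=p["outlier_fold"], max_frac=p["outlier_max_frac"])
    lamin0 = _load_track(d / "laminB1_day0.bedgraph", sizes,
                         _lamin_bin(), missing="nan")
    lamin9 = _load_track(d / "laminB1_day9.bedgraph", sizes,
                         _lamin_bin(), missing="nan")
    c0, c9 = lads_mod.lamin_center_values(lamin0, lamin9, lad_list)

    name_of = {0: "B1-like", 1: "B2-like"}
    records = []
    for i, lad in enumerate(lad_list):
        lab = relabeled[i]
        cluster = name_of.get(lab, "outlier")
        records.append(lads_mod.LADRecord(lad, cluster, c0[i], c9[i]))

    out = outdir / "lads"
    out.mkdir(parents=True, exist_ok=True)
    gio.write_bed(
        [gio.GenomicInterval(r.interval.chrom, r.interval.start,
                             r.interval.end, name=r.cluster_label)
         for r in records], out / "lad_clusters.bed")
    tests = {}
    for tp in ("day0", "day9"):
        res, boxes = lads_mod.compare_lad_clusters(
            [r for r in records if r.cluster_label != "outlier"], tp)
        tests[tp] = {
            "U": res.U, "p_value": res.p_value, "n1": res.n1, "n2": res.n2,
            "method": res.method,
            "significance": lads_mod.significance_stars(res.p_value),
            "box": {k: {"median": v.median, "q1": v.q1, "q3": v.q3,
                        "whisker_low": v.whisker_low,
                        "whisker_high": v.whisker_high, "n": v.n}
                    for k, v in boxes.items()},
        }
    sizes_by = {name_of.get(c, "outlier"): int((relabeled == c).sum())
                for c in (0, 1)}
    sizes_by["outlier"] = int((relabeled == -1).sum())
    summary = {"params": p, "cluster_sizes": sizes_by,
               "outlier_cluster_ids": outliers, "tests": tests}
    with open(out / "lad_tests.json", "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)
    return summary


def _lamin_bin() -> int:
    return int(simdata.SimConfig.__dataclass_fields__["lamin_bin"].default)


def report(outdir: Path) -> dict:
    """Consolidated run report: TSS ranking summary, Venn cardinalities,
    cluster sizes, LAD test p-values with significance stars."""
    outdir = Path(outdir)
    if not outdir.is_dir():
        raise DependencyError(f"run directory {outdir} does not exist")
    sections = {}
    gaps = []
    for stage, fname in (("tss", "summary.json"),
                         ("cluster-tss", "summary.json"),
                         ("compartments", "summary.json"),
                         ("targets", "venn.json"),
                         ("lads", "lad_tests.json")):
        path = outdir / stage / fname
        if path.exists():
            with open(path) as fh:
                sections[stage] = json.load(fh)
        else:
            gaps.append(stage)
    if not sections:
        raise DependencyError(f"no stage outputs found under {outdir}")
    out = {"sections": sections, "missing_stages": gaps}
    rep_dir = outdir / "report"
    rep_dir.mkdir(exist_ok=True)
    with open(rep_dir / "report.json", "w") as fh:
        json.dump(out, fh, indent=1, sort_keys=True)
    return out


_IMPLS = {
    "simulate": _stage_simulate,
    "tracks": _stage_tracks,
    "compartments": _stage_compartments,
    "tss": _stage_tss,
    "cluster-tss": _stage_cluster_tss,
    "deg": _stage_deg,
    "targets": _stage_targets,
    "lads": _stage_lads,
}


def run_stage(name: str, config: Dict[str, dict], outdir,
              seed: Optional[int] = None) -> dict:
    """Run one pipeline stage into ``outdir`` and append to the manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if name == "report":
        summary = report(outdir)
        entry_summary = {"missing_stages": summary["missing_stages"]}
    elif name in _IMPLS:
        for dep in _STAGE_DEPS[name]:
            _require(outdir, dep)
        entry_summary = _IMPLS[name](config, outdir, seed)
    else:
        raise ConfigError(f"unknown stage {name!r}; valid: {', '.join(STAGES)}")
    stage_dir = outdir / name
    inventory = sorted(
        str(f.relative_to(outdir)) for f in stage_dir.rglob("*") if f.is_file()
    )
    checksums = {rel: _sha256(outdir / rel) for rel in inventory}
    entry = {
        "stage": name,
        "seed": seed,
        "config": config.get(name.replace("-", "_"), config.get(name, {})),
        "summary": entry_summary,
        "outputs": checksums,
    }
    _append_manifest(outdir, entry)
    return entry
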