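# demark

Multi-scale integration of repressive histone-mark coverage (H3K9me2
CUT&Tag-style tracks), Hi-C A/B compartments, RNA-seq differential
expression and lamin B1 DamID profiles — built to identify genes whose
transcription is driven by **iron-dependent histone demethylation** and to
characterise lamina-associated-domain (LAD) dynamics during adipocyte
differentiation.

The package is aimed at computational epigenomicists who want the
downstream analysis chain as reusable, tested code: it consumes standard
text formats (bedGraph tracks, BED intervals, GTF/TSV transcript models,
count tables) and never requires raw sequencing data. A seeded synthetic
epigenome generator plants every structure the pipeline infers, so the
whole chain is validated end-to-end against known ground truth.

## The analyses

Writing `log2FC = log2((a + c)/(b + c))` for pseudocounted fold changes of
CPM-normalized binned coverage, the pipeline implements:

1. **Compartment scale** — A/B calls from the sign of the Hi-C PC1
   eigenvector track; boundaries at PC1 sign changes; boundary-anchored
   mean profiles (±1 Mb, 50-kb bins) showing that knockdown of the
   demethylase JMJD1A raises H3K9me2 preferentially in the A compartment
   (PC1 > 0).
2. **TSS scale** — mean log2FC in ±1.5-kb windows around each TSS for
   three comparisons (knockdown vs. control; wild-type rescue vs. LacZ;
   iron-coordination mutant H1122A vs. wild-type), ranked and k-means
   clustered (k = 3, elbow-checked) into demethylated / unchanged /
   opposite response patterns.
3. **Expression scale** — a negative-binomial Wald test with pooled
   method-of-moments dispersion per contrast, Benjamini–Hochberg FDR
   < 0.05, and the three-way set logic: genes **down on knockdown**,
   **restored by wild-type rescue**, and **not restored by the
   iron-coordination mutant** are the iron-dependent targets; intersecting
   with the demethylated TSS cluster gives the demethylation-driven
   targets.
4. **LAD scale** — LAD-centered signal matrices (±0.5 Mb, 10-kb bins),
   k-means grouping into high/low H3K9me2 clusters, removal of extreme
   outlier clusters (> 20-fold mean signal and tiny membership), and a
   Mann–Whitney U comparison of lamin B1 log-ratios at LAD centers between
   clusters at day 0 and day 9 of differentiation.

## Worked example

Run the full chain on the synthetic epigenome (two 40-Mb chromosomes,
2,000 genes, 200 LADs; ~30 s on one CPU):

```sh
demark simulate --outdir run --seed 1
for stage in tracks compartments tss cluster-tss deg targets lads report; do
    demark $stage --outdir run
done
```

`run/report/report.json` then contains (seed 1):

* `compartments`: 16 boundaries; the knockdown-vs-control H3K9me2 profile
  averages **+0.122** on the A side of boundaries vs. **−0.007** on the
  B side — demethylation is A-compartment-restricted.
* `tss`: 2,000 TSS windows scored, 964 with positive knockdown log2FC;
  k-means clusters A1/A2/A3 of sizes **305 / 1,393 / 302** (planted:
  300 / 1,400 / 300), elbow method confirming k = 3.
* `targets`: Venn triple intersection of **93** iron-dependent target
  genes (93 of the 100 planted recovered, no false positives in this
  run), **55** of which fall in the demethylated TSS cluster.
* `lads`: clusters of **88 / 107 / 5** LADs; the 5 extreme-signal LADs
  are removed by the 20-fold rule; lamin B1 at LAD centers differs
  between the surviving clusters at day 0 (Mann–Whitney p ≈ 9e-16, `***`)
  but not at day 9 (p ≈ 0.12, `NS`), while declining in both clusters —
  lamina detachment during differentiation is independent of H3K9me2
  status.

Every stage writes its tunable constants into `run/manifest.json`;
re-running with the same config and seed reproduces byte-identical
outputs.

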