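# Methods

## Scope and data model

All analyses operate on fixed-bin signal tracks (`BinnedTrack`: one float
vector per chromosome, bin size in bp, last bin possibly partial) and
interval/transcript lists. Coordinates are 0-based half-open throughout;
GTF input is converted on read. Two missing-data policies exist: count
tracks treat uncovered bins as zero (zero coverage is information), while
PC1 and DamID log-ratio tracks treat them as NaN (absent is absent). All
window means are length-weighted and NaN-ignoring, computed via cached
per-chromosome prefix integrals so region×bin matrices cost O(1) per
cell.

## Track normalization and comparison

Coverage is normalized to counts per million (value × 1e6 / track total)
per replicate, replicates are averaged bin-wise, and conditions are
compared as `log2((a + c)/(b + c))`. The pseudocount `c` defaults to 1.0
on the CPM scale — the single most result-sensitive constant in the
chain, which is why every comparison object and the run manifest record
it. It damps fold changes at low coverage: with typical bin CPM near 1,
a true 0.4 log2-unit shift reads out near 0.13. Correlation matrices are
Pearson on mean-pooled 100-kb bins, pairwise-complete over NaN; replicate
PCA runs on 10-kb bins (SVD of the bin-centered sample matrix), with the
sign convention that the largest-magnitude loading is positive.

## Compartments

A bin is A when PC1 > 0, B when PC1 < 0, undefined when NaN. For
boundary detection, zero/NaN bins inherit the previous non-missing sign
(leading gaps take the first non-missing sign); this resolves the
zero case without creating spurious double flips. A boundary sits on the
edge between opposite-sign runs; `min_run` (default 1, the literal
sign-change rule) optionally requires both flanking runs to span that
many bins, for flickery real PC1 tracks. Boundary profiles orient every
window B→A left-to-right, mirroring A→B boundaries (a no-mirror flag
exists); windows truncated by chromosome ends are NaN-padded.

## TSS and gene-body matrices

Reference-point matrices use fixed windows around the TSS (default
±1.5 kb at 500-bp bins); scale-regions matrices rescale the gene body to
5 kb (10 bins) between unscaled 500-bp flanks, using length-weighted
means over equal fractions of the real body. Minus-strand rows are
reported 5′→3′. The TSS score is the plain mean log2FC over the window —
a scalar is needed for ranking and set logic, and the mean is the natural
reduction; ranking sorts descending with (chrom, tss, transcript_id) tie
breaks. Per gene, the longest transcript is kept (ties: lexicographically
smallest transcript id).

## Clustering

k-means uses k-means++ with `n_init = 10` restarts and a fixed seed
(default 17); clusters are relabeled by descending centroid mean of the
first feature, so cluster 0 ("A1-like") is always the strongest
knockdown-induced H3K9me2 gain. TSS features are the three comparison
scores, z-scored per feature by default (raw mode retained); rows with
NaN are dropped and counted. k is fixed at 3 for the TSS patterns, with
the elbow method as a check: the chosen k maximizes the discrete second
difference of the WCSS curve, and an "elbow strength" (that second
difference over WCSS at the smallest k) flags structureless data. LAD
clustering uses one feature per condition/timepoint — the row mean over
the ±0.5 Mb window — because the groups are defined by signal level and
low-dimensional features keep the elbow interpretable; full-matrix mode
is available behind a flag. With truly extreme outlier rows the WCSS
drop from k=1→2 dwarfs everything else and the second-difference rule
picks k=2, so the pipeline fixes k=3 for LADs and treats the elbow as
diagnostic output.

## Differential expression and target logic

The differential test is deliberately simple — the scientific content is
the three-contrast set logic, not the test. Counts are scaled to the mean
library size; a single common dispersion φ is estimated by pooled method
of moments (φ = Σ(s² − m)/Σm² over genes and both groups, floored at 0);
the Wald statistic is the pseudocounted log2 ratio of group means over
its delta-method standard error, referred to a standard normal
(two-sided). On equal-means NB simulations (φ = 0.1, 2,000 genes, 3 vs 3)
the empirical type-I rate at α = 0.05 sits at ≈ 0.05 (asserted within
[0.03, 0.07] in the suite). FDR control is Benjamini–Hochberg at 0.05.
Direction requires both FDR < 0.05 and a non-zero fold change. Gene ids
are matched as exact strings across the RNA and chromatin layers;
mismatches are dropped and counted.

## LAD analysis

LAD matrices anchor at interval midpoints (`start + floor(length/2)`,
strand ignored). The outlier rule removes a cluster only when its mean
feature signal exceeds `fold` (default 20) times the mean of the other
clusters' means **and** its membership is at most `max_frac` of the LADs
— both conditions, so a genuinely large high-signal cluster is never
deleted. The operation default for `max_frac` is 0.01 (a handful out of
thousands); the pipeline passes 0.05 because the synthetic genome
carries 5 outliers among 200 LADs (2.5%) rather than among ~2,000.
Survivors are relabeled by descending mean signal (B1-like = higher).
Lamin B1 center values are read from the bin containing the midpoint;
NaN centers are excluded with counts reported. The Mann–Whitney U test
uses exact enumeration when both n ≤ 8 and the data are tie-free,
otherwise the normal approximation with tie and continuity corrections;
box summaries report min/max whiskers plus 1.5×IQR outliers separately.
Significance stars follow the two-level convention: `*` p < 0.05,
`***` p < 0.005.

## Synthetic epigenome

The generator plants every inferred structure and emits standard formats
plus a truth JSON; all randomness derives from one seed through
`SeedSequence`, so outputs are byte-identical per seed. Default scale is
two 40-Mb chromosomes — large enough for ~16 compartment segments, 2,000
genes and 200 LADs, small enough that the full chain runs in ~30 s.

* **Compartments.** Alternating A/B segments; A lengths 2–4 Mb and B
  lengths 6–8 Mb (overall 2–8 Mb span). B segments are drawn longer so
  the B compartment always hosts the LAD demand with a full ±0.5 Mb
  analysis margin; a side effect is a ~60/40 B/A genome. PC1 is
  ±amplitude (1.0) plus Gaussian noise (sd 0.2) per 100-kb bin, segment
  edges on the PC1 grid, so noiseless recovery is exact.
* **Chromatin tracks.** Per-1-kb-bin Poisson counts around lognormal
  means (sd 0.3 in log space, fixed per bin across conditions —
  biological signal, cancelling in fold changes). Baseline 30 (A) vs 60
  (B) expected counts per bin: the repressive mark is B-enriched. In
  demethylating conditions (control, wild-type rescue, vehicle) means
  are divided by 2^effect; the effect is δ = 0.5 log2 units over
  responsive gene regions (sign flipped for the 'opposite' class),
  0.4 diffusely across other A bins, and exactly 0 over unchanged-gene
  TSS windows — the TSS window *is* the class definition, so an
  unchanged TSS is pinned at zero rather than at the diffuse level.
  Two replicates per condition.
* **Genes.** 2,000 genes on non-overlapping slots (5–10 kb bodies,
  ≥14 kb spacing, so ±1.5 kb windows never collide). Responsive classes
  (15% demethylated, 15% opposite) are placed only in A, matching the
  compartment restriction of the effect; unchanged genes prefer A (60%)
  but spill to B when slots run out.
* **Expression.** NB counts (φ = 0.1, means loguniform 50–500, 3
  replicates, ±20% depth variation) for the five-condition rescue
  design. 100 iron-dependent genes carry 4-fold effects in all three
  contrasts; 60 of them come from the demethylated TSS class (the
  planted demethylation-driven set). Ninety decoys violate exactly one
  contrast each to stress the Venn logic.
* **LADs and lamin B1.** 200 LADs of 110–130 kb inside B segments with
  ±0.5 Mb margins. The B1/B2 distinction is regional: whole B segments
  are 'high' (×1.8 baseline) or 'low', and LADs inherit the group; a
  group-independent ×1.5 in-LAD enrichment sits on top. This matches
  the "relatively high vs. low H3K9me2" character of the two groups and
  — critically — keeps the groups recoverable despite neighbouring LADs
  sharing analysis windows at this genome scale (per-LAD offsets would
  contaminate neighbours' windows beyond recognition). The five outlier
  LADs sit in saturated constant-level blocks (50× B baseline over
  midpoint ±480 kb, clear of all other LADs' windows), making them one
  tight cluster ~25-fold above the others. Lamin B1 log-ratios at 10-kb
  bins: background −0.5; day 0 in-LAD 1.0 (B1-like) vs 0.7 (B2-like);
  day 9 both 0.2; noise sd 0.2 — a planted day-0 shift, no day-9 shift,
  and a decline in every group.

What the generator does **not** emulate: read-level noise and mapping
artefacts, fragment-size structure of tagmentation data, distance decay
or TAD structure in Hi-C (PC1 is simulated directly), realistic genome
composition, compartment switching over time, or correlated
gene-gene expression. Passing tests therefore demonstrate that the
implementation computes each statistic correctly and recovers planted
structure under NB/Poisson noise — not that the statistical choices are
optimal for real sequencing data.

## Numerical and degenerate-input choices

Pseudocounts guard all log ratios (tracks: 1.0 CPM; expression: 0.5
normalized counts). Ties in ranking, longest-transcript selection and
nearest-gene annotation break lexicographically; k-means determinism
comes from the fixed seed; WCSS curves are computed at the same seed per
k. Degenerate inputs raise typed errors: empty anchor/LAD/sample lists,
all-zero CPM totals, mismatched bin grids, identical LAD feature rows
(clustering undefined), all clusters flagged as outliers. p-values are
clipped into (0, 1]. The CLI maps these to exit codes (2 config,
3 missing dependency, 1 runtime).

## Known limitations

The NB Wald test with common dispersion is a stand-in with correct
calibration on the simulated design; it does not reproduce
edgeR's TMM normalization, tagwise shrinkage or exact tests, and
concordance with edgeR on real data is out of scope. The elbow rule is a
heuristic; on structureless data it still returns an argmax, flagged
only by low elbow strength. Boundary detection at `min_run = 1` is the
literal sign-change rule and will over-call boundaries on noisy real PC1
tracks. bigWig input is not required anywhere; bedGraph is the canonical
exchange format (a bigWig reader can be slotted behind the same
contract).
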