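# Methods

This note documents the statistical models, defaults and design choices in
`nichestate`, and what the synthetic cohort does and does not establish
about behavior on real data.

## Coordinate and data model

All coordinates are 0-based half-open (BED convention); chromosome names
match by exact string equality with no "chr" aliasing. A gene is anchored
by a single strand-aware TSS base pair. Distances from a point to an
interval are 0 inside the interval, otherwise `start − pos` upstream and
`pos − end` downstream. Nearest-feature ties (exactly equidistant up- and
downstream) resolve to the feature with the smaller start coordinate — an
arbitrary but deterministic rule, applied uniformly to promoter and ATAC
assignment. Signal beyond chromosome ends is zero-padded rather than
truncated so per-gene signal matrices stay rectangular.

## Spike-in normalization

Size factors are median-of-ratios restricted to spike-in rows: for sample
*j*, the median over spike-in rows *g* of `c_gj / geomean_g(c_g·)`,
computed over rows with nonzero counts in every sample, then rescaled to
geometric mean 1. At least 5 usable spike-in rows are required; an
all-zero spike-in column is a hard error naming the sample. Because
spike-ins share one true abundance per row, dividing counts by the factors
equalizes spike-in abundance, and any per-sample depth or preparation
distortion common to genes and spike-ins cancels from fold changes.

## Negative-binomial Wald test

For counts `c_gj` with size factors `s_j`, normalized values
`y_gj = c_gj / s_j` and group means `q̂_A, q̂_B`:

* **Fold change** `log2FC = log2(q̂_B + 0.5) − log2(q̂_A + 0.5)`. The 0.5
  pseudocount stabilizes zero-count features.
* **Dispersion** per feature by method of moments on the within-group
  scatter, `α̂ = (s² − q·E[1/s_j]) / q²`, pooled with df weights across
  **every replicate group in the design** (all tissue × genotype groups
  with ≥ 2 samples), not only the two tested groups. Using all groups is
  what full-design fitting does in standard DE tools and roughly doubles
  the residual degrees of freedom here, which matters at n = 3.
* **Shrinkage** 50/50 toward a mean–dispersion trend: features are binned
  into ≤ 20 equal-count bins by mean expression and the bin medians,
  pooled to be non-increasing in mean (PAVA), form the trend. The raw
  moment estimator is strongly right-skewed at few replicates, so its
  median underestimates the dispersion; the bin medians are therefore
  multiplied by the global mean/median ratio of the positive raw
  estimates, keeping the median's outlier robustness while centering the
  trend on the unbiased moment scale. The final dispersion is floored at
  1e−8. Without the full-design pooling and the skew alignment, the test's
  raw type-I rate at α = 0.05 runs visibly above nominal at n = 3; with
  them it sits just below nominal (the acceptance metrics recompute this).
* **Wald statistic** `log2FC / se` with the delta-method standard error
  from `Var(q̂) = n⁻² Σ_j (q̂/s_j + α q̂²)`, two-sided normal p, and BH
  adjustment over tested (non-spike-in) features.

Calls use padj < 0.05 and |log2FC| > 1 for both DEGs and DARs. This test
is a deliberately transparent substitute for DESeq2-style machinery: no
Cook's-distance outlier handling, no apeglm shrinkage, no RUV factor
analysis beyond the spike-in scaling. Its acceptance surface is recovery
of planted truth, not replication of DESeq2 output on real data.

## Interaction contrast

The knockout's effect on the organ difference is estimated as
`(Int.WT − St.WT) − (Int.KO − St.KO)`: the difference of the two
within-genotype tissue contrasts, with standard errors combined in
quadrature. For a balanced design this equals the factorial-GLM
interaction coefficient; the design here is balanced by construction.
Calls use padj < 0.2 and |estimate| > 1 — deliberately permissive, since
the interaction is a difference of differences with double the variance.

## TPM

`TPM_g = 1e6 · (c_g / s_j / len_g) / Σ_g' (c_g' / s_j / len_g')` with
spike-ins excluded from the table and the denominator; columns sum to 1e6
exactly, and a replicate-averaged table per tissue × genotype condition is
also produced. Ligand repertoire comparisons use Spearman's rho (average
ranks for ties) on `log(TPM + 1)` of the secreted-ligand subset.

## Consensus peaks, DARs and cCRE classes

The consensus peakset is the gap-0 union-merge of all input peak sets;
region ids are `chrom:start-end` and provenance records contributing sets.
ATAC counts over consensus regions are normalized by all-feature
median-of-ratios (no spike-ins in ATAC) and tested with the same NB Wald
machinery. Regions are classed by the distance of their midpoint to the
nearest TSS using the conventional band edges — ≤ 200 bp promoter-like,
≤ 2 kb proximal-enhancer, else distal-enhancer — a download-free stand-in
for a cCRE registry lookup; an external annotation can replace it by
joining on region ids.

## Promoter state

Promoters are approximated as the midpoint of the nearest merged H3K4me3
peak within 50 kb of the TSS; genes with no such peak are excluded from
promoter-level analyses and reported. Signal matrices cover promoter
± 4 kb in 50 bp bins (160 bins). Clustering is k-means with k = 3 and 10
restarts on per-bin standardized rows; the arbitrary k-means indices are
relabelled deterministically from the raw matrix — C1 is the cluster with
the greatest breadth (mean fraction of bins above half the matrix-global
90th-percentile signal), C2 the remaining cluster with the larger
central-bin mean, C3 the rest — so the labels carry the broad / focal-high
/ low semantics regardless of seed. Both the breadth quantile and the
window are configurable.

State calls use a ± 1 kb window around the approximated promoter. One
window width is used for both state classification and DEG–DAR proximity
for coherence. With a state annotation the label with the largest bp
overlap wins (ties: Bivalent > Active > Repressed > Other); otherwise
co-occupancy rules apply (K4∧K27me3 Bivalent; K4∧K27ac Active; K27me3
alone Repressed; else Other). Switch tables cross-tabulate per-tissue
states over a gene set, with an explicit unassigned margin, and report
both counts and fractions so headline ratios remain auditable.

## Exact tests

Fisher's two-sided p uses the probability-mass rule (sum over tables with
the observed margins whose probability does not exceed the observed
table's). For table totals ≤ 2000, both Fisher and the upper-tail
hypergeometric are evaluated in exact integer arithmetic (binomial
coefficients, integer tie comparison, one final division), which removes
floating-point tie ambiguity entirely; larger tables use log-space
evaluation with a 1e−7 relative tie slack. The odds ratio reported is the
conditional MLE. Hypergeometric fold enrichment is observed/expected
`k / (K·n/N)`; the universe N is the analysis's gene universe (genes with
an assigned promoter and ATAC peak in the pipeline) and is always
reported alongside.

## The synthetic cohort

The generator emulates the statistical structure the analysis assumes, on
a synthetic genome (default 2 × 101 Mb, genes every 100 kb so nearest-peak
logic is unambiguous; spacing is configurable to create deliberate 50 kb
assignment failures). Defaults define the study conditions:

* 2,000 genes, 3 replicates per tissue × genotype (12 samples), NB counts
  with log-normal baseline means (ln μ ~ N(ln 100, 1)) and dispersion
  0.05; 10% tissue DEGs at |log2FC| = 2 (half per direction, exact
  counts).
* 50 spike-in rows with constant true abundance (ln ~ N(ln 2000, 0.5))
  and near-Poisson dispersion 0.002 — spike-ins carry technical noise
  only, which is what makes them usable as normalization anchors; gene and
  spike-in rows alike are scaled by per-sample depth distortions drawn
  uniformly from [0.5, 2].
* Promoter chromatin per (gene, tissue): 30% of promoter-assignable genes
  switch Bivalent (Int) → Active (St), 20% are stable bivalent, 5% each
  repressed/other (no H3K4me3, hence unassignable), the rest stable
  active. H3K27me3 realizes a broad ≥ 5 kb domain or a ≤ 1 kb focal peak
  (50/50 where marked) or background — the C1/C2/C3 archetypes.
* PRC2 sensitivity (knockout derepression of +2 log₂ units in the
  affected organ) is planted at rate 0.8 under K27me3-marked promoters and
  0.2 elsewhere — a 4-fold enrichment in K27me3-high clusters, and a
  majority-derepressed C1/C2 stratum so cluster medians land at +2.
* Promoter ATAC peaks of DEGs become sign-matched DARs with probability
  0.8; non-DEG promoter peaks never do; distal peaks at 0.5% — a planted
  ~10-fold DEG/DAR-proximity coupling and a DEG-stratum
  accessibility–expression correlation.

All randomness flows from one root seed through named substreams (genome,
truth, tracks, atac, counts), so bundles are byte-identical across runs.

**What the synthetic cohort does not model:** read-level artifacts (GC or
Tn5 bias, duplicates, mappability), dispersion heterogeneity across genes,
correlated replicates or batch structure beyond a scalar depth factor,
peak-calling noise (peak coordinates are exact), partially-overlapping or
nested promoters, and continuous chromatin-state gradations (states are
planted categorically). Passing tests therefore establish correctness of
the algorithms and calibration under the assumed NB model — not robustness
to real-data pathologies; the DESeq2/RUV-seq route remains the reference
for production analyses of real cohorts.

## Numerical and degenerate-input conventions

BH-adjusted p-values are clipped to be ≥ raw p. Zero-variance correlation
strata are reported with r = NaN and flagged rather than dropped. A zero
Fisher margin yields p = 1 and a NaN odds ratio; an empty C3 cluster or a
zero C3 rate flags the enrichment fold as NaN/∞ rather than erroring.
Empty consensus unions are legal (warning-level), empty gene sets are not.
Pipeline TSVs are written with `%.6g` floats so identical configs produce
byte-identical files.

## Problem sizes

Default test and acceptance runs use the 2,000-gene cohort (8,000 ATAC
peaks, 12 samples per assay); the exact-test sweep covers all ~6.4e5
contingency tables with total ≤ 60. These sizes give every recovery
metric a comfortable margin of sampling error while keeping a full
verification run in the tens of seconds on one CPU.
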