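# nichestate

Integrative chromatin-state analysis for gastrointestinal mesenchymal
niches: from RNA/ATAC count matrices and histone-mark peak/signal tracks to
differentially expressed genes, differentially accessible regions, bivalent
promoters, PRC2-sensitive gene strata, chromatin-state switches between
organs, and secreted-ligand repertoire comparisons.

## The problem

During gut development, the stomach and intestinal mesenchyme show nearly
identical chromatin accessibility yet express distinct transcriptional
programs. A key mechanism is promoter **bivalency**: co-occupancy of
H3K4me3 (active/poised) and H3K27me3 (Polycomb repression) keeps
lineage-determining genes poised, and Polycomb Repressive Complex 2 (PRC2)
maintains this state without altering accessibility. Probing that model
requires stitching together several assays — spike-in normalized RNA-seq,
ATAC-seq over a consensus peakset, histone ChIP peaks and simplified
ChromHMM states — and a battery of statistics linking them.

`nichestate` implements that full analysis as a tested, reusable library,
plus a synthetic-cohort generator that plants every effect the analysis is
supposed to find (tissue DEGs, knockout derepression, bivalent promoters,
state switches, promoter-coupled DARs) so each stage can be verified
against known truth at desk scale.

## The methods at its core

* **Spike-in anchored normalization** — per-sample size factors by
  median-of-ratios over spike-in rows, rescaled to geometric mean 1.
* **NB Wald differential testing** — per-feature dispersion by method of
  moments on normalized counts (estimated across all replicate groups),
  shrunk 50/50 toward a monotone binned-median trend; log₂ fold change from
  group means with a 0.5 pseudocount; delta-method standard error; BH
  correction. DEGs/DARs at padj < 0.05 and |log₂FC| > 1; the four-group
  interaction contrast (Int.WT − St.WT) − (Int.KO − St.KO) at padj < 0.2.
* **Promoter approximation** — promoter = midpoint of the nearest merged
  H3K4me3 peak within 50 kb of the TSS; nearest consensus ATAC peak within
  50 kb attached; ±4 kb / 50 bp signal matrices.
* **C1/C2/C3 clustering** — k-means (k = 3) on per-bin standardized
  H3K27me3 profiles, deterministically relabelled: C1 broad domains, C2
  high focal peaks, C3 low signal.
* **State classification** — from a simplified ChromHMM annotation
  (largest-overlap rule) or from mark co-occupancy: K4∧K27me3 → Bivalent,
  K4∧K27ac → Active, K27me3 alone → Repressed.
* **Cross-talk statistics** — exact hypergeometric enrichment of DEGs among
  DAR-proximal promoters, Fisher tests of PRC2 sensitivity by cluster,
  Pearson correlation of expression vs promoter accessibility by stratum,
  TPM from spike-in normalized counts, and Spearman comparison of
  secreted-ligand repertoires.

## Worked example

```bash
python examples/02_differential_expression.py
```

```
Int vs St (WT): {'n_tested': 2000, 'n_called': 203, 'n_up': 102, 'n_down': 101}
sensitivity 1.000, empirical FDR 0.015 (planted |log2FC| = 2 at padj < 0.05, |log2FC| > 1)
interaction calls: 851, sensitivity 0.986
```

On the default simulated cohort (2,000 genes, 10% planted tissue DEGs at
|log₂FC| = 2, NB dispersion 0.05, 3 replicates per tissue × genotype), the
tissue contrast recovers 203 DEGs, essentially all planted ones, with an
empirical false-discovery rate of 1.5% — and the interaction contrast flags
the genes whose organ difference collapses upon knockout.

```bash
python examples/04_enrichment_statistics.py
```

```
DEGs with a promoter-proximal DAR: 9.5-fold enrichment (hypergeometric p = 3.44e-179) over 1800 genes
PRC2-sensitive genes in C1uC2 vs C3: 3.8-fold (Fisher p = 6.9e-143)
Pearson r (DEG-or-DAR-proximal): 0.870 over 189 promoters; ...
Pearson r (non-significant): -0.029 over 1611 promoters; median promoter accessibility change 1.14-fold
```

The planted 10-fold expression/accessibility coupling and the 4-fold
enrichment of knockout-sensitive genes in H3K27me3-high promoter clusters
are both recovered; promoters without significant changes move less than
1.15-fold in accessibility at the median — accessibility-independent
regulation, the signature the analysis is designed to expose.

Other entry points: `examples/01_simulate_cohort.py` (the generator and its
planted-truth table), `examples/03_promoter_states.py` (promoter
approximation, C1/C2/C3 clustering, Bivalent→Active switch tabulation), and
the `nichestate` CLI (`nichestate simulate|all --out DIR --seed N`).

## Layout

```
src/nichestate/
  intervals.py    genomic interval model, BED/narrowPeak/bedGraph/state-BED I/O,
                  merge / nearest / binned-signal queries
  simulate.py     synthetic cohort generator + planted-truth tables
  de.py           spike-in size factors, NB Wald test, interaction contrast, TPM
  atac.py         consensus peakset, DAR calling, cCRE distance classes
  promoters.py    promoter approximation, signal matrices, clustering, states
  enrichment.py   exact Fisher/hypergeometric, correlations, ligand repertoires
  pipeline.py     end-to-end orchestration with YAML config
  cli.py          thin click front end
```

See `docs/methods.md` for the statistical model, defaults, and limitations.
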