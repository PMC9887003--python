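"""Enrichment, association and correlation statistics.

Links expression, accessibility, promoter chromatin class and PRC2
sensitivity: hypergeometric fold enrichment of gene-set overlaps, Fisher
exact tests on 2x2 tables, expression-accessibility correlation by
stratum, fold-change distributions by promoter cluster, and secreted-ligand
repertoire comparison by Spearman correlation.

The Fisher two-sided p-value follows the probability-mass rule (sum of all
tables with the observed margins whose probability does not exceed that of
the observed table). For tables with total <= ``EXACT_LIMIT`` both Fisher
and hypergeometric tail probabilities are evaluated in exact integer
arithmetic (binomial coefficients and integer tie comparisons), so small
tables carry no floating-point tie ambiguity; larger tables fall back to
log-space evaluation.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb, inf

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

__all__ = [
    "ContingencySummary",
    "CorrelationSummary",
    "hypergeom_enrichment",
    "fisher_2x2",
    "deg_dar_association",
    "cluster_sensitivity_enrichment",
    "accessibility_expression_correlation",
    "lfc_by_cluster",
    "ligand_repertoire_compare",
]

EXACT_LIMIT = 2000  # table totals up to this size use exact integer arithmetic


class StatsError(ValueError):
    pass


@dataclass
class ContingencySummary:
    table: tuple[tuple[int, int], tuple[int, int]]
    odds_ratio: float  # inf flagged as math.inf, undefined as nan
    fold: float
    p: float
    test: str

    def as_dict(self) -> dict:
        return {
            "table": [list(self.table[0]), list(self.table[1])],
            "odds_ratio": self.odds_ratio,
            "fold": self.fold,
            "p": self.p,
            "test": self.test,
        }


@dataclass
class CorrelationSummary:
    stratum: str
    n: int
    r: float  # nan when undefined (zero variance)
    median_abs_fold: float  # 2^|median log2FC|, nan if not applicable

    def as_dict(self) -> dict:
        return {
            "stratum": self.stratum,
            "n": self.n,
            "r": self.r,
            "median_abs_fold": self.median_abs_fold,
        }


def _hypergeom_sf_exact(k: int, N: int, K: int, n: int) -> float:
    """P(X >= k) for hypergeometric(N, K, n) by exact integer summation."""
    if k <= max(0, K + n - N):
        return 1.0
    num = sum(comb(K, x) * comb(N - K, n - x) for x in range(k, min(K, n) + 1))
    return num / comb(N, n)


def hypergeom_enrichment(k: int, K: int, n: int, N: int) -> ContingencySummary:
    """Upper-tail hypergeometric enrichment of an overlap of size ``k``.

    ``K`` and ``n`` are the two set sizes within a universe of ``N``;
    ``fold`` is observed/expected overlap, ``p`` is P(X >= k).
    """
    if not (0 <= k <= min(K, n) and 0 <= K <= N and 0 <= n <= N):
        raise StatsError(f"inconsistent sizes k={k}, K={K}, n={n}, N={N}")
    expected = K * n / N if N > 0 else 0.0
    fold = k / expected if expected > 0 else (0.0 if k == 0 else inf)
    if N <= EXACT_LIMIT:
        p = _hypergeom_sf_exact(k, N, K, n)
    else:
        p = float(np.exp(stats.hypergeom.logsf(k - 1, N, K, n))) if k > 0 else 1.0
    table = ((k, K - k), (n - k, N - K - n + k))
    a, b = table[0]
    c, d = table[1]
    orat = (a * d) / (b * c) if b * c > 0 else (inf if a * d > 0 else float("nan"))
    return ContingencySummary(table, orat, fold, min(p, 1.0), "hypergeometric")


def _fisher_exact_int(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by exact integer enumeration over the support."""
    r1, r0, c1 = a + b, c + d, a + c
    N = r1 + r0
    lo, hi = max(0, c1 - r0), min(r1, c1)
    # unnormalized pmf weights are integers: comb(r1, x) * comb(r0, c1 - x)
    weights = [comb(r1, x) * comb(r0, c1 - x) for x in range(lo, hi + 1)]
    w_obs = weights[a - lo]
    num = sum(w for w in weights if w <= w_obs)
    return num / comb(N, c1)


def _fisher_log(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p in log space for large tables (1e-7 tie slack)."""
    r1, r0, c1 = a + b, c + d, a + c
    N = r1 + r0
    lo, hi = max(0, c1 - r0), min(r1, c1)
    x = np.arange(lo, hi + 1)
    logw = (
        gammaln(r1 + 1)
        - gammaln(x + 1)
        - gammaln(r1 - x + 1)
        + gammaln(r0 + 1)
        - gammaln(c1 - x + 1)
        - gammaln(r0 - c1 + x + 1)
    )
    logw -= logw.max()
    w = np.exp(logw)
    mask = w <= w[a - lo] * (1 + 1e-7)
    return float(w[mask].sum() / w.sum())


def fisher_2x2(table) -> ContingencySummary:
    """Two-sided Fisher exact test with conditional-MLE odds ratio.

    A zero margin yields p = 1 and an undefined (NaN) odds ratio.
    """
    (a, b), (c, d) = table
    for x in (a, b, c, d):
        if x < 0 or int(x) != x:
            raise StatsError("table entries must be non-negative integers")
    a, b, c, d = int(a), int(b), int(c), int(d)
    N = a + b + c + d
    if min(a + b, c + d, a + c, b + d) == 0 or N == 0:
        return ContingencySummary(((a, b), (c, d)), float("nan"), float("nan"), 1.0, "fisher")
    if N <= EXACT_LIMIT:
        p = _fisher_exact_int(a, b, c, d)
    else:
        p = _fisher_log(a, b, c, d)
    orat = float(stats.contingency.odds_ratio([[a, b], [c, d]], kind="conditional").statistic)
    total_rate = (a + c) / N
    fold = (a / (a + b)) / total_rate if total_rate > 0 else float("nan")
    return ContingencySummary(((a, b), (c, d)), orat, fold, min(p, 1.0), "fisher")


def deg_dar_association(
    deg_flags: pd.Series, dar_proximal_flags: pd.Series
) -> ContingencySummary:
    """Hypergeometric enrichment of DEGs among genes with a proximal DAR.

    Both flag series are boolean over the same gene universe (genes with an
    assigned promoter/ATAC peak). The expected overlap under independence
    is K*n/N; ``fold`` is observed/expected.
    """
    if len(deg_flags) == 0:
        raise StatsError("empty gene universe")
    dar_proximal_flags = dar_proximal_flags.reindex(deg_flags.index, fill_value=False)
    N = int(len(deg_flags))
    K = int(deg_flags.sum())
    n = int(dar_proximal_flags.sum())
    k = int((deg_flags & dar_proximal_flags).sum())
    return hypergeom_enrichment(k, K, n, N)


def cluster_sensitivity_enrichment(
    clusters: pd.Series, sensitive: pd.Series, high=("C1", "C2"), low: str = "C3"
) -> ContingencySummary:
    """Enrichment of PRC2-sensitive genes in H3K27me3-high clusters vs C3.

    ``fold`` = sensitivity rate in C1 u C2 divided by the rate in C3; the
    Fisher test is on the (high vs C3) x (sensitive vs not) 2x2 table.
    An empty C3 (or a zero C3 rate with nonzero high rate) flags the fold
    as infinite.
    """
    sensitive = sensitive.reindex(clusters.index)
    hi_mask = clusters.isin(high)
    lo_mask = clusters == low
    n_hi, n_lo = int(hi_mask.sum()), int(lo_mask.sum())
    k_hi = int(sensitive[hi_mask].sum())
    k_lo = int(sensitive[lo_mask].sum())
    if n_lo == 0:
        fold = float("nan")
    else:
        rate_lo = k_lo / n_lo
        rate_hi = k_hi / n_hi if n_hi else 0.0
        fold = rate_hi / rate_lo if rate_lo > 0 else (inf if rate_hi > 0 else 1.0)
    fisher = fisher_2x2(((k_hi, n_hi - k_hi), (k_lo, n_lo - k_lo)))
    return ContingencySummary(fisher.table, fisher.odds_ratio, fold, fisher.p, "fisher")


def accessibility_expression_correlation(
    rna_lfc: pd.Series,
    atac_lfc_by_gene: pd.Series,
    significant: pd.Series,
) -> list[CorrelationSummary]:
    """Pearson correlation of RNA vs promoter-ATAC log2FC by stratum.

    ``significant`` marks genes that are DEGs or have a DAR-proximal
    promoter; the complementary stratum collects genes without significant
    changes. Also reports, per stratum, the median absolute accessibility
    fold change 2^|median |log2FC|| — the "half of DEG promoters change
    less than x-fold" style summary. Strata with zero-variance vectors are
    reported with r = NaN rather than dropped.
    """
    common = rna_lfc.index.intersection(atac_lfc_by_gene.dropna().index)
    rna = rna_lfc.loc[common]
    atac = atac_lfc_by_gene.loc[common]
    sig = significant.reindex(common, fill_value=False)
    out = []
    for label, mask in (("DEG-or-DAR-proximal", sig), ("non-significant", ~sig)):
        x = rna[mask].to_numpy(dtype=float)
        y = atac[mask].to_numpy(dtype=float)
        n = len(x)
        if n < 3 or np.std(x) == 0 or np.std(y) == 0:
            r = float("nan")
        else:
            r = float(stats.pearsonr(x, y).statistic)
        med_fold = float(2 ** np.median(np.abs(y))) if n else float("nan")
        out.append(CorrelationSummary(label, n, r, med_fold))
    return out


def lfc_by_cluster(
    lfc: pd.Series, clusters: pd.Series, direction: pd.Series, organ: str
) -> pd.DataFrame:
    """Box-plot statistics of knockout log2FC per (cluster, DEG direction).

    ``direction`` labels each gene's tissue-enrichment (e.g. "St-up",
    "Int-up"); quartiles are linear-interpolation (type 7) quantiles.
    Empty cells yield n = 0 rows with NaN statistics.
    """
    frame = pd.DataFrame({"lfc": lfc, "cluster": clusters, "direction": direction}).dropna(
        subset=["cluster", "direction"]
    )
    rows = []
    for clu in sorted(frame["cluster"].unique()):
        for dirn in sorted(frame["direction"].unique()):
            vals = frame.loc[
                (frame["cluster"] == clu) & (frame["direction"] == dirn), "lfc"
            ].to_numpy(dtype=float)
            if len(vals):
                q1, med, q3 = np.percentile(vals, [25, 50, 75])
            else:
                q1 = med = q3 = float("nan")
            rows.append(
                {
                    "organ": organ,
                    "cluster": clu,
                    "direction": dirn,
                    "n": len(vals),
                    "q1": q1,
                    "median": med,
                    "q3": q3,
                }
            )
    return pd.DataFrame(rows)


def _stars(padj: float, tiers=(0.05, 0.01, 0.001)) -> str:
    s = sum(padj < t for t in tiers)
    return "*" * s


def ligand_repertoire_compare(
    tpm_by_condition: pd.DataFrame,
    ligand_ids: list[str],
    de_tables: dict[str, pd.DataFrame] | None = None,
    reference: str | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Secreted-ligand repertoire comparison across conditions.

    Restricts the replicate-averaged TPM table to ligand genes and returns
    (1) a differential-ligand table with log(TPM+1) per condition and
    significance-star tiers from the supplied DE tables (padj < 0.05/0.01/
    0.001 -> one/two/three stars), and (2) the pairwise Spearman rho matrix
    over conditions on log(TPM+1), with ties handled by average ranks.
    """
    ligands = [g for g in ligand_ids if g in tpm_by_condition.index]
    if len(ligands) < 3:
        raise StatsError(f"need >= 3 ligand genes present, have {len(ligands)}")
    log_tpm = np.log(tpm_by_condition.loc[ligands] + 1.0)
    conds = list(log_tpm.columns)
    rho = pd.DataFrame(np.eye(len(conds)), index=conds, columns=conds)
    for i, ci in enumerate(conds):
        for j in range(i + 1, len(conds)):
            cj = conds[j]
            r = float(stats.spearmanr(log_tpm[ci], log_tpm[cj]).statistic)
            rho.loc[ci, cj] = rho.loc[cj, ci] = r
    table = log_tpm.copy()
    table.columns = [f"log_tpm1.{c}" for c in conds]
    if de_tables:
        for name, de in de_tables.items():
            padj = de["padj"].reindex(ligands)
            table[f"stars.{name}"] = [
                _stars(p) if np.isfinite(p) else "" for p in padj
            ]
    return table, rho
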