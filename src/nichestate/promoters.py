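"""Promoter approximation, signal matrices, H3K27me3 clustering and
chromatin-state classification.

Gene promoters are approximated as the midpoint of the nearest merged
H3K4me3 peak within 50 kb of the annotated TSS; genes without such a peak
are excluded from promoter-level analyses and reported. Promoters are then
attached to the nearest consensus ATAC peak (within 50 kb), profiled over
promoter +/- 4 kb in 50 bp bins, clustered by H3K27me3 shape into
C1 (broad domains) / C2 (high focal peaks) / C3 (low signal), and assigned
a simplified chromatin state per tissue either from a state annotation
(largest-overlap rule) or from mark-peak co-occupancy: H3K4me3 with
H3K27me3 is the bivalent hallmark, H3K4me3 with H3K27ac (and no H3K27me3)
is active, H3K27me3 alone is repressed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .intervals import (
    GeneModel,
    GenomicInterval,
    SignalTrack,
    StateAnnotation,
    extract_binned_signal,
    nearest_feature,
)

__all__ = [
    "PromoterMap",
    "approximate_promoters",
    "assign_promoter_atac",
    "build_signal_matrix",
    "cluster_promoters",
    "classify_state",
    "classify_states",
    "tabulate_switches",
]

STATE_PRIORITY = ("Bivalent", "Active", "Repressed", "Other")


class PromoterError(ValueError):
    pass


@dataclass
class PromoterMap:
    """Assigned promoters (gene -> position) plus the unassigned remainder."""

    table: pd.DataFrame  # index gene_id; chrom, promoter_pos, tss_distance
    unassigned: list[str]

    @property
    def genes(self) -> list[str]:
        return list(self.table.index)


def approximate_promoters(
    genes: list[GeneModel],
    k4_peaks: list[GenomicInterval],
    max_dist: int = 50_000,
) -> PromoterMap:
    """Promoter = midpoint of the nearest H3K4me3 peak within ``max_dist`` of the TSS."""
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for pk in sorted(k4_peaks):
        by_chrom.setdefault(pk.chrom, []).append(pk)
    rows, unassigned = [], []
    for g in genes:
        hit = nearest_feature(g.chrom, g.tss, by_chrom.get(g.chrom, []), max_dist)
        if hit is None:
            unassigned.append(g.gene_id)
            continue
        peak, dist = hit
        rows.append(
            {
                "gene_id": g.gene_id,
                "chrom": g.chrom,
                "promoter_pos": peak.midpoint,
                "tss_distance": dist,
            }
        )
    table = pd.DataFrame(rows).set_index("gene_id") if rows else pd.DataFrame(
        columns=["chrom", "promoter_pos", "tss_distance"]
    )
    return PromoterMap(table, unassigned)


def assign_promoter_atac(
    promoters: PromoterMap,
    consensus: list[GenomicInterval],
    max_dist: int = 50_000,
) -> pd.Series:
    """Nearest consensus ATAC region id per promoter (None beyond ``max_dist``)."""
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for pk in sorted(consensus):
        by_chrom.setdefault(pk.chrom, []).append(pk)
    out = {}
    for gene_id, row in promoters.table.iterrows():
        hit = nearest_feature(
            row["chrom"], int(row["promoter_pos"]), by_chrom.get(row["chrom"], []), max_dist
        )
        out[gene_id] = None if hit is None else (hit[0].name or f"{hit[0].chrom}:{hit[0].start}-{hit[0].end}")
    return pd.Series(out, name="atac_region", dtype=object)


def build_signal_matrix(
    promoters: PromoterMap,
    track: SignalTrack,
    flank: int = 4_000,
    bin_size: int = 50,
) -> pd.DataFrame:
    """Genes x bins matrix of mean signal over promoter +/- ``flank``."""
    mats = [
        extract_binned_signal(track, row["chrom"], int(row["promoter_pos"]), flank, bin_size)
        for _, row in promoters.table.iterrows()
    ]
    n_bins = 2 * flank // bin_size
    cols = [f"bin{i}" for i in range(n_bins)]
    if not mats:
        return pd.DataFrame(columns=cols)
    return pd.DataFrame(np.vstack(mats), index=promoters.table.index, columns=cols)


def cluster_promoters(
    k27_matrix: pd.DataFrame,
    seed: int = 0,
    n_init: int = 10,
    breadth_quantile: float = 90.0,
) -> pd.Series:
    """K-means (k=3) H3K27me3 shape clusters, relabelled C1/C2/C3.

    Rows are standardized per bin before clustering. The arbitrary k-means
    indices are then relabelled deterministically from the raw signal:
    C1 is the cluster with the greatest breadth (mean fraction of bins above
    half the matrix-wide 90th-percentile signal), C2 the remaining cluster
    with the larger central-bin mean, C3 the rest — matching broad domains,
    high focal peaks, and low signal respectively.
    """
    if len(k27_matrix) < 3:
        raise PromoterError(f"need >= 3 promoters to cluster, have {len(k27_matrix)}")
    raw = k27_matrix.to_numpy(dtype=float)
    mu = raw.mean(axis=0)
    sd = raw.std(axis=0)
    z = (raw - mu) / np.where(sd > 0, sd, 1.0)
    km = KMeans(n_clusters=3, n_init=n_init, random_state=seed)
    idx = km.fit_predict(z)
    thresh = 0.5 * np.percentile(raw, breadth_quantile)
    breadth = np.array(
        [(raw[idx == c] > thresh).mean() if (idx == c).any() else 0.0 for c in range(3)]
    )
    n_bins = raw.shape[1]
    center = slice(n_bins // 2 - max(1, n_bins // 20), n_bins // 2 + max(1, n_bins // 20))
    height = np.array(
        [raw[idx == c, center].mean() if (idx == c).any() else 0.0 for c in range(3)]
    )
    c1 = int(np.argmax(breadth))
    rest = [c for c in range(3) if c != c1]
    c2 = rest[int(np.argmax(height[rest]))]
    c3 = [c for c in rest if c != c2][0]
    mapping = {c1: "C1", c2: "C2", c3: "C3"}
    return pd.Series([mapping[i] for i in idx], index=k27_matrix.index, name="cluster")


def _overlaps(chrom: str, start: int, end: int, peaks: list[GenomicInterval]) -> bool:
    return any(p.chrom == chrom and p.start < end and p.end > start for p in peaks)


def classify_state(
    chrom: str,
    promoter_pos: int,
    k4_peaks: list[GenomicInterval],
    k27me3_peaks: list[GenomicInterval],
    k27ac_peaks: list[GenomicInterval],
    states: StateAnnotation | None = None,
    window: int = 1_000,
) -> str:
    """Simplified chromatin state of the promoter +/- ``window`` bp.

    With a state annotation, the label with the largest bp overlap wins
    (ties resolved Bivalent > Active > Repressed > Other). Otherwise the
    call is mark-based: K4+K27me3 -> Bivalent; K4+K27ac without K27me3 ->
    Active; K27me3 without K4 -> Repressed; else Other.
    """
    start, end = max(0, promoter_pos - window), promoter_pos + window
    if states is not None:
        ov = states.overlap_by_state(chrom, start, end)
        best = max(STATE_PRIORITY, key=lambda s: (ov[s], -STATE_PRIORITY.index(s)))
        if ov[best] > 0:
            return best
        return "Other"
    k4 = _overlaps(chrom, start, end, k4_peaks)
    k27me3 = _overlaps(chrom, start, end, k27me3_peaks)
    k27ac = _overlaps(chrom, start, end, k27ac_peaks)
    if k4 and k27me3:
        return "Bivalent"
    if k4 and k27ac:
        return "Active"
    if k27me3:
        return "Repressed"
    return "Other"


def classify_states(
    promoters: PromoterMap,
    k4_peaks: list[GenomicInterval],
    k27me3_peaks: list[GenomicInterval],
    k27ac_peaks: list[GenomicInterval],
    states: StateAnnotation | None = None,
    window: int = 1_000,
) -> pd.Series:
    """Vector of per-gene promoter states (see :func:`classify_state`)."""
    by_chrom: dict[str, dict[str, list[GenomicInterval]]] = {}
    for name, peaks in (("k4", k4_peaks), ("k27me3", k27me3_peaks), ("k27ac", k27ac_peaks)):
        d: dict[str, list[GenomicInterval]] = {}
        for p in peaks:
            d.setdefault(p.chrom, []).append(p)
        by_chrom[name] = d
    out = {}
    for gene_id, row in promoters.table.iterrows():
        chrom = row["chrom"]
        out[gene_id] = classify_state(
            chrom,
            int(row["promoter_pos"]),
            by_chrom["k4"].get(chrom, []),
            by_chrom["k27me3"].get(chrom, []),
            by_chrom["k27ac"].get(chrom, []),
            states=states,
            window=window,
        )
    return pd.Series(out, name="state")


def tabulate_switches(
    gene_ids: list[str],
    states_a: pd.Series,
    states_b: pd.Series,
    labels: tuple[str, str] = ("A", "B"),
) -> pd.DataFrame:
    """Cross-tabulate promoter states between two tissues over a gene set.

    Returns a long-format table with counts and fractions of the gene set;
    genes missing a state in either tissue are collected in an explicit
    ``unassigned`` row. The headline Bivalent->Active cell can be read off
    directly.
    """
    vocab = list(STATE_PRIORITY)
    counts = {(sa, sb): 0 for sa in vocab for sb in vocab}
    unassigned = 0
    for g in gene_ids:
        sa = states_a.get(g)
        sb = states_b.get(g)
        if sa in vocab and sb in vocab:
            counts[(sa, sb)] += 1
        else:
            unassigned += 1
    n = len(gene_ids)
    rows = [
        {
            "from": sa,
            "to": sb,
            "switch": f"{sa}->{sb}",
            "count": c,
            "fraction": c / n if n else float("nan"),
        }
        for (sa, sb), c in counts.items()
    ]
    rows.append(
        {
            "from": "unassigned",
            "to": "unassigned",
            "switch": "unassigned",
            "count": unassigned,
            "fraction": unassigned / n if n else float("nan"),
        }
    )
    out = pd.DataFrame(rows)
    out.attrs["tissues"] = labels
    return out
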