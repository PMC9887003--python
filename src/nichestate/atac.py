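"""Consensus accessible regions, differential accessibility, cCRE classes.

The consensus peakset is the gap-0 union-merge of peaks called across all
tissues and conditions; it is the counting universe for differential
accessibility. DARs are called with the same NB Wald machinery as genes,
at padj < 0.05 and |log2FC| > 1. Regions are classed promoter-like /
proximal-enhancer / distal-enhancer from the distance of their midpoint to
the nearest TSS, using the conventional 200 bp / 2 kb band edges.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .de import CountMatrix, call_degs, nb_wald_test
from .intervals import GeneModel, GenomicInterval, merge_intervals

__all__ = ["ConsensusPeakSet", "build_consensus", "call_dars", "annotate_ccre"]


@dataclass
class ConsensusPeakSet:
    """Merged, non-overlapping regions with stable ids and provenance."""

    regions: list[GenomicInterval]  # sorted; name = "chrom:start-end"
    provenance: dict[str, list[str]]  # region id -> contributing input set names

    def ids(self) -> list[str]:
        return [r.name for r in self.regions]

    def __len__(self) -> int:
        return len(self.regions)


def build_consensus(peak_sets: dict[str, list[GenomicInterval]]) -> ConsensusPeakSet:
    """Union-merge (gap 0) of all input peak sets into consensus regions.

    Region ids are ``chrom:start-end``; provenance records which input sets
    contributed at least one peak to each region. An empty union yields an
    empty set (not an error).
    """
    if not peak_sets:
        raise ValueError("need at least one peak set")
    all_peaks = [p for peaks in peak_sets.values() for p in peaks]
    merged = merge_intervals(all_peaks, max_gap=0)
    regions = [
        GenomicInterval(m.chrom, m.start, m.end, name=f"{m.chrom}:{m.start}-{m.end}")
        for m in merged
    ]
    prov: dict[str, list[str]] = {r.name: [] for r in regions}
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for r in regions:
        by_chrom.setdefault(r.chrom, []).append(r)
    starts_by_chrom = {c: [r.start for r in rs] for c, rs in by_chrom.items()}
    from bisect import bisect_right

    for set_name, peaks in peak_sets.items():
        seen: set[str] = set()
        for p in peaks:
            rs = by_chrom.get(p.chrom)
            if not rs:
                continue
            # regions are disjoint and sorted: the overlap run starts at the
            # region containing/preceding p.start and extends while start < p.end
            i = max(0, bisect_right(starts_by_chrom[p.chrom], p.start) - 1)
            while i < len(rs) and rs[i].start < p.end:
                r = rs[i]
                if r.end > p.start and r.name not in seen:
                    prov[r.name].append(set_name)
                    seen.add(r.name)
                i += 1
    return ConsensusPeakSet(regions, prov)


def call_dars(
    atac_counts: CountMatrix,
    group_a: list[str],
    group_b: list[str],
    size_factors: pd.Series,
    padj_max: float = 0.05,
    lfc_min: float = 1.0,
) -> tuple[pd.DataFrame, dict]:
    """Differential accessibility over consensus regions (B vs A).

    Delegates to the NB Wald test and calls DARs at padj < ``padj_max`` and
    |log2FC| > ``lfc_min`` (absolute-value rule, so losses of accessibility
    count too). Returns the flagged table and a summary with the DAR count
    and percentage of the consensus universe.
    """
    res = nb_wald_test(atac_counts, group_a, group_b, size_factors)
    res = call_degs(res, padj_max=padj_max, lfc_min=lfc_min)
    n = len(res)
    n_dar = int(res["call"].sum())
    summary = {
        "n_regions": n,
        "n_dar": n_dar,
        "pct_dar": 100.0 * n_dar / n if n else 0.0,
        "n_up": int((res["call"] & (res["log2fc"] > 0)).sum()),
        "n_down": int((res["call"] & (res["log2fc"] < 0)).sum()),
    }
    return res, summary


def annotate_ccre(
    consensus: ConsensusPeakSet,
    genes: list[GeneModel],
    promoter_dist: int = 200,
    proximal_dist: int = 2_000,
) -> pd.DataFrame:
    """Distance-based cCRE class per region: promoter-like / proximal / distal.

    The region midpoint is compared with the nearest TSS: within
    ``promoter_dist`` -> promoter-like, within ``proximal_dist`` ->
    proximal-enhancer, else distal-enhancer. The three classes partition
    the region set.
    """
    if not genes:
        raise ValueError("gene set must be non-empty")
    tss_by_chrom: dict[str, list[int]] = {}
    for g in genes:
        tss_by_chrom.setdefault(g.chrom, []).append(g.tss)
    for v in tss_by_chrom.values():
        v.sort()
    import bisect

    rows = []
    for r in consensus.regions:
        mid = r.midpoint
        tss_list = tss_by_chrom.get(r.chrom)
        if not tss_list:
            dist = None
        else:
            i = bisect.bisect_left(tss_list, mid)
            cands = tss_list[max(0, i - 1) : i + 1]
            dist = min(abs(mid - t) for t in cands)
        if dist is None:
            cls = "distal-enhancer"
            dist = -1
        elif dist <= promoter_dist:
            cls = "promoter-like"
        elif dist <= proximal_dist:
            cls = "proximal-enhancer"
        else:
            cls = "distal-enhancer"
        rows.append(
            {"region": r.name, "ccre_class": cls, "tss_distance": int(dist)}
        )
    return pd.DataFrame(rows).set_index("region")
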