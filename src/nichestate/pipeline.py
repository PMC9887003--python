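"""End-to-end orchestration: simulate -> normalize/DE -> DAR -> promoter
state -> statistics, as one reproducible run.

Stages communicate only through files under the run directory; every
threshold lives in :class:`RunConfig` (defaulting to the analysis cutoffs:
padj < 0.05 with |log2FC| > 1 for DEGs/DARs, padj < 0.2 for the
interaction contrast, 50 kb promoter assignment, +/-1 kb proximity,
+/-4 kb signal windows) and a single root seed governs all stochastic
steps. Re-running with the same config reproduces byte-identical tables.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import atac as atac_mod
from . import de as de_mod
from . import enrichment as enr
from . import promoters as prom_mod
from .intervals import merge_intervals, read_intervals
from .io import read_count_matrix, read_genes, read_ligand_list, read_signal_track
from .simulate import TISSUES, Cohort, CohortDesign, generate_cohort

__all__ = ["RunConfig", "run_pipeline"]

FLOAT_FMT = "%.6g"


class PipelineError(RuntimeError):
    pass


@dataclass
class RunConfig:
    """Complete, serializable description of a pipeline run."""

    out_dir: str = "nichestate_run"
    seed: int = 0
    simulate: bool = True
    input_dir: str | None = None  # existing bundle when simulate is False
    design: CohortDesign = field(default_factory=CohortDesign)

    padj_max: float = 0.05
    lfc_min: float = 1.0
    interaction_padj: float = 0.2
    interaction_est: float = 1.0
    promoter_max_dist: int = 50_000
    proximity_window: int = 1_000
    state_window: int = 1_000
    flank: int = 4_000
    bin_size: int = 50
    cluster_seed: int = 0
    cluster_n_init: int = 10
    ccre_promoter_dist: int = 200
    ccre_proximal_dist: int = 2_000
    use_state_annotation: bool = True

    def __post_init__(self) -> None:
        for name in (
            "padj_max", "lfc_min", "interaction_padj", "interaction_est",
            "promoter_max_dist", "proximity_window", "flank", "bin_size",
        ):
            if getattr(self, name) <= 0:
                raise PipelineError(f"threshold {name} must be positive")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["design"] = self.design.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "design" in d and isinstance(d["design"], dict):
            d["design"] = CohortDesign.from_dict(d["design"])
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def _write(df: pd.DataFrame, path: str, **kw) -> None:
    df.to_csv(path, sep="\t", float_format=FLOAT_FMT, **kw)


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage and return the machine-readable summary dict.

    Also writes per-stage TSVs, ``summary.json`` and ``run_log.txt`` under
    ``config.out_dir``.
    """
    os.makedirs(config.out_dir, exist_ok=True)
    log_lines = [f"seed={config.seed}"]

    # ---- inputs ---------------------------------------------------------
    if config.simulate:
        design = dataclasses.replace(config.design, seed=config.seed)
        bundle_dir = os.path.join(config.out_dir, "cohort")
        cohort = generate_cohort(design, bundle_dir)
        log_lines.append(f"simulated cohort in {bundle_dir}")
    else:
        if not config.input_dir or not os.path.isdir(config.input_dir):
            raise PipelineError(f"input stage: bundle directory not found: {config.input_dir}")
        cohort = Cohort(config.input_dir, config.design)
    for req in ("rna_counts.tsv", "atac_counts.tsv", "genes.tsv"):
        if not os.path.exists(cohort.path(req)):
            raise PipelineError(f"input stage: missing required input {req}")

    genes = read_genes(cohort.path("genes.tsv"))
    gene_lengths = pd.Series({g.gene_id: g.length for g in genes})
    ligands = read_ligand_list(cohort.path("ligands.tsv"))

    # ---- stage: normalization + differential expression -----------------
    rna = read_count_matrix(
        cohort.path("rna_counts.tsv"), cohort.path("rna_meta.tsv"), cohort.path("spikeins.txt")
    )
    sf = de_mod.spikein_size_factors(rna)
    _write(sf.to_frame(), os.path.join(config.out_dir, "size_factors.tsv"))

    contrasts: dict[str, pd.DataFrame] = {}
    # tissue contrast (Int vs St) within each genotype
    for geno in ("WT", "KO"):
        res = de_mod.nb_wald_test(rna, rna.group("St", geno), rna.group("Int", geno), sf)
        contrasts[f"Int.vs.St.{geno}"] = de_mod.call_degs(res, config.padj_max, config.lfc_min)
    # knockout contrast (KO vs WT) within each tissue
    for tissue in TISSUES:
        res = de_mod.nb_wald_test(rna, rna.group(tissue, "WT"), rna.group(tissue, "KO"), sf)
        contrasts[f"KO.vs.WT.{tissue}"] = de_mod.call_degs(res, config.padj_max, config.lfc_min)
    inter = de_mod.interaction_contrast(rna, sf, config.interaction_padj, config.interaction_est)
    for name, tab in contrasts.items():
        _write(tab, os.path.join(config.out_dir, f"de_{name}.tsv"), index_label="feature")
    _write(inter, os.path.join(config.out_dir, "de_interaction.tsv"), index_label="feature")

    tpm, tpm_avg = de_mod.compute_tpm(rna, gene_lengths, sf)
    _write(tpm_avg, os.path.join(config.out_dir, "tpm_by_condition.tsv"), index_label="gene")

    # ---- stage: consensus peaks + differential accessibility -------------
    peak_sets = {}
    peak_dir = cohort.path("peaks")
    for fn in sorted(os.listdir(peak_dir)):
        if fn.endswith(".narrowPeak"):
            peak_sets[fn[: -len(".narrowPeak")]] = read_intervals(
                os.path.join(peak_dir, fn), "narrowPeak"
            )
    consensus = atac_mod.build_consensus(peak_sets)
    atac_cm = read_count_matrix(cohort.path("atac_counts.tsv"), cohort.path("atac_meta.tsv"))
    missing = [i for i in consensus.ids() if i not in atac_cm.counts.index]
    if missing:
        raise PipelineError(f"atac stage: {len(missing)} consensus regions lack counts")
    atac_cm = de_mod.CountMatrix(
        atac_cm.counts.loc[consensus.ids()], atac_cm.meta, atac_cm.spikein
    )
    atac_sf = de_mod.median_of_ratios_size_factors(atac_cm.counts)
    dar_tab, dar_summary = atac_mod.call_dars(
        atac_cm, atac_cm.group("St", "WT"), atac_cm.group("Int", "WT"), atac_sf,
        config.padj_max, config.lfc_min,
    )
    ccre = atac_mod.annotate_ccre(
        consensus, genes, config.ccre_promoter_dist, config.ccre_proximal_dist
    )
    dar_out = dar_tab.join(ccre)
    _write(dar_out, os.path.join(config.out_dir, "dars_Int.vs.St.WT.tsv"), index_label="region")

    # ---- stage: promoter state ------------------------------------------
    k4_union = merge_intervals(
        [p for t in TISSUES for p in read_intervals(cohort.path("chip", f"k4_{t}.narrowPeak"), "narrowPeak")]
    )
    promoters = prom_mod.approximate_promoters(genes, k4_union, config.promoter_max_dist)
    atac_assign = prom_mod.assign_promoter_atac(
        promoters, consensus.regions, config.promoter_max_dist
    )
    log_lines.append(
        f"promoters assigned for {len(promoters.genes)} genes; "
        f"{len(promoters.unassigned)} unassigned"
    )

    k27_int = read_signal_track(cohort.path("tracks", "k27me3_Int.bedgraph"), config.bin_size)
    k27_mat = prom_mod.build_signal_matrix(promoters, k27_int, config.flank, config.bin_size)
    clusters = prom_mod.cluster_promoters(
        k27_mat, seed=config.cluster_seed, n_init=config.cluster_n_init
    )

    states = {}
    for tissue in TISSUES:
        ann = (
            read_intervals(cohort.path("states", f"states_{tissue}.bed"), "state-bed")
            if config.use_state_annotation
            else None
        )
        states[tissue] = prom_mod.classify_states(
            promoters,
            read_intervals(cohort.path("chip", f"k4_{tissue}.narrowPeak"), "narrowPeak"),
            read_intervals(cohort.path("chip", f"k27me3_{tissue}.narrowPeak"), "narrowPeak"),
            read_intervals(cohort.path("chip", f"k27ac_{tissue}.narrowPeak"), "narrowPeak"),
            states=ann,
            window=config.state_window,
        )
    switches = prom_mod.tabulate_switches(
        promoters.genes, states["Int"], states["St"], labels=("Int", "St")
    )
    prom_table = promoters.table.copy()
    prom_table["atac_region"] = atac_assign
    prom_table["cluster"] = clusters
    prom_table["state_Int"] = states["Int"]
    prom_table["state_St"] = states["St"]
    _write(prom_table, os.path.join(config.out_dir, "promoters.tsv"), index_label="gene")
    _write(switches, os.path.join(config.out_dir, "state_switches.tsv"), index=False)

    # ---- stage: cross-talk statistics ------------------------------------
    wt = contrasts["Int.vs.St.WT"]
    universe = prom_table.index[prom_table["atac_region"].notna()]
    deg_flags = wt.loc[universe, "call"]
    atac_lfc_by_gene = prom_table.loc[universe, "atac_region"].map(dar_tab["log2fc"])
    dar_call_by_gene = (
        prom_table.loc[universe, "atac_region"].map(dar_tab["call"]).fillna(False).astype(bool)
    )
    # proximity: promoter within +/- proximity_window of its assigned region
    region_pos = {
        r.name: (r.start, r.end) for r in consensus.regions
    }
    prox = []
    for g in universe:
        rid = prom_table.loc[g, "atac_region"]
        s, e = region_pos[rid]
        p = int(prom_table.loc[g, "promoter_pos"])
        d = 0 if s <= p < e else min(s - p if p < s else 10**9, p - e if p >= e else 10**9)
        prox.append(d <= config.proximity_window)
    proximal = pd.Series(prox, index=universe)
    dar_proximal = dar_call_by_gene & proximal
    assoc = enr.deg_dar_association(deg_flags, dar_proximal)

    strata = enr.accessibility_expression_correlation(
        wt.loc[universe, "log2fc"], atac_lfc_by_gene, deg_flags | dar_proximal
    )
    ko_int = contrasts["KO.vs.WT.Int"]
    sens_enr = enr.cluster_sensitivity_enrichment(
        clusters, ko_int.loc[clusters.index, "call"]
    )
    direction = wt["log2fc"].where(wt["call"]).map(
        lambda v: ("Int-up" if v > 0 else "St-up") if pd.notna(v) else np.nan
    )
    lfc_tables = pd.concat(
        [
            enr.lfc_by_cluster(
                contrasts[f"KO.vs.WT.{t}"]["log2fc"].reindex(clusters.index),
                clusters,
                direction.reindex(clusters.index),
                organ=t,
            )
            for t in TISSUES
        ],
        ignore_index=True,
    )
    _write(lfc_tables, os.path.join(config.out_dir, "lfc_by_cluster.tsv"), index=False)

    ligand_tab, rho = enr.ligand_repertoire_compare(
        tpm_avg, ligands,
        de_tables={"KO.vs.WT.Int": ko_int, "KO.vs.WT.St": contrasts["KO.vs.WT.St"]},
    )
    _write(ligand_tab, os.path.join(config.out_dir, "ligand_table.tsv"), index_label="gene")
    _write(rho, os.path.join(config.out_dir, "ligand_spearman.tsv"), index_label="condition")

    # ---- summary ----------------------------------------------------------
    biv_active = switches.loc[switches["switch"] == "Bivalent->Active"]
    summary = {
        "seed": config.seed,
        "n_genes": int(len(gene_lengths)),
        "de": {k: de_mod.summarize_calls(v) for k, v in contrasts.items()},
        "interaction": {"n_called": int(inter["call"].sum()), "n_tested": int(len(inter))},
        "dar": dar_summary,
        "ccre_classes": ccre["ccre_class"].value_counts().to_dict(),
        "promoters": {
            "n_assigned": int(len(promoters.genes)),
            "n_unassigned": int(len(promoters.unassigned)),
            "cluster_sizes": clusters.value_counts().to_dict(),
        },
        "switch_bivalent_to_active": {
            "count": int(biv_active["count"].iloc[0]),
            "denominator": int(len(promoters.genes)),
            "fraction": float(biv_active["fraction"].iloc[0]),
        },
        "deg_dar_association": assoc.as_dict(),
        "accessibility_expression": [s.as_dict() for s in strata],
        "cluster_sensitivity": sens_enr.as_dict(),
        "ligand_spearman": {
            f"{a}~{b}": float(rho.loc[a, b])
            for i, a in enumerate(rho.index)
            for b in rho.index[i + 1 :]
        },
        "universe_size": int(len(universe)),
    }
    cfg_yaml = yaml.safe_dump(config.to_dict(), sort_keys=True)
    summary["config_sha256"] = hashlib.sha256(cfg_yaml.encode()).hexdigest()
    with open(os.path.join(config.out_dir, "summary.json"), "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True, default=float)
        fh.write("\n")
    config.to_yaml(os.path.join(config.out_dir, "config.yaml"))
    with open(os.path.join(config.out_dir, "run_log.txt"), "w") as fh:
        fh.write("\n".join(log_lines) + "\n")
    return summary
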