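"""Synthetic two-tissue (Int/St), two-genotype (WT/KO) cohort generator.

Generates a complete in-silico analogue of the data the pipeline consumes:
gene models on a synthetic genome, H3K4me3/H3K27me3/H3K27ac peak sets and
binned signal tracks per tissue, simplified chromatin-state BEDs, ATAC peak
sets per condition, RNA and ATAC count matrices with spike-in rows, a
secreted-ligand list — and a machine-readable planted-truth table keyed to
every downstream quantity (tissue DEGs, PRC2 sensitivity per organ,
promoter archetypes, bivalency, state switches, DARs).

The generative model:

* Genes sit at fixed spacing on the synthetic genome so nearest-peak logic
  is unambiguous; spacing is configurable to create deliberate 50 kb
  assignment failures.
* RNA counts are negative binomial with log-normal baseline means, a
  symmetric planted tissue effect of |log2FC| = 2 for differential genes,
  and a per-organ knockout derepression of +2 log2 units for
  PRC2-sensitive genes. Per-sample depth distortions (0.5-2x) multiply all
  rows; spike-in rows share a constant true abundance and are near-Poisson
  (technical noise only), so they anchor normalization.
* Promoter chromatin is planted per (gene, tissue): bivalent promoters get
  overlapping H3K4me3 + H3K27me3 peaks, active promoters H3K4me3 + H3K27ac,
  repressed ones H3K27me3 alone. H3K27me3 realizes three archetypes: a
  broad >= 5 kb domain, a sharp <= 1 kb focal peak, or background. A fixed
  fraction of promoter-assignable genes switches Bivalent (Int) -> Active
  (St). PRC2 sensitivity is planted at a higher rate under
  H3K27me3-marked promoters (4-fold by default), and tissue-DEG promoter
  ATAC peaks are planted as sign-matched DARs, coupling expression to
  accessibility.

All randomness flows from one root seed through named substreams, so the
bundle is byte-identical across runs with the same design.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .intervals import GeneModel, GenomicInterval, write_intervals

__all__ = [
    "CohortDesign",
    "Cohort",
    "generate_cohort",
    "simplify_states",
    "DEFAULT_STATE_MAP",
    "nb_counts",
]

TISSUES = ("Int", "St")
GENOTYPES = ("WT", "KO")

#: default raw ChromHMM-style label -> simplified state mapping
DEFAULT_STATE_MAP = {
    "Tss-active": "Active",
    "TssFlnk": "Active",
    "Enhancer-active": "Active",
    "Transcribed": "Active",
    "TssBivalent": "Bivalent",
    "EnhancerPoised": "Bivalent",
    "PolycombRepressed": "Repressed",
    "Heterochromatin": "Repressed",
    "Quiescent": "Other",
    "Low": "Other",
}


class DesignError(ValueError):
    pass


@dataclass
class CohortDesign:
    """All knobs of the synthetic cohort; defaults define the study conditions."""

    n_genes: int = 2000
    n_spikeins: int = 50
    chrom_sizes: dict = field(
        default_factory=lambda: {"chr1": 101_000_000, "chr2": 101_000_000}
    )
    gene_spacing: int = 100_000
    replicates: int = 3
    seed: int = 0

    # planted gene classes
    deg_fraction: float = 0.10          # WT tissue DEGs (half Int-up, half St-up)
    deg_lfc: float = 2.0                # |log2FC| of planted DEGs
    derepression_lfc: float = 2.0       # KO log2 gain at PRC2-sensitive promoters
    switch_fraction: float = 0.30       # Bivalent(Int)->Active(St), of assignable genes
    stable_bivalent_fraction: float = 0.20
    repressed_fraction: float = 0.05    # no H3K4me3 anywhere -> promoter-unassignable
    other_fraction: float = 0.05
    prc2_rate_high: float = 0.8         # sensitivity rate at K27me3-marked promoters
    prc2_rate_low: float = 0.2          # ... elsewhere (4-fold planted enrichment)

    # accessibility
    atac_peaks_per_gene_distal: int = 3
    dar_prob_deg_promoter: float = 0.8  # DEG promoter peak becomes sign-matched DAR
    dar_prob_nondeg_promoter: float = 0.0
    dar_distal_fraction: float = 0.005
    dar_lfc: float = 2.0

    # count model
    dispersion: float = 0.05
    mu_log_mean: float = float(np.log(100.0))
    mu_log_sd: float = 1.0
    spike_dispersion: float = 0.002     # spike-ins carry technical noise only
    spike_log_mean: float = float(np.log(2000.0))
    spike_log_sd: float = 0.5
    distortion_range: tuple = (0.5, 2.0)

    # chromatin geometry / signal levels (bp, arbitrary signal units)
    track_bin: int = 50
    k4_halfwidth: int = 400
    k27ac_halfwidth: int = 400
    broad_halfwidth: int = 2500         # broad domain >= 5 kb
    focal_halfwidth: int = 400          # focal peak <= 1 kb
    k4_level: float = 6.0
    k27ac_level: float = 4.0
    broad_level: float = 3.0
    focal_level: float = 8.0
    promoter_jitter: int = 1000         # K4 peak center offset from TSS
    atac_promoter_halfwidth: int = 250

    ligand_fraction: float = 0.05

    def __post_init__(self) -> None:
        for name in (
            "deg_fraction", "switch_fraction", "stable_bivalent_fraction",
            "repressed_fraction", "other_fraction", "prc2_rate_high",
            "prc2_rate_low", "dar_prob_deg_promoter", "dar_prob_nondeg_promoter",
            "dar_distal_fraction", "ligand_fraction",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise DesignError(f"{name} must be in [0, 1], got {v}")
        if self.replicates < 2:
            raise DesignError("replicates must be >= 2")
        if self.dispersion <= 0 or self.spike_dispersion <= 0:
            raise DesignError("dispersion must be > 0")

    def capacity(self) -> int:
        return sum(
            max(0, int(size) // self.gene_spacing - 1)
            for size in self.chrom_sizes.values()
        )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["distortion_range"] = list(self.distortion_range)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CohortDesign":
        d = dict(d)
        if "distortion_range" in d:
            d["distortion_range"] = tuple(d["distortion_range"])
        return cls(**d)


@dataclass
class Cohort:
    """Paths of a generated bundle plus convenience loaders."""

    outdir: str
    design: CohortDesign

    def path(self, *parts: str) -> str:
        return os.path.join(self.outdir, *parts)

    def genes(self) -> list[GeneModel]:
        df = pd.read_csv(self.path("genes.tsv"), sep="\t")
        return [
            GeneModel(
                r.gene_id, r.chrom, r.strand, int(r.tss), int(r.length),
                bool(r.is_secreted_ligand),
            )
            for r in df.itertuples()
        ]

    def truth_genes(self) -> pd.DataFrame:
        return pd.read_csv(self.path("truth_genes.tsv"), sep="\t", index_col=0)

    def truth_peaks(self) -> pd.DataFrame:
        return pd.read_csv(self.path("truth_peaks.tsv"), sep="\t", index_col=0)

    def rna_counts(self):
        from .io import read_count_matrix

        return read_count_matrix(
            self.path("rna_counts.tsv"),
            self.path("rna_meta.tsv"),
            self.path("spikeins.txt"),
        )

    def atac_counts(self):
        from .io import read_count_matrix

        return read_count_matrix(self.path("atac_counts.tsv"), self.path("atac_meta.tsv"))


def _rng(seed: int, stream: str) -> np.random.Generator:
    """Named substream: independent generator derived from the root seed."""
    ss = np.random.SeedSequence([seed & 0x7FFFFFFF, abs(hash_stream(stream))])
    return np.random.default_rng(ss)


def hash_stream(name: str) -> int:
    # stable (non-salted) string hash for substream derivation
    h = 2166136261
    for ch in name.encode():
        h = ((h ^ ch) * 16777619) & 0xFFFFFFFF
    return h


def nb_counts(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative binomial sampling via the gamma-Poisson mixture."""
    mean = np.asarray(mean, dtype=float)
    lam = rng.gamma(shape=1.0 / dispersion, scale=mean * dispersion)
    return rng.poisson(lam)


def simplify_states(raw_labels, mapping: dict | None = None) -> list[str]:
    """Map raw chromatin-state labels onto {Active, Bivalent, Repressed, Other}.

    Raises a validation error listing every unmapped label.
    """
    mapping = DEFAULT_STATE_MAP if mapping is None else mapping
    unmapped = sorted({lb for lb in raw_labels if lb not in mapping})
    if unmapped:
        raise DesignError(f"unmapped state label(s): {unmapped}")
    bad = sorted({v for v in mapping.values() if v not in ("Active", "Bivalent", "Repressed", "Other")})
    if bad:
        raise DesignError(f"mapping targets outside the state vocabulary: {bad}")
    return [mapping[lb] for lb in raw_labels]


def _exact_flags(rng: np.random.Generator, n: int, fraction: float) -> np.ndarray:
    """Boolean vector with an exact round(fraction*n) True count, shuffled."""
    k = int(round(fraction * n))
    flags = np.zeros(n, dtype=bool)
    flags[:k] = True
    rng.shuffle(flags)
    return flags


def _aligned_span(center: int, halfwidth: int, bin_width: int) -> tuple[int, int]:
    start = max(0, (center - halfwidth) // bin_width * bin_width)
    end = -((-(center + halfwidth)) // bin_width) * bin_width
    return start, end


def generate_cohort(design: CohortDesign, outdir: str) -> Cohort:
    """Generate the full on-disk bundle; deterministic given the design seed."""
    cap = design.capacity()
    if cap < design.n_genes:
        raise DesignError(
            f"genome too small: capacity {cap} genes at {design.gene_spacing} bp "
            f"spacing, requested {design.n_genes}"
        )
    os.makedirs(outdir, exist_ok=True)
    for sub in ("peaks", "chip", "tracks", "states"):
        os.makedirs(os.path.join(outdir, sub), exist_ok=True)

    # ---- genome layout ------------------------------------------------
    rng_g = _rng(design.seed, "genome")
    chroms, tss_pos = [], []
    for chrom in sorted(design.chrom_sizes):
        n_here = max(0, int(design.chrom_sizes[chrom]) // design.gene_spacing - 1)
        for i in range(n_here):
            if len(chroms) >= design.n_genes:
                break
            chroms.append(chrom)
            tss_pos.append(design.gene_spacing * (i + 1))
    n = design.n_genes
    gene_ids = [f"gene{i:05d}" for i in range(n)]
    strands = np.where(np.arange(n) % 2 == 0, "+", "-")
    lengths = rng_g.integers(500, 5001, size=n)
    ligand = _exact_flags(rng_g, n, design.ligand_fraction)

    genes_df = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "chrom": chroms,
            "strand": strands,
            "tss": tss_pos,
            "length": lengths,
            "is_secreted_ligand": ligand,
        }
    )
    genes_df.to_csv(os.path.join(outdir, "genes.tsv"), sep="\t", index=False)
    genes_df.loc[ligand, ["gene_id"]].to_csv(
        os.path.join(outdir, "ligands.tsv"), sep="\t", index=False
    )

    # ---- planted truth: states, archetypes, DE, PRC2 ------------------
    rng_t = _rng(design.seed, "truth")

    # promoter-unassignable classes first (no H3K4me3 anywhere)
    class_lbl = np.array(["stable-active"] * n, dtype=object)
    order = rng_t.permutation(n)
    n_repressed = int(round(design.repressed_fraction * n))
    n_other = int(round(design.other_fraction * n))
    class_lbl[order[:n_repressed]] = "repressed"
    class_lbl[order[n_repressed : n_repressed + n_other]] = "other"
    assignable = ~np.isin(class_lbl, ("repressed", "other"))
    idx_assign = np.flatnonzero(assignable)
    perm = rng_t.permutation(len(idx_assign))
    n_switch = int(round(design.switch_fraction * len(idx_assign)))
    n_biv = int(round(design.stable_bivalent_fraction * len(idx_assign)))
    class_lbl[idx_assign[perm[:n_switch]]] = "switch"
    class_lbl[idx_assign[perm[n_switch : n_switch + n_biv]]] = "stable-bivalent"

    state_int = np.empty(n, dtype=object)
    state_st = np.empty(n, dtype=object)
    for i, lbl in enumerate(class_lbl):
        if lbl == "switch":
            state_int[i], state_st[i] = "Bivalent", "Active"
        elif lbl == "stable-bivalent":
            state_int[i] = state_st[i] = "Bivalent"
        elif lbl == "repressed":
            state_int[i] = state_st[i] = "Repressed"
        elif lbl == "other":
            state_int[i] = state_st[i] = "Other"
        else:
            state_int[i] = state_st[i] = "Active"

    def archetype(states: np.ndarray) -> np.ndarray:
        marked = np.isin(states, ("Bivalent", "Repressed"))
        shapes = np.where(rng_t.random(n) < 0.5, "broad-K27me3", "focal-high-K27me3")
        return np.where(marked, shapes, "low-K27me3")

    arch_int = archetype(state_int)
    arch_st = archetype(state_st)

    # tissue DEGs: exact count, half up in each tissue, independent of state
    deg_flags = _exact_flags(rng_t, n, design.deg_fraction)
    signs = np.zeros(n, dtype=int)
    deg_idx = np.flatnonzero(deg_flags)
    half = len(deg_idx) // 2
    deg_perm = rng_t.permutation(deg_idx)
    signs[deg_perm[:half]] = 1          # Int-up
    signs[deg_perm[half:]] = -1         # St-up

    # PRC2 sensitivity per organ: enriched 4-fold under K27me3-marked promoters
    def prc2_flags(states: np.ndarray) -> np.ndarray:
        marked = np.isin(states, ("Bivalent", "Repressed"))
        rate = np.where(marked, design.prc2_rate_high, design.prc2_rate_low)
        return rng_t.random(n) < rate

    prc2_int = prc2_flags(state_int)
    prc2_st = prc2_flags(state_st)
    interaction_truth = prc2_int != prc2_st  # |true estimate| = derepression_lfc

    # ---- chromatin peaks, tracks, state BEDs ---------------------------
    rng_tr = _rng(design.seed, "tracks")
    jitter = rng_tr.integers(-design.promoter_jitter, design.promoter_jitter + 1, size=n)
    prom_center = np.asarray(tss_pos) + jitter  # K4 peak midpoint when present

    k4_peaks = {t: [] for t in TISSUES}
    k27me3_peaks = {t: [] for t in TISSUES}
    k27ac_peaks = {t: [] for t in TISSUES}
    track_rows = {(m, t): [] for m in ("k4", "k27me3", "k27ac") for t in TISSUES}
    state_rows = {t: [] for t in TISSUES}

    def add_peak(dst, chrom, center, hw, level, mark, tissue):
        s, e = _aligned_span(center, hw, design.track_bin)
        dst.append(GenomicInterval(chrom, s, e, score=level))
        track_rows[(mark, tissue)].append((chrom, s, e, level))

    for i in range(n):
        chrom, c = chroms[i], int(prom_center[i])
        for tissue, states, arch in (("Int", state_int, arch_int), ("St", state_st, arch_st)):
            st = states[i]
            if st in ("Active", "Bivalent"):
                add_peak(k4_peaks[tissue], chrom, c, design.k4_halfwidth,
                         design.k4_level, "k4", tissue)
            if st == "Active":
                add_peak(k27ac_peaks[tissue], chrom, c, design.k27ac_halfwidth,
                         design.k27ac_level, "k27ac", tissue)
            if st in ("Bivalent", "Repressed"):
                if arch[i] == "broad-K27me3":
                    hw, lvl = design.broad_halfwidth, design.broad_level
                else:
                    hw, lvl = design.focal_halfwidth, design.focal_level
                add_peak(k27me3_peaks[tissue], chrom, c, hw, lvl, "k27me3", tissue)
            state_rows[tissue].append(
                GenomicInterval(chrom, max(0, c - 1000), c + 1000, name=st)
            )

    for tissue in TISSUES:
        for mark, peaks in (("k4", k4_peaks), ("k27me3", k27me3_peaks), ("k27ac", k27ac_peaks)):
            write_intervals(
                os.path.join(outdir, "chip", f"{mark}_{tissue}.narrowPeak"),
                sorted(peaks[tissue]),
                "narrowPeak",
            )
    # bedGraph tracks: one fixed-width bin per line, nonzero bins only
    for (mark, tissue), rows in track_rows.items():
        path = os.path.join(outdir, "tracks", f"{mark}_{tissue}.bedgraph")
        with open(path, "w") as fh:
            for chrom, s, e, level in sorted(rows):
                for b in range(s, e, design.track_bin):
                    fh.write(f"{chrom}\t{b}\t{b + design.track_bin}\t{level}\n")
    for tissue in TISSUES:
        write_intervals(
            os.path.join(outdir, "states", f"states_{tissue}.bed"),
            sorted(state_rows[tissue], key=lambda iv: (iv.chrom, iv.start)),
            "state-bed",
        )

    # ---- ATAC peaks, truth DARs ---------------------------------------
    rng_a = _rng(design.seed, "atac")
    peak_records = []  # (peak_id, chrom, start, end, gene, kind)
    for i in range(n):
        chrom, t0 = chroms[i], int(tss_pos[i])
        hw = design.atac_promoter_halfwidth
        peak_records.append((chrom, t0 - hw, t0 + hw, gene_ids[i], "promoter"))
        for k in range(design.atac_peaks_per_gene_distal):
            off = 10_000 * (k + 1) + int(rng_a.integers(-1000, 1001))
            peak_records.append(
                (chrom, t0 + off - 250, t0 + off + 250, gene_ids[i], "distal")
            )
    peaks_df = pd.DataFrame(
        peak_records, columns=["chrom", "start", "end", "gene", "kind"]
    ).sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)
    peaks_df["peak_id"] = (
        peaks_df["chrom"] + ":" + peaks_df["start"].astype(str) + "-" + peaks_df["end"].astype(str)
    )

    # DAR planting: sign-matched at DEG promoter peaks, sparse elsewhere
    sign_by_gene = dict(zip(gene_ids, signs))
    dar_sign = np.zeros(len(peaks_df), dtype=int)
    for j, row in enumerate(peaks_df.itertuples()):
        if row.kind == "promoter":
            g_sign = sign_by_gene[row.gene]
            prob = (
                design.dar_prob_deg_promoter if g_sign != 0 else design.dar_prob_nondeg_promoter
            )
            if rng_a.random() < prob:
                dar_sign[j] = g_sign if g_sign != 0 else (1 if rng_a.random() < 0.5 else -1)
        else:
            if rng_a.random() < design.dar_distal_fraction:
                dar_sign[j] = 1 if rng_a.random() < 0.5 else -1
    peaks_df["dar_sign"] = dar_sign

    # per-condition peak sets: random nonempty subsets of the 4 conditions
    conditions = [(t, g) for t in TISSUES for g in GENOTYPES]
    membership = rng_a.random((len(peaks_df), 4)) < 0.9
    empty = ~membership.any(axis=1)
    membership[empty, rng_a.integers(0, 4, size=int(empty.sum()))] = True
    for ci, (tissue, geno) in enumerate(conditions):
        sel = peaks_df[membership[:, ci]]
        write_intervals(
            os.path.join(outdir, "peaks", f"atac_{tissue}_{geno}.narrowPeak"),
            [
                GenomicInterval(r.chrom, r.start, r.end, score=1.0, name=r.peak_id)
                for r in sel.itertuples()
            ],
            "narrowPeak",
        )

    # ---- count matrices ------------------------------------------------
    rng_c = _rng(design.seed, "counts")
    samples = [
        f"{t}_{g}_r{k + 1}" for t in TISSUES for g in GENOTYPES for k in range(design.replicates)
    ]
    meta = pd.DataFrame(
        {
            "sample": samples,
            "tissue": [s.split("_")[0] for s in samples],
            "genotype": [s.split("_")[1] for s in samples],
            "replicate": [int(s.split("_r")[1]) for s in samples],
        }
    ).set_index("sample")

    lo, hi = design.distortion_range
    depth = rng_c.uniform(lo, hi, size=len(samples))

    mu = np.exp(rng_c.normal(design.mu_log_mean, design.mu_log_sd, size=n))
    log2_effect = np.zeros((n, len(samples)))
    for j, s in enumerate(samples):
        tissue, geno = meta.loc[s, "tissue"], meta.loc[s, "genotype"]
        tsign = 1.0 if tissue == "Int" else -1.0
        log2_effect[:, j] += 0.5 * design.deg_lfc * signs * tsign
        if geno == "KO":
            dere = prc2_int if tissue == "Int" else prc2_st
            log2_effect[:, j] += design.derepression_lfc * dere
    gene_mean = mu[:, None] * 2.0**log2_effect * depth[None, :]
    gene_counts = nb_counts(rng_c, gene_mean, design.dispersion)

    spike_ids = [f"spike{i:03d}" for i in range(design.n_spikeins)]
    spike_mu = np.exp(
        rng_c.normal(design.spike_log_mean, design.spike_log_sd, size=design.n_spikeins)
    )
    spike_mean = spike_mu[:, None] * depth[None, :]
    spike_counts = nb_counts(rng_c, spike_mean, design.spike_dispersion)

    rna = pd.DataFrame(
        np.vstack([gene_counts, spike_counts]),
        index=gene_ids + spike_ids,
        columns=samples,
    )
    rna.to_csv(os.path.join(outdir, "rna_counts.tsv"), sep="\t", index_label="feature")
    meta.to_csv(os.path.join(outdir, "rna_meta.tsv"), sep="\t")
    with open(os.path.join(outdir, "spikeins.txt"), "w") as fh:
        fh.write("\n".join(spike_ids) + "\n")

    # ATAC counts over the master peak set (modest depth variation)
    atac_depth = rng_c.uniform(0.8, 1.25, size=len(samples))
    atac_mu = np.exp(rng_c.normal(design.mu_log_mean, design.mu_log_sd, size=len(peaks_df)))
    atac_effect = np.zeros((len(peaks_df), len(samples)))
    dar_sign_arr = peaks_df["dar_sign"].to_numpy()
    for j, s in enumerate(samples):
        tsign = 1.0 if meta.loc[s, "tissue"] == "Int" else -1.0
        atac_effect[:, j] = 0.5 * design.dar_lfc * dar_sign_arr * tsign
    atac_mean = atac_mu[:, None] * 2.0**atac_effect * atac_depth[None, :]
    atac_counts = nb_counts(rng_c, atac_mean, design.dispersion)
    atac = pd.DataFrame(atac_counts, index=peaks_df["peak_id"], columns=samples)
    atac.to_csv(os.path.join(outdir, "atac_counts.tsv"), sep="\t", index_label="feature")
    meta.to_csv(os.path.join(outdir, "atac_meta.tsv"), sep="\t")

    # ---- truth tables ---------------------------------------------------
    true_sf = depth / np.exp(np.mean(np.log(depth)))
    truth_genes = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "class": class_lbl,
            "tissue_de_sign": signs,          # +1 Int-up, -1 St-up, 0 null
            "true_lfc_int_vs_st": design.deg_lfc * signs,
            "prc2_sensitive_int": prc2_int,
            "prc2_sensitive_st": prc2_st,
            "interaction": interaction_truth,
            "archetype_int": arch_int,
            "archetype_st": arch_st,
            "state_int": state_int,
            "state_st": state_st,
            "switch": [f"{a}->{b}" for a, b in zip(state_int, state_st)],
            "promoter_assignable": assignable,
            "promoter_center": prom_center,
        }
    ).set_index("gene_id")
    truth_genes.to_csv(os.path.join(outdir, "truth_genes.tsv"), sep="\t")
    truth_peaks = peaks_df.set_index("peak_id")[["chrom", "start", "end", "gene", "kind", "dar_sign"]]
    truth_peaks["true_lfc_int_vs_st"] = design.dar_lfc * truth_peaks["dar_sign"]
    truth_peaks.to_csv(os.path.join(outdir, "truth_peaks.tsv"), sep="\t")
    pd.DataFrame({"sample": samples, "true_size_factor": true_sf}).set_index("sample").to_csv(
        os.path.join(outdir, "truth_size_factors.tsv"), sep="\t"
    )
    with open(os.path.join(outdir, "design.json"), "w") as fh:
        json.dump(design.to_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")

    return Cohort(outdir, design)
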