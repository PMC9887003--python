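"""Generate a synthetic two-tissue (Int/St), two-genotype (WT/KO) cohort.

Builds a small in-silico bundle — gene models, histone-mark peaks and
tracks, chromatin-state BEDs, ATAC peaks, RNA/ATAC count matrices with
spike-ins — together with the planted-truth table that downstream examples
check against.
"""

from nichestate import CohortDesign, generate_cohort

design = CohortDesign(
    n_genes=500,
    n_spikeins=30,
    chrom_sizes={"chr1": 26_000_000, "chr2": 26_000_000},
    seed=42,
)
cohort = generate_cohort(design, "example_cohort")

truth = cohort.truth_genes()
print(f"bundle written to {cohort.outdir}")
print(f"genes: {len(truth)}  ({(truth.tissue_de_sign != 0).sum()} planted tissue DEGs)")
print("promoter classes:")
print(truth["class"].value_counts().to_string())
# Each class maps to a chromatin configuration: "switch" genes are bivalent
# (H3K4me3+H3K27me3) in the intestine and active (H3K4me3+H3K27ac) in the
# stomach; "repressed"/"other" genes lack H3K4me3 and will have no
# approximable promoter downstream.
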