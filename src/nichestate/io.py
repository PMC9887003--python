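"""Tabular I/O: count matrices with metadata, gene models, signal tracks."""

from __future__ import annotations

import pandas as pd

from .de import CountMatrix, DEError
from .intervals import GeneModel, SignalTrack, read_intervals

__all__ = [
    "read_count_matrix",
    "read_genes",
    "read_signal_track",
    "read_ligand_list",
]


def read_count_matrix(
    counts_path, meta_path, spikein_path=None
) -> CountMatrix:
    """Load a counts TSV (feature id column + sample columns) with metadata.

    ``spikein_path``, if given, lists spike-in feature ids one per line.
    """
    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    meta = pd.read_csv(meta_path, sep="\t", index_col=0)
    required = {"tissue", "genotype", "replicate"}
    missing = required - set(meta.columns)
    if missing:
        raise DEError(f"sample metadata missing column(s): {sorted(missing)}")
    if meta[list(required)].isna().any().any():
        raise DEError("incomplete sample metadata")
    spike = pd.Series(False, index=counts.index)
    if spikein_path is not None:
        with open(spikein_path) as fh:
            ids = [line.strip() for line in fh if line.strip()]
        spike.loc[spike.index.intersection(ids)] = True
    if (counts.to_numpy() != counts.to_numpy().astype(int)).any():
        raise DEError("counts must be integers")
    return CountMatrix(counts.astype(int), meta, spike)


def read_genes(path) -> list[GeneModel]:
    """Read a gene-model TSV (gene_id, chrom, strand, tss, length[, ligand])."""
    df = pd.read_csv(path, sep="\t")
    ligcol = "is_secreted_ligand" if "is_secreted_ligand" in df.columns else None
    return [
        GeneModel(
            str(r.gene_id),
            str(r.chrom),
            str(r.strand),
            int(r.tss),
            int(r.length),
            bool(getattr(r, ligcol)) if ligcol else False,
        )
        for r in df.itertuples()
    ]


def read_ligand_list(path) -> list[str]:
    df = pd.read_csv(path, sep="\t")
    return [str(g) for g in df["gene_id"]]


def read_signal_track(path, bin_width: int = 50) -> SignalTrack:
    """Load a bedGraph whose lines are single bins on a fixed grid."""
    track = SignalTrack(bin_width)
    for iv in read_intervals(path, "bedGraph"):
        for b in range(iv.start, iv.end, bin_width):
            track.add(iv.chrom, b, iv.score or 0.0)
    return track
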