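"""Reading and writing paired multiome datasets.

On-disk layout (all plain text) mirrors the common CellRanger-style export:
sparse Matrix Market counts plus TSV/BED annotation sidecars.

    atac.mtx        cells x peaks (or peaks x cells; orientation inferred)
    peaks.bed       BED3 peak intervals
    rna.mtx         cells x genes
    genes.tsv       BED6-like gene table (or a GTF with gene records)
    barcodes.tsv    one barcode per line
"""

from __future__ import annotations

import os
import re

import numpy as np
import pandas as pd
import scipy.io as sio
import scipy.sparse as sp

from ._types import GENE_COLUMNS, MultiomeDataset

__all__ = [
    "read_peaks_bed",
    "read_genes_bed",
    "read_genes_gtf",
    "load_dataset",
    "save_dataset",
    "load_dataset_dir",
]

_GTF_ATTR = re.compile(r'(\w+) "([^"]*)"')


def read_peaks_bed(path) -> pd.DataFrame:
    """Read BED3+ peak intervals (0-based half-open)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df = df.iloc[:, :3]
    df.columns = ["chrom", "start", "end"]
    df["chrom"] = df["chrom"].astype(str)
    return df


def read_genes_bed(path) -> pd.DataFrame:
    """Read a BED6 gene table: chrom, start, end, gene_id, score/symbol, strand."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] < 6:
        raise ValueError("gene BED must have 6 columns (chrom start end name symbol strand)")
    df = df.iloc[:, :6]
    df.columns = ["chrom", "start", "end", "gene_id", "symbol", "strand"]
    df["symbol"] = df["symbol"].replace(".", np.nan).fillna(df["gene_id"]).astype(str)
    return df[list(GENE_COLUMNS)].astype({"chrom": str})


def read_genes_gtf(path) -> pd.DataFrame:
    """Extract gene records (feature == 'gene') from a GTF file."""
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 9 or parts[2] != "gene":
                continue
            attrs = dict(_GTF_ATTR.findall(parts[8]))
            gid = attrs.get("gene_id")
            if gid is None:
                continue
            rows.append(
                dict(
                    gene_id=gid,
                    symbol=attrs.get("gene_name", gid),
                    chrom=str(parts[0]),
                    # GTF is 1-based closed; convert to 0-based half-open
                    start=int(parts[3]) - 1,
                    end=int(parts[4]),
                    strand=parts[6],
                )
            )
    if not rows:
        raise ValueError(f"no gene records found in {path}")
    return pd.DataFrame(rows, columns=list(GENE_COLUMNS))


def _read_counts(path, n_cells: int) -> sp.csr_matrix:
    """Read an MTX count matrix, transposing to cells-by-features if needed."""
    M = sp.csr_matrix(sio.mmread(path))
    if M.shape[0] == n_cells:
        return M
    if M.shape[1] == n_cells:
        return sp.csr_matrix(M.T)
    raise ValueError(f"matrix {path} has shape {M.shape}; neither axis matches {n_cells} barcodes")


def load_dataset(atac_mtx, peaks_bed, rna_mtx, genes_file, barcodes_tsv) -> MultiomeDataset:
    """Assemble a :class:`MultiomeDataset` from individual files.

    ``genes_file`` may be a BED6 table or a GTF (detected by extension).
    """
    barcodes = pd.read_csv(barcodes_tsv, sep="\t", header=None)[0].astype(str).tolist()
    peaks = read_peaks_bed(peaks_bed)
    if str(genes_file).endswith((".gtf", ".gtf.gz")):
        genes = read_genes_gtf(genes_file)
    else:
        genes = read_genes_bed(genes_file)
    X = _read_counts(atac_mtx, len(barcodes))
    Y = _read_counts(rna_mtx, len(barcodes))
    return MultiomeDataset(X=X, Y=Y, cell_ids=barcodes, peaks=peaks, genes=genes)


def save_dataset(ds: MultiomeDataset, outdir) -> None:
    """Write a dataset as MTX + BED/TSV sidecars (cells-by-features orientation)."""
    os.makedirs(outdir, exist_ok=True)
    sio.mmwrite(os.path.join(outdir, "atac.mtx"), sp.coo_matrix(ds.X))
    sio.mmwrite(os.path.join(outdir, "rna.mtx"), sp.coo_matrix(ds.Y))
    ds.peaks[["chrom", "start", "end"]].to_csv(
        os.path.join(outdir, "peaks.bed"), sep="\t", header=False, index=False
    )
    bed6 = ds.genes[["chrom", "start", "end", "gene_id", "symbol", "strand"]]
    bed6.to_csv(os.path.join(outdir, "genes.tsv"), sep="\t", header=False, index=False)
    pd.Series(ds.cell_ids).to_csv(
        os.path.join(outdir, "barcodes.tsv"), sep="\t", header=False, index=False
    )


def load_dataset_dir(indir) -> MultiomeDataset:
    """Load a dataset previously written by :func:`save_dataset`."""
    genes_tsv = os.path.join(indir, "genes.tsv")
    df = pd.read_csv(genes_tsv, sep="\t", header=None)
    df.columns = ["chrom", "start", "end", "gene_id", "symbol", "strand"]
    genes = df[list(GENE_COLUMNS)].astype({"chrom": str, "symbol": str})
    barcodes = pd.read_csv(os.path.join(indir, "barcodes.tsv"), sep="\t", header=None)[0]
    barcodes = barcodes.astype(str).tolist()
    return MultiomeDataset(
        X=_read_counts(os.path.join(indir, "atac.mtx"), len(barcodes)),
        Y=_read_counts(os.path.join(indir, "rna.mtx"), len(barcodes)),
        cell_ids=barcodes,
        peaks=read_peaks_bed(os.path.join(indir, "peaks.bed")),
        genes=genes,
    )
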