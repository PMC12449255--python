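"""Core containers for paired single-cell multiome data.

A :class:`MultiomeDataset` holds a cell-by-peak ATAC count matrix and a
cell-by-gene RNA count matrix over the *same* cells (matched barcodes), plus
genomic annotations for every feature.  All coordinates are 0-based,
half-open (BED convention).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

__all__ = [
    "GenomicInterval",
    "GeneAnnotation",
    "MultiomeDataset",
    "EmptyDatasetError",
]

PEAK_COLUMNS = ("chrom", "start", "end")
GENE_COLUMNS = ("gene_id", "symbol", "chrom", "start", "end", "strand")


class EmptyDatasetError(ValueError):
    """Raised when a filtering step removes every cell or every feature."""


class GenomicInterval(NamedTuple):
    """Half-open genomic interval [start, end) on one chromosome."""

    chrom: str
    start: int
    end: int


class GeneAnnotation(NamedTuple):
    gene_id: str
    symbol: str
    chrom: str
    start: int
    end: int
    strand: str


def _as_csr_counts(M, name: str) -> sp.csr_matrix:
    M = sp.csr_matrix(M)
    if M.nnz and M.data.min() < 0:
        raise ValueError(f"{name} must hold nonnegative counts")
    return M


@dataclass
class MultiomeDataset:
    """Paired ATAC (cells x peaks) and RNA (cells x genes) count matrices.

    Parameters
    ----------
    X : sparse matrix, cells x peaks
        ATAC fragment/insertion counts.
    Y : sparse matrix, cells x genes
        RNA UMI counts.
    cell_ids : sequence of str
        Barcodes, shared between the two modalities (same order).
    peaks : DataFrame with columns chrom/start/end
    genes : DataFrame with columns gene_id/symbol/chrom/start/end/strand
    """

    X: sp.csr_matrix
    Y: sp.csr_matrix
    cell_ids: list = field(default_factory=list)
    peaks: pd.DataFrame = None
    genes: pd.DataFrame = None

    def __post_init__(self):
        self.X = _as_csr_counts(self.X, "X")
        self.Y = _as_csr_counts(self.Y, "Y")
        self.cell_ids = list(self.cell_ids)
        self.peaks = self.peaks.reset_index(drop=True)
        self.genes = self.genes.reset_index(drop=True)
        self.validate()

    # -- invariants ------------------------------------------------------
    def validate(self) -> None:
        n, p = self.X.shape
        n2, q = self.Y.shape
        if n != n2:
            raise ValueError(f"X has {n} cells but Y has {n2}")
        if len(self.cell_ids) != n:
            raise ValueError("cell_ids length does not match matrices")
        for col in PEAK_COLUMNS:
            if col not in self.peaks.columns:
                raise ValueError(f"peaks table missing column {col!r}")
        for col in GENE_COLUMNS:
            if col not in self.genes.columns:
                raise ValueError(f"genes table missing column {col!r}")
        if len(self.peaks) != p:
            raise ValueError(f"{p} peak columns but {len(self.peaks)} annotations")
        if len(self.genes) != q:
            raise ValueError(f"{q} gene columns but {len(self.genes)} annotations")
        if (self.peaks["start"] >= self.peaks["end"]).any():
            raise ValueError("peak intervals must satisfy start < end")
        if (self.genes["start"] >= self.genes["end"]).any():
            raise ValueError("gene intervals must satisfy start < end")
        if not self.genes["strand"].isin(["+", "-"]).all():
            raise ValueError("gene strand must be '+' or '-'")
        key = list(zip(self.peaks["chrom"], self.peaks["start"], self.peaks["end"]))
        if len(set(key)) != len(key):
            raise ValueError("duplicate peak intervals")
        if self.genes["gene_id"].duplicated().any():
            raise ValueError("duplicate gene ids")

    # -- convenience -----------------------------------------------------
    @property
    def n_cells(self) -> int:
        return self.X.shape[0]

    @property
    def n_peaks(self) -> int:
        return self.X.shape[1]

    @property
    def n_genes(self) -> int:
        return self.Y.shape[1]

    def peak_names(self) -> list:
        return [
            f"{c}:{s}-{e}"
            for c, s, e in zip(self.peaks["chrom"], self.peaks["start"], self.peaks["end"])
        ]

    def peak_intervals(self) -> list:
        return [
            GenomicInterval(c, int(s), int(e))
            for c, s, e in zip(self.peaks["chrom"], self.peaks["start"], self.peaks["end"])
        ]

    def gene_annotations(self) -> list:
        return [GeneAnnotation(*row) for row in self.genes[list(GENE_COLUMNS)].itertuples(index=False)]

    def subset_cells(self, idx: Sequence[int]) -> "MultiomeDataset":
        idx = np.asarray(idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        if idx.size == 0:
            raise EmptyDatasetError("cell filter removed every cell")
        return MultiomeDataset(
            X=self.X[idx],
            Y=self.Y[idx],
            cell_ids=[self.cell_ids[i] for i in idx],
            peaks=self.peaks,
            genes=self.genes,
        )

    def subset_features(self, peak_idx=None, gene_idx=None) -> "MultiomeDataset":
        X, peaks = self.X, self.peaks
        Y, genes = self.Y, self.genes
        if peak_idx is not None:
            peak_idx = np.asarray(peak_idx)
            if peak_idx.dtype == bool:
                peak_idx = np.flatnonzero(peak_idx)
            if peak_idx.size == 0:
                raise EmptyDatasetError("peak filter removed every peak")
            X = X[:, peak_idx]
            peaks = peaks.iloc[peak_idx]
        if gene_idx is not None:
            gene_idx = np.asarray(gene_idx)
            if gene_idx.dtype == bool:
                gene_idx = np.flatnonzero(gene_idx)
            if gene_idx.size == 0:
                raise EmptyDatasetError("gene filter removed every gene")
            Y = Y[:, gene_idx]
            genes = genes.iloc[gene_idx]
        return MultiomeDataset(X=X, Y=Y, cell_ids=self.cell_ids, peaks=peaks, genes=genes)

    def __eq__(self, other) -> bool:
        if not isinstance(other, MultiomeDataset):
            return NotImplemented
        return (
            self.X.shape == other.X.shape
            and self.Y.shape == other.Y.shape
            and (self.X != other.X).nnz == 0
            and (self.Y != other.Y).nnz == 0
            and self.cell_ids == other.cell_ids
            and self.peaks.equals(other.peaks)
            and self.genes.equals(other.genes)
        )
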