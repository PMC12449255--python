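"""Quality control and normalisation of paired multiome counts.

Cells are filtered on total RNA/ATAC counts and mitochondrial fraction;
features are filtered to autosomes, outside blacklist regions, and above
minimum detection rates.  RNA counts are library-size normalised, log1p
transformed, restricted to highly variable genes (HVGs) and z-scaled;
ATAC counts are TF-IDF weighted.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import scipy.sparse as sp

from ._types import EmptyDatasetError, GenomicInterval, MultiomeDataset

__all__ = [
    "QCParams",
    "filter_cells",
    "filter_features",
    "normalize_rna",
    "lognormalize",
    "tfidf_transform",
    "preprocess",
    "ProcessedData",
]

log = logging.getLogger(__name__)

#: chromosomes kept after feature filtering: autosomes, with or without "chr"
STANDARD_AUTOSOMES = frozenset(
    [f"chr{i}" for i in range(1, 23)] + [str(i) for i in range(1, 23)]
)
_EXCLUDED_CHROMS = frozenset(["chrX", "chrY", "chrM", "chrMT", "X", "Y", "M", "MT"])


@dataclass
class QCParams:
    """Thresholds for cell- and feature-level quality control.

    ``None`` count bounds are resolved to the (1st, 99th) percentiles of the
    per-cell totals, the conventional reading of "excessively low or high".
    """

    min_rna_counts: Optional[float] = None
    max_rna_counts: Optional[float] = None
    min_atac_counts: Optional[float] = None
    max_atac_counts: Optional[float] = None
    max_mito_fraction: float = 0.20
    min_cells_peak: int = 5
    min_frac_gene: float = 0.01
    n_hvg: int = 3000
    blacklist: list = field(default_factory=list)
    chrom_whitelist: Optional[frozenset] = None

    def __post_init__(self):
        if not (0.0 <= self.max_mito_fraction <= 1.0):
            raise ValueError("max_mito_fraction must be in [0, 1]")
        for name in ("min_cells_peak", "min_frac_gene", "n_hvg"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")

    def whitelist(self) -> frozenset:
        return self.chrom_whitelist if self.chrom_whitelist is not None else STANDARD_AUTOSOMES


def _resolve_bounds(totals: np.ndarray, lo, hi):
    if lo is None:
        lo = np.percentile(totals, 1)
    if hi is None:
        hi = np.percentile(totals, 99)
    return lo, hi


def filter_cells(
    ds: MultiomeDataset,
    mito_fraction_per_cell: Sequence[float],
    qc: QCParams,
) -> MultiomeDataset:
    """Remove cells with out-of-range counts or high mitochondrial fraction.

    Mitochondrial fractions above ``qc.max_mito_fraction`` (strictly) are
    excluded, as are cells whose RNA or ATAC totals fall outside the
    configured bounds (inclusive).
    """
    mito = np.asarray(mito_fraction_per_cell, dtype=float)
    if mito.shape != (ds.n_cells,):
        raise ValueError(f"mito fractions have shape {mito.shape}, expected ({ds.n_cells},)")
    if mito.size and (mito.min() < 0 or mito.max() > 1):
        raise ValueError("mito fractions must lie in [0, 1]")

    rna_tot = np.asarray(ds.Y.sum(axis=1)).ravel()
    atac_tot = np.asarray(ds.X.sum(axis=1)).ravel()
    rna_lo, rna_hi = _resolve_bounds(rna_tot, qc.min_rna_counts, qc.max_rna_counts)
    atac_lo, atac_hi = _resolve_bounds(atac_tot, qc.min_atac_counts, qc.max_atac_counts)

    keep = (
        (rna_tot >= rna_lo)
        & (rna_tot <= rna_hi)
        & (atac_tot >= atac_lo)
        & (atac_tot <= atac_hi)
        & (mito <= qc.max_mito_fraction)
        # empty cells are unusable downstream whatever the bounds say
        & (rna_tot > 0)
        & (atac_tot > 0)
    )
    n_drop = int((~keep).sum())
    if keep.sum() == 0:
        raise EmptyDatasetError("cell QC removed every cell")
    if n_drop:
        log.info("filter_cells: removed %d / %d cells", n_drop, ds.n_cells)
    return ds.subset_cells(keep)


def _overlaps_blacklist(chrom, start, end, blacklist) -> np.ndarray:
    """Half-open overlap of feature intervals against blacklist intervals."""
    hit = np.zeros(len(chrom), dtype=bool)
    for bl in blacklist:
        b = GenomicInterval(*bl) if not isinstance(bl, GenomicInterval) else bl
        hit |= (chrom == b.chrom) & (start < b.end) & (end > b.start)
    return hit


def filter_features(ds: MultiomeDataset, qc: QCParams) -> MultiomeDataset:
    """Keep autosomal, non-blacklisted features above detection thresholds.

    Peaks must be detected (nonzero) in at least ``qc.min_cells_peak`` cells;
    genes in at least ``qc.min_frac_gene`` of cells.
    """
    wl = qc.whitelist()
    n = ds.n_cells

    def _chrom_ok(table):
        if table["chrom"].isna().any():
            raise ValueError("missing chromosome annotation")
        chrom = table["chrom"].to_numpy(dtype=object)
        ok = np.array([c in wl and c not in _EXCLUDED_CHROMS for c in chrom])
        ok &= ~_overlaps_blacklist(
            np.asarray(chrom),
            table["start"].to_numpy(),
            table["end"].to_numpy(),
            qc.blacklist,
        )
        return ok

    peak_ok = _chrom_ok(ds.peaks)
    gene_ok = _chrom_ok(ds.genes)

    peak_det = np.asarray((ds.X > 0).sum(axis=0)).ravel()
    gene_det = np.asarray((ds.Y > 0).sum(axis=0)).ravel()
    peak_ok &= peak_det >= qc.min_cells_peak
    gene_ok &= gene_det >= qc.min_frac_gene * n

    log.info(
        "filter_features: kept %d / %d peaks, %d / %d genes",
        int(peak_ok.sum()), ds.n_peaks, int(gene_ok.sum()), ds.n_genes,
    )
    return ds.subset_features(peak_idx=peak_ok, gene_idx=gene_ok)


def lognormalize(Y, target_sum: float = 1e4) -> np.ndarray:
    """Library-size normalise to ``target_sum`` counts per cell, then log1p."""
    Y = sp.csr_matrix(Y, dtype=float)
    totals = np.asarray(Y.sum(axis=1)).ravel()
    if np.any(totals == 0):
        raise ValueError("cell with zero total count; run cell QC first")
    Yn = sp.diags(target_sum / totals) @ Y
    Yn.data = np.log1p(Yn.data)
    return np.asarray(Yn.todense())


def normalize_rna(Y, n_hvg: int = 3000):
    """Normalise RNA counts and select highly variable genes.

    Library-size normalisation to 1e4 per cell, log1p, HVG selection by the
    binned normalized-dispersion statistic (Seurat flavour), then per-gene
    z-scaling of the HVG submatrix.

    Returns
    -------
    Y_norm : dense (n_cells, n_hvg) array, z-scaled log-normalised expression
    hvg_index : int array of the selected gene columns, in original order
    """
    import scanpy as sc
    from anndata import AnnData

    Y = sp.csr_matrix(Y)
    n, q = Y.shape
    if q < n_hvg:
        raise ValueError(f"requested {n_hvg} HVGs but only {q} genes present")
    logY = lognormalize(Y)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if n_hvg < q:
            adata = AnnData(logY.copy())
            sc.pp.highly_variable_genes(adata, flavor="seurat")
            disp = np.nan_to_num(
                adata.var["dispersions_norm"].to_numpy(dtype=float), nan=-np.inf
            )
            # exactly n_hvg genes: rank by normalized dispersion, ties by index
            hvg_index = np.sort(np.argsort(-disp, kind="stable")[:n_hvg])
        else:
            hvg_index = np.arange(q)

    sub = logY[:, hvg_index]
    mu = sub.mean(axis=0)
    sd = sub.std(axis=0)
    sd[sd == 0] = 1.0  # constant genes scale to all-zero columns
    Y_norm = (sub - mu) / sd
    return Y_norm, hvg_index


def hvg_dispersion(Y) -> np.ndarray:
    """Normalized dispersion per gene (Seurat flavour), for rank inspection."""
    import scanpy as sc
    from anndata import AnnData

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        adata = AnnData(lognormalize(Y))
        sc.pp.highly_variable_genes(adata, flavor="seurat")
    return adata.var["dispersions_norm"].to_numpy()


def tfidf_transform(X) -> sp.csr_matrix:
    """TF-IDF weight the cell-by-peak matrix.

    TF is the within-cell count fraction; IDF = log(1 + n / (1 + df)) where
    df is the number of cells in which the peak is detected.  Zero entries
    stay zero, so the sparsity pattern is preserved.
    """
    X = sp.csr_matrix(X, dtype=float)
    n = X.shape[0]
    totals = np.asarray(X.sum(axis=1)).ravel()
    if np.any(totals == 0):
        raise ValueError("cell with zero ATAC counts; run cell QC first")
    tf = sp.diags(1.0 / totals) @ X
    df_counts = np.asarray((X > 0).sum(axis=0)).ravel()
    idf = np.log(1.0 + n / (1.0 + df_counts))
    return sp.csr_matrix(tf @ sp.diags(idf))


@dataclass
class ProcessedData:
    """Clean dataset plus the derived matrices downstream stages consume."""

    dataset: MultiomeDataset  # filtered cells/features, genes restricted to HVGs
    Y_norm: np.ndarray        # n x n_hvg z-scaled log-normalised expression
    X_tfidf: sp.csr_matrix    # n x p TF-IDF ATAC matrix
    hvg_index: np.ndarray     # HVG columns relative to the filtered gene table


def preprocess(
    ds: MultiomeDataset,
    qc: Optional[QCParams] = None,
    mito_fraction_per_cell: Optional[Sequence[float]] = None,
) -> ProcessedData:
    """Run the full QC + normalisation chain on a raw paired dataset."""
    qc = qc or QCParams()
    if mito_fraction_per_cell is None:
        mito_fraction_per_cell = np.zeros(ds.n_cells)
    ds = filter_cells(ds, mito_fraction_per_cell, qc)
    ds = filter_features(ds, qc)
    n_hvg = min(qc.n_hvg, ds.n_genes)
    Y_norm, hvg_index = normalize_rna(ds.Y, n_hvg=n_hvg)
    ds = ds.subset_features(gene_idx=hvg_index)
    X_tfidf = tfidf_transform(ds.X)
    return ProcessedData(dataset=ds, Y_norm=Y_norm, X_tfidf=X_tfidf, hvg_index=hvg_index)
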