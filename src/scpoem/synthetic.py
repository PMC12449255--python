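"""Synthetic paired multiome data with planted regulatory structure.

The generator emulates a homogeneous cell population profiled by a paired
scRNA/scATAC assay:

* peaks sit on a regular grid along a small number of synthetic chromosomes
  and are grouped into contiguous *co-accessibility blocks* driven by shared
  per-cell latent factors;
* genes belong to *co-expression modules* with shared latent factors;
* a subset of genes receives *planted cis links*: their expression mean
  depends on the (pre-dropout) accessibility state of one or more peaks
  placed within +/-100 kb of the gene body, among decoy peaks sharing the
  same window.

RNA counts are negative-binomial with Bernoulli dropout; ATAC counts are
Bernoulli open/closed states thinned by dropout and inflated to small
integer counts.  Ground truth (links, blocks, modules) is returned alongside
the dataset so every pipeline stage can be scored.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
import scipy.sparse as sp

from ._types import MultiomeDataset

__all__ = ["SyntheticConfig", "GroundTruth", "generate", "worked_example", "WorkedExample"]


@dataclass
class SyntheticConfig:
    """Study conditions for the synthetic paired dataset.

    Defaults describe a small homogeneous population with clear but noisy
    cis-regulatory signal: 500 cells, 200 peaks in blocks of 10, 40 genes in
    4 modules, 20 genes carrying one planted link each.
    """

    n_cells: int = 500
    n_peaks: int = 200
    n_genes: int = 40
    n_modules: int = 4
    links_per_gene: int = 1
    n_linked_genes: Optional[int] = 20  # None -> every gene is linked
    peak_block_size: int = 10
    n_chroms: int = 2
    peak_spacing: int = 12_000      # bp between peak starts
    peak_width: int = 500
    gene_length: int = 2_000
    max_link_offset: int = 60_000   # |gene start - planted peak| upper bound, bp
    effect_size: float = 2.0        # log-scale boost per planted open peak
    module_strength: float = 0.8    # log-scale loading of the module factor
    block_strength: float = 1.5     # logit-scale loading of the block factor
    base_logit: float = -0.5        # baseline accessibility logit
    base_mean: float = 3.0          # baseline RNA mean per cell
    noise_dispersion: float = 2.0   # NB size parameter (smaller = noisier)
    dropout_atac: float = 0.3
    dropout_rna: float = 0.2
    seed: int = 0

    def __post_init__(self):
        for name in ("n_cells", "n_peaks", "n_genes", "n_modules", "links_per_gene",
                     "peak_block_size", "n_chroms", "peak_spacing", "peak_width",
                     "gene_length"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        for name in ("dropout_atac", "dropout_rna"):
            v = getattr(self, name)
            if not (0.0 <= v < 1.0):
                raise ValueError(f"{name} must be in [0, 1)")
        if self.peak_width >= self.peak_spacing:
            raise ValueError("peak_width must be smaller than peak_spacing")


@dataclass
class GroundTruth:
    """Planted structure: peak->gene links, peak blocks, gene modules."""

    links: list                     # (peak_index, gene_index) pairs
    peak_blocks: list = field(default_factory=list)  # disjoint index arrays
    gene_modules: list = field(default_factory=list)

    def link_set(self) -> set:
        return set(self.links)


def _layout_peaks(cfg: SyntheticConfig) -> pd.DataFrame:
    per_chrom = int(np.ceil(cfg.n_peaks / cfg.n_chroms))
    rows = []
    for i in range(cfg.n_peaks):
        c = i // per_chrom
        k = i % per_chrom
        start = (k + 1) * cfg.peak_spacing
        rows.append((f"chr{c + 1}", start, start + cfg.peak_width))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def generate(cfg: SyntheticConfig | None = None):
    """Draw one synthetic dataset.

    Returns ``(MultiomeDataset, GroundTruth)``.  The same config (same seed)
    always returns an identical dataset.
    """
    cfg = cfg or SyntheticConfig()
    rng = np.random.default_rng(cfg.seed)
    n, p, q = cfg.n_cells, cfg.n_peaks, cfg.n_genes

    peaks = _layout_peaks(cfg)
    chrom_ends = peaks.groupby("chrom")["end"].max().to_dict()

    # disjoint contiguous co-accessibility blocks per chromosome
    blocks = []
    for c in peaks["chrom"].unique():
        idx = np.flatnonzero(peaks["chrom"].to_numpy() == c)
        for s in range(0, len(idx), cfg.peak_block_size):
            blk = idx[s:s + cfg.peak_block_size]
            if len(blk) >= 2:
                blocks.append(blk)
    block_of = np.full(p, -1)
    for b, blk in enumerate(blocks):
        block_of[blk] = b

    # ATAC accessibility: latent block factor per cell drives open state
    f_block = rng.normal(size=(n, len(blocks)))
    logit = np.full((n, p), cfg.base_logit)
    in_block = block_of >= 0
    logit[:, in_block] += cfg.block_strength * f_block[:, block_of[in_block]]
    prob_open = 1.0 / (1.0 + np.exp(-logit))
    open_state = rng.random((n, p)) < prob_open
    atac_counts = open_state * (1 + rng.poisson(0.25, size=(n, p)))
    atac_counts[rng.random((n, p)) < cfg.dropout_atac] = 0

    # gene modules
    modules = [np.arange(q)[m::cfg.n_modules] for m in range(cfg.n_modules)]
    module_of = np.zeros(q, dtype=int)
    for m, mem in enumerate(modules):
        module_of[mem] = m
    f_mod = rng.normal(size=(n, cfg.n_modules))

    # planted links and gene placement
    n_linked = q if cfg.n_linked_genes is None else min(cfg.n_linked_genes, q)
    linked_genes = np.sort(rng.choice(q, size=n_linked, replace=False))
    links = []
    gene_rows = []
    chroms = peaks["chrom"].to_numpy()
    starts = peaks["start"].to_numpy()
    available = rng.permutation(p).tolist()

    def _place_gene(anchor_peak):
        c = chroms[anchor_peak]
        lo = max(0, starts[anchor_peak] - cfg.max_link_offset)
        hi = min(chrom_ends[c] - cfg.gene_length, starts[anchor_peak] + cfg.max_link_offset)
        gstart = int(rng.integers(lo, max(lo + 1, hi)))
        return c, gstart, gstart + cfg.gene_length

    linked_set = set(linked_genes.tolist())
    for j in range(q):
        if j in linked_set:
            anchor = available.pop()
            gene_links = [anchor]
            if cfg.links_per_gene > 1:
                # extra links drawn near the anchor so the window constraint holds
                near = np.flatnonzero(
                    (chroms == chroms[anchor])
                    & (np.abs(starts - starts[anchor]) <= cfg.max_link_offset)
                )
                near = near[near != anchor]
                extra = rng.choice(near, size=min(cfg.links_per_gene - 1, near.size),
                                   replace=False)
                gene_links.extend(int(e) for e in extra)
            if len(gene_links) < cfg.links_per_gene:
                raise ValueError("infeasible geometry: not enough peaks within the link window")
            c, gs, ge = _place_gene(anchor)
            for pk in gene_links:
                links.append((int(pk), j))
        else:
            anchor = int(rng.integers(0, p))
            c, gs, ge = _place_gene(anchor)
        gene_rows.append((f"g{j:04d}", f"G{j:04d}", c, gs, ge,
                          "+" if rng.random() < 0.5 else "-"))
    genes = pd.DataFrame(gene_rows, columns=["gene_id", "symbol", "chrom", "start", "end", "strand"])

    # verify the planted links satisfy the +/-100 kb candidate window
    for pk, j in links:
        g = genes.iloc[j]
        if not (starts[pk] < g["end"] + 100_000 and peaks["end"][pk] > g["start"] - 100_000):
            raise AssertionError("planted link escaped the 100 kb window")

    # RNA expression: module factor + planted accessibility effect
    log_mu = np.log(cfg.base_mean) + cfg.module_strength * f_mod[:, module_of]
    for pk, j in links:
        centred = open_state[:, pk].astype(float) - prob_open[:, pk].mean()
        log_mu[:, j] = log_mu[:, j] + cfg.effect_size * centred / max(1, cfg.links_per_gene)
    mu = np.exp(log_mu)
    r = cfg.noise_dispersion
    rna_counts = rng.negative_binomial(r, r / (r + mu))
    rna_counts[rng.random((n, q)) < cfg.dropout_rna] = 0

    ds = MultiomeDataset(
        X=sp.csr_matrix(atac_counts),
        Y=sp.csr_matrix(rna_counts),
        cell_ids=[f"cell{i:05d}" for i in range(n)],
        peaks=peaks,
        genes=genes,
    )
    truth = GroundTruth(links=links, peak_blocks=blocks, gene_modules=modules)
    return ds, truth


@dataclass
class WorkedExample:
    """Tiny fixed instance with hand-checkable network supports."""

    dataset: MultiomeDataset
    truth: GroundTruth
    Wpp: sp.csr_matrix
    Wgg: sp.csr_matrix
    Wpg_by_method: dict

    @property
    def p(self) -> int:
        return self.dataset.n_peaks

    @property
    def q(self) -> int:
        return self.dataset.n_genes

    def expected_pairs(self, T: int) -> int:
        """Algorithm-1 emission count with no dead rows: T * (p+q) * 5."""
        return T * (self.p + self.q) * 5


def worked_example() -> WorkedExample:
    """A fixed 20-cell x 12-peak x 4-gene instance.

    The attached networks are built by hand so that every transition row is
    live: peaks form three cliques of four, genes form a complete graph, and
    each peak-gene weight is positive exactly when the peak lies in the
    gene's +/-100 kb window (which here covers the whole layout).
    """
    from .networks import candidate_peaks

    cfg = SyntheticConfig(
        n_cells=20, n_peaks=12, n_genes=4, n_modules=2, n_linked_genes=4,
        peak_block_size=4, n_chroms=1, peak_spacing=10_000,
        max_link_offset=30_000, seed=20240101 % (2**31),
    )
    ds, truth = generate(cfg)

    p, q = ds.n_peaks, ds.n_genes
    Wpp = np.zeros((p, p))
    for blk in truth.peak_blocks:
        for a in blk:
            for b in blk:
                if a != b:
                    Wpp[a, b] = 1.0 + 0.1 * ((a + b) % 3)
    Wgg = np.ones((q, q)) - np.eye(q)

    Wpg_by_method = {}
    for scale, method in zip((1.0, 0.5, 2.0), ("lasso", "rf", "xgboost")):
        W = np.zeros((p, q))
        for j, gene in enumerate(ds.genes.itertuples(index=False)):
            cand = candidate_peaks(gene, ds.peaks, window_bp=100_000)
            W[cand, j] = scale * (1.0 + 0.05 * cand)
        Wpg_by_method[method] = sp.csr_matrix(W)

    return WorkedExample(
        dataset=ds,
        truth=truth,
        Wpp=sp.csr_matrix(Wpp),
        Wgg=sp.csr_matrix(Wgg),
        Wpg_by_method=Wpg_by_method,
    )
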