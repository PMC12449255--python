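"""High-level model interface: fit the whole pipeline in one call.

``ScPOEM`` wraps a :class:`~scpoem._types.MultiomeDataset` plus the stage
configurations; ``fit(seed)`` runs QC, joint-network construction, meta-path
walks and embedding training, returning a :class:`ScPOEMResults` that holds
every intermediate product and exposes the distance-based analyses.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
import scipy.sparse as sp

from . import downstream, embedding, metapath, networks, preprocess
from ._types import MultiomeDataset

__all__ = ["ScPOEM", "ScPOEMResults", "differential_regulation_results"]


def _child_seeds(seed: int, n: int) -> list:
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(n)]


class ScPOEM:
    """Co-embedding model for one paired multiome dataset.

    Parameters
    ----------
    data : MultiomeDataset
        Raw paired counts with annotations.
    qc : QCParams, optional
        Cell/feature filtering and HVG settings.
    coaccess : CoAccessParams, optional
        Peak-peak co-accessibility workflow settings.
    peak_gene : PeakGeneParams, optional
        Per-gene regression settings (window, tree sizes, ...).
    train : TrainConfig, optional
        Embedding dimension and SGD hyperparameters.
    T : int
        Meta-path sweeps per node (paths per node per walk generation).
    clip : (float, float)
        Quantile clipping bounds applied to every weight matrix.
    mito_fraction : array, optional
        Per-cell mitochondrial read fraction; zeros when absent.

    Examples
    --------
    >>> from scpoem import synthetic, ScPOEM
    >>> ds, truth = synthetic.generate()
    >>> res = ScPOEM(ds).fit(seed=1)            # doctest: +SKIP
    >>> res.nearest_peaks(res.gene_ids[0], K=5)  # doctest: +SKIP
    """

    def __init__(
        self,
        data: MultiomeDataset,
        *,
        qc: Optional[preprocess.QCParams] = None,
        coaccess: Optional[networks.CoAccessParams] = None,
        peak_gene: Optional[networks.PeakGeneParams] = None,
        train: Optional[embedding.TrainConfig] = None,
        T: int = 5,
        clip: tuple = (0.10, 0.90),
        mito_fraction=None,
    ):
        self.data = data
        self.qc = qc or preprocess.QCParams()
        self.coaccess = coaccess or networks.CoAccessParams()
        self.peak_gene = peak_gene or networks.PeakGeneParams()
        self.train_config = train or embedding.TrainConfig()
        self.T = T
        self.clip = clip
        self.mito_fraction = mito_fraction

    @classmethod
    def from_files(cls, atac_mtx, peaks_bed, rna_mtx, genes_file, barcodes_tsv, **kwargs):
        from .io import load_dataset

        return cls(load_dataset(atac_mtx, peaks_bed, rna_mtx, genes_file, barcodes_tsv), **kwargs)

    def fit(self, seed: int = 0) -> "ScPOEMResults":
        """Run preprocess -> networks -> walks -> embedding with one seed."""
        s_pp, s_lasso, s_rf, s_xgb, s_walk, s_train = _child_seeds(seed, 6)

        proc = preprocess.preprocess(self.data, self.qc, self.mito_fraction)
        ds = proc.dataset

        Wpp = networks.build_peak_peak(ds.X, ds.peaks, self.coaccess, seed=s_pp)
        Wgg = networks.build_gene_gene(proc.Y_norm)
        Wpg = {
            "lasso": networks.build_peak_gene(proc.X_tfidf, proc.Y_norm, ds.genes, ds.peaks,
                                              "lasso", self.peak_gene, seed=s_lasso),
            "rf": networks.build_peak_gene(proc.X_tfidf, proc.Y_norm, ds.genes, ds.peaks,
                                           "rf", self.peak_gene, seed=s_rf),
            "xgboost": networks.build_peak_gene(proc.X_tfidf, proc.Y_norm, ds.genes, ds.peaks,
                                                "xgboost", self.peak_gene, seed=s_xgb),
        }

        ts = metapath.build_transition_set(Wpp, Wgg, Wpg, lo=self.clip[0], hi=self.clip[1])
        walk = metapath.generate_training_pairs(ts, self.T, np.random.default_rng(s_walk))

        n_nodes = ds.n_peaks + ds.n_genes

        def pair_sampler(rng):
            fresh = metapath.generate_training_pairs(ts, self.T, rng)
            return fresh.E_u, fresh.E_v, fresh.E_w

        F, history = embedding.train(
            (walk.E_u, walk.E_v, walk.E_w), n_nodes, self.train_config,
            np.random.default_rng(s_train),
            pair_sampler=pair_sampler if self.train_config.resample_paths else None,
        )
        node_ids = ds.peak_names() + list(ds.genes["gene_id"])
        node_types = np.array(["peak"] * ds.n_peaks + ["gene"] * ds.n_genes)
        emb = embedding.EmbeddingMatrix(F=F, node_ids=node_ids, node_types=node_types,
                                        training_log=history)
        return ScPOEMResults(
            model=self, seed=seed, processed=proc, Wpp=Wpp, Wgg=Wgg, Wpg=Wpg,
            transitions=ts, walk=walk, embedding=emb,
        )


@dataclass
class ScPOEMResults:
    """Everything the fitted pipeline produced."""

    model: ScPOEM
    seed: int
    processed: preprocess.ProcessedData
    Wpp: sp.csr_matrix
    Wgg: sp.csr_matrix
    Wpg: dict
    transitions: metapath.TransitionSet
    walk: metapath.WalkResult
    embedding: embedding.EmbeddingMatrix

    # -- accessors -------------------------------------------------------
    @property
    def dataset(self) -> MultiomeDataset:
        return self.processed.dataset

    @property
    def gene_ids(self) -> list:
        return list(self.dataset.genes["gene_id"])

    @property
    def peak_names(self) -> list:
        return self.dataset.peak_names()

    @property
    def training_log(self) -> pd.DataFrame:
        return pd.DataFrame(self.embedding.training_log, columns=["epoch", "objective"])

    def distance(self, u, v) -> float:
        return embedding.pairwise_distance(self.embedding, u, v)

    def nearest_peaks(self, gene, K: int = 10):
        return embedding.nearest_peaks(self.embedding, gene, K)

    def gene_peak_distances(self, gene) -> pd.Series:
        """Distances from one gene to every peak, as a Series."""
        g = self.embedding.row(gene)
        rows = self.embedding.peak_rows()
        d = np.linalg.norm(self.embedding.F[rows] - g, axis=1)
        return pd.Series(d, index=[self.embedding.node_ids[i] for i in rows])

    def ranking(self, within_bp: Optional[int] = None) -> pd.DataFrame:
        """Ranked peak-gene pairs; optionally only pairs within ``within_bp``
        of the gene body."""
        if within_bp is None:
            return downstream.rank_peak_gene_pairs(self.embedding)
        ds = self.dataset
        peak_rows = self.embedding.peak_rows()
        gene_rows = self.embedding.gene_rows()
        gene_pos = {gene_rows[i]: ds.genes.iloc[i] for i in range(len(gene_rows))}
        peak_pos = {peak_rows[i]: ds.peaks.iloc[i] for i in range(len(peak_rows))}

        def in_window(g, pk):
            gene = gene_pos[g]
            peak = peak_pos[pk]
            return (
                peak["chrom"] == gene["chrom"]
                and peak["start"] < gene["end"] + within_bp
                and peak["end"] > gene["start"] - within_bp
            )

        return downstream.rank_peak_gene_pairs(self.embedding, pair_filter=in_window)

    def cluster_genes(self, n_groups: int, size_min: int = 10, size_max: int = 50,
                      seed: int = 0, assign_rule: str = "knn_union", K: int = 5):
        """Size-bounded gene subgroups with assigned peak sets."""
        F_genes = self.embedding.F[self.embedding.gene_rows()]
        groups = downstream.cluster_genes(F_genes, n_groups, size_min, size_max, seed)
        gene_ids = self.gene_ids
        out = []
        for gid, members in enumerate(groups):
            ids = [gene_ids[m] for m in members]
            peaks = downstream.assign_peaks(self.embedding, ids, rule=assign_rule, K=K)
            out.append(downstream.GeneSubgroup(subgroup_id=gid, gene_ids=ids,
                                               assigned_peak_ids=sorted(peaks)))
        return out

    # -- reporting -------------------------------------------------------
    def summary(self) -> str:
        ds = self.dataset
        log = self.training_log
        lines = [
            "scPOEM co-embedding results",
            "=" * 43,
            f"cells                    {ds.n_cells:>10d}",
            f"peaks (after QC)         {ds.n_peaks:>10d}",
            f"genes (HVGs)             {ds.n_genes:>10d}",
            f"embedding dim            {self.embedding.d:>10d}",
            f"meta-path sweeps T       {self.model.T:>10d}",
            f"training pairs |E|       {self.walk.n_pairs:>10d}",
            f"epochs run               {len(log):>10d}",
            f"final mean objective     {log['objective'].iloc[-1]:>10.4f}",
            f"seed                     {self.seed:>10d}",
        ]
        dead = self.transitions.dead_rows()
        lines.append(
            "dead transition rows     "
            + " ".join(f"{k}:{len(v)}" for k, v in dead.items())
        )
        return "\n".join(lines)

    def save(self, outdir) -> None:
        """Write embedding, ranking and training log as TSV files."""
        import os

        os.makedirs(outdir, exist_ok=True)
        emb = self.embedding
        df = pd.DataFrame(emb.F)
        df.insert(0, "node_type", emb.node_types)
        df.insert(0, "node_id", emb.node_ids)
        df.to_csv(os.path.join(outdir, "embedding.tsv"), sep="\t", index=False)
        self.training_log.to_csv(os.path.join(outdir, "training_log.tsv"),
                                 sep="\t", index=False)
        pd.DataFrame({
            "u": self.walk.E_u, "v": self.walk.E_v, "w": self.walk.E_w,
        }).to_csv(os.path.join(outdir, "training_pairs.tsv"), sep="\t", index=False)


def differential_regulation_results(res_a: ScPOEMResults, res_b: ScPOEMResults,
                                    **kwargs) -> downstream.DifferentialResult:
    """Differential-regulation ranking between two fitted conditions."""
    genes_a = res_a.gene_ids
    set_b = set(res_b.gene_ids)
    shared = [g for g in genes_a if g in set_b]
    ia = [genes_a.index(g) for g in shared]
    genes_b = res_b.gene_ids
    ib = [genes_b.index(g) for g in shared]
    FA = res_a.embedding.F[res_a.embedding.gene_rows()][ia]
    FB = res_b.embedding.F[res_b.embedding.gene_rows()][ib]
    return downstream.differential_regulation(FA, FB, shared, **kwargs)
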