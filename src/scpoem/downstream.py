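"""Biology-facing analyses on the trained co-embedding.

Distances between gene and peak rows are turned into importance scores and
per-gene peak rankings; gene embeddings are clustered into size-bounded
subgroups with assigned peak sets; and two conditions' gene embeddings are
compared by Laplacian manifold alignment to rank differentially regulated
genes.  Generic interval/pair precision-recall and subsample-stability
utilities support evaluation on data with known or external truth.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.stats import spearmanr
from sklearn.cluster import KMeans
from sklearn.neighbors import NearestNeighbors

from .embedding import EmbeddingMatrix

__all__ = [
    "importance_score",
    "rank_peak_gene_pairs",
    "GeneSubgroup",
    "cluster_genes",
    "assign_peaks",
    "DifferentialResult",
    "differential_regulation",
    "overlap_eval",
    "stability_correlations",
    "subsample_stability",
]


def importance_score(distance):
    """Importance of a peak-gene link: exp(-distance), in (0, 1]."""
    d = np.asarray(distance, dtype=float)
    if np.any(d < 0):
        raise ValueError("distances must be nonnegative")
    out = np.exp(-d)
    return float(out) if np.isscalar(distance) or d.ndim == 0 else out


def rank_peak_gene_pairs(emb: EmbeddingMatrix, max_pairs: int | None = None,
                         pair_filter=None) -> pd.DataFrame:
    """Rank all (gene, peak) pairs by ascending embedded distance.

    ``pair_filter(gene_row, peak_row) -> bool`` optionally restricts the
    universe (e.g. to within-window pairs).  Returns a DataFrame with
    gene_id, peak_id, distance, importance and the within-gene rank.
    """
    peak_rows = emb.peak_rows()
    gene_rows = emb.gene_rows()
    records = []
    for g in gene_rows:
        dist = np.linalg.norm(emb.F[peak_rows] - emb.F[g], axis=1)
        for pk, d in zip(peak_rows, dist):
            if pair_filter is not None and not pair_filter(g, pk):
                continue
            records.append((emb.node_ids[g], emb.node_ids[pk], float(d)))
    df = pd.DataFrame(records, columns=["gene_id", "peak_id", "distance"])
    df["importance"] = np.exp(-df["distance"])
    df["rank"] = df.groupby("gene_id")["distance"].rank(method="first").astype(int)
    df = df.sort_values(["gene_id", "rank"], kind="stable").reset_index(drop=True)
    if max_pairs is not None:
        df = df.nsmallest(max_pairs, "distance").reset_index(drop=True)
    return df


@dataclass
class GeneSubgroup:
    subgroup_id: int
    gene_ids: list
    assigned_peak_ids: list


def cluster_genes(F_genes: np.ndarray, n_groups: int, size_min: int = 10,
                  size_max: int = 50, seed: int = 0) -> list:
    """Size-bounded k-means clustering of gene embedding rows.

    K-means centroids are repaired greedily: oversized clusters shed their
    farthest members to the nearest non-full cluster, and undersized
    clusters pull the nearest available genes, until every group size lies
    in [size_min, size_max].
    """
    F = np.asarray(F_genes, dtype=float)
    q = F.shape[0]
    if not (n_groups * size_min <= q <= n_groups * size_max):
        raise ValueError(
            f"{q} genes cannot be split into {n_groups} groups of size "
            f"[{size_min}, {size_max}]"
        )
    km = KMeans(n_clusters=n_groups, random_state=seed, n_init=10)
    labels = km.fit_predict(F)
    centroids = km.cluster_centers_.copy()

    def sizes():
        return np.bincount(labels, minlength=n_groups)

    # shrink oversized clusters
    for c in range(n_groups):
        while sizes()[c] > size_max:
            members = np.flatnonzero(labels == c)
            d_own = np.linalg.norm(F[members] - centroids[c], axis=1)
            victim = members[int(np.argmax(d_own))]
            open_cl = np.flatnonzero(sizes() < size_max)
            open_cl = open_cl[open_cl != c]
            d_new = np.linalg.norm(centroids[open_cl] - F[victim], axis=1)
            labels[victim] = open_cl[int(np.argmin(d_new))]
    # grow undersized clusters
    for c in range(n_groups):
        while sizes()[c] < size_min:
            donors = np.flatnonzero((sizes() > size_min)[labels])
            d = np.linalg.norm(F[donors] - centroids[c], axis=1)
            recruit = donors[int(np.argmin(d))]
            labels[recruit] = c

    groups = []
    for c in range(n_groups):
        groups.append(np.flatnonzero(labels == c))
    assert sum(len(g) for g in groups) == q
    return groups


def assign_peaks(emb: EmbeddingMatrix, gene_ids, rule: str = "knn_union",
                 K: int = 5, radius: float | None = None) -> set:
    """Peak set associated with a gene subgroup.

    ``knn_union`` takes the union of each member gene's K nearest peaks;
    ``radius`` takes peaks within ``radius`` of the subgroup centroid.
    """
    peak_rows = emb.peak_rows()
    if rule == "knn_union":
        from .embedding import nearest_peaks

        out = set()
        for g in gene_ids:
            out.update(pid for pid, _ in nearest_peaks(emb, g, K))
        return out
    if rule == "radius":
        if radius is None:
            raise ValueError("radius rule requires a radius")
        centroid = np.mean([emb.row(g) for g in gene_ids], axis=0)
        dist = np.linalg.norm(emb.F[peak_rows] - centroid, axis=1)
        return {emb.node_ids[r] for r, d in zip(peak_rows, dist) if d <= radius}
    raise ValueError(f"unknown rule {rule!r}")


# ---------------------------------------------------------------------------
# differential regulation via manifold alignment
# ---------------------------------------------------------------------------

@dataclass
class DifferentialResult:
    """Per-gene displacement between two aligned condition embeddings."""

    table: pd.DataFrame  # gene_id, score, rank [, p_value]

    def top(self, n: int = 10) -> pd.DataFrame:
        return self.table.head(n)


def _cosine_knn_graph(F: np.ndarray, k: int) -> sp.csr_matrix:
    """Symmetric KNN graph weighted by nonnegative cosine similarity."""
    n = F.shape[0]
    k = min(k, n - 1)
    nn = NearestNeighbors(n_neighbors=k + 1, metric="cosine").fit(F)
    dist, idx = nn.kneighbors(F)
    rows = np.repeat(np.arange(n), k)
    cols = idx[:, 1:].ravel()
    sims = np.clip(1.0 - dist[:, 1:].ravel(), 0.0, None)
    W = sp.csr_matrix((sims, (rows, cols)), shape=(n, n))
    W = W.maximum(W.T)
    W.setdiag(0)
    W.eliminate_zeros()
    return W


def _align_scores(WA, WB, mu, d_align):
    n = WA.shape[0]
    anchors = sp.eye(n) * mu
    W = sp.bmat([[WA, anchors], [anchors, WB]], format="csr")
    deg = np.asarray(W.sum(axis=1)).ravel()
    if np.any(deg == 0):
        warnings.warn("disconnected joint graph; regularising the Laplacian")
        W = W + sp.eye(2 * n) * 1e-8
        deg = np.asarray(W.sum(axis=1)).ravel()
    L = sp.diags(deg) - W
    n_vec = min(d_align + 2, 2 * n - 1)
    if 2 * n <= 1500:
        vals, vecs = np.linalg.eigh(np.asarray(L.todense()))
    else:
        from scipy.sparse.linalg import eigsh

        vals, vecs = eigsh(L.tocsc(), k=n_vec, sigma=-1e-6, which="LM")
        order = np.argsort(vals)
        vals, vecs = vals[order], vecs[:, order]
    keep = np.flatnonzero(vals > 1e-10)[:d_align]  # drop trivial constant modes
    Z = vecs[:, keep]
    return np.linalg.norm(Z[:n] - Z[n:], axis=1)


def differential_regulation(F_genes_A: np.ndarray, F_genes_B: np.ndarray,
                            shared_genes, d_align: int = 20, n_perm: int = 0,
                            seed: int = 0, k: int = 20,
                            anchor_weight="auto") -> DifferentialResult:
    """Rank genes by cross-condition displacement after manifold alignment.

    Cosine-similarity KNN graphs are built from each condition's gene
    embedding rows and jointly embedded through the unnormalised Laplacian of
    the two graphs anchored gene-to-gene.  The anchor weight defaults to the
    maximum weighted degree of the two graphs, which makes every
    cross-condition-inconsistent eigenmode at least as costly as any
    within-graph mode, so identical conditions yield zero displacement.
    Scores are the Euclidean displacement of each gene between its two
    aligned representations; optional permutation p-values shuffle the
    gene-identity correspondence.
    """
    FA = np.asarray(F_genes_A, dtype=float)
    FB = np.asarray(F_genes_B, dtype=float)
    shared_genes = list(shared_genes)
    n = len(shared_genes)
    if n == 0:
        raise ValueError("no shared genes between conditions")
    if FA.shape[0] != n or FB.shape[0] != n:
        raise ValueError("embedding rows must match shared_genes")

    WA = _cosine_knn_graph(FA, k)
    WB = _cosine_knn_graph(FB, k)
    if anchor_weight == "auto":
        deg = max(
            np.asarray(WA.sum(axis=1)).max(),
            np.asarray(WB.sum(axis=1)).max(),
        )
        mu = float(max(deg, 1.0))
    else:
        mu = float(anchor_weight)

    scores = _align_scores(WA, WB, mu, d_align)
    table = pd.DataFrame({"gene_id": shared_genes, "score": scores})

    if n_perm > 0:
        rng = np.random.default_rng(seed)
        exceed = np.zeros(n)
        for _ in range(n_perm):
            perm = rng.permutation(n)
            WB_perm = WB[perm][:, perm]
            null = _align_scores(WA, WB_perm, mu, d_align)
            exceed += null >= scores
        table["p_value"] = (1.0 + exceed) / (1.0 + n_perm)

    table = table.sort_values("score", ascending=False, kind="stable").reset_index(drop=True)
    table["rank"] = np.arange(1, n + 1)
    return DifferentialResult(table=table)


# ---------------------------------------------------------------------------
# evaluation utilities
# ---------------------------------------------------------------------------

def overlap_eval(ranking: pd.DataFrame, truth_pairs=None, truth_intervals=None,
                 top_fraction: float = 0.1):
    """Precision/recall of the top-ranked peak-gene pairs against a truth set.

    ``truth_pairs`` is an iterable of (gene_id, peak_id); alternatively
    ``truth_intervals`` maps gene_id -> list of (chrom, start, end) and a
    ranked peak counts as positive when its interval overlaps one of the
    gene's truth intervals (half-open).  Peak ids must be "chrom:start-end".
    """
    df = ranking.sort_values("distance", kind="stable")
    n_top = max(1, math.ceil(top_fraction * len(df)))
    top = df.head(n_top)

    if truth_pairs is not None:
        truth = set((g, p) for g, p in truth_pairs)
        if not truth:
            raise ValueError("empty truth set")
        tp = sum((g, p) in truth for g, p in zip(top["gene_id"], top["peak_id"]))
    elif truth_intervals is not None:
        if not truth_intervals:
            raise ValueError("empty truth set")

        def _hit(gene_id, peak_id):
            ivs = truth_intervals.get(gene_id, [])
            chrom, span = peak_id.split(":")
            s, e = (int(x) for x in span.split("-"))
            return any(chrom == c and s < iv_e and e > iv_s for c, iv_s, iv_e in ivs)

        tp = sum(_hit(g, p) for g, p in zip(top["gene_id"], top["peak_id"]))
        truth = {
            (g, iv) for g, ivs in truth_intervals.items() for iv in ivs
        }
    else:
        raise ValueError("provide truth_pairs or truth_intervals")

    precision = tp / n_top
    recall = tp / len(truth)
    return precision, recall, tp


def _gene_peak_distance_matrix(result):
    """(q, p) matrix of embedded gene-to-peak distances from a fit result."""
    emb = result.embedding
    gr, pr = emb.gene_rows(), emb.peak_rows()
    G, P = emb.F[gr], emb.F[pr]
    sq = np.sum(G**2, axis=1)[:, None] + np.sum(P**2, axis=1)[None, :] - 2 * G @ P.T
    return np.sqrt(np.maximum(sq, 0.0)), [emb.node_ids[i] for i in gr], [emb.node_ids[i] for i in pr]


def planted_link_auroc(result, truth_pairs, window_bp: int = 200_000):
    """AUROC of distance-ranking planted vs non-planted window pairs.

    ``truth_pairs`` is a set of (gene_id, peak_name) ground-truth links.  The
    pair universe is every (gene, peak) with the peak within ``window_bp`` of
    the gene body — the evaluation protocol used for peak-gene detection —
    ranked by ascending embedded distance.

    Returns ``(auroc, mean_planted_distance, mean_nonplanted_distance)``.
    """
    from sklearn.metrics import roc_auc_score

    from .networks import candidate_peaks

    ds = result.dataset
    emb = result.embedding
    gene_rows = emb.gene_rows()
    names = ds.peak_names()
    labels, dists = [], []
    for j, gene in enumerate(ds.genes.itertuples(index=False)):
        cand = candidate_peaks(gene, ds.peaks, window_bp)
        g = emb.F[gene_rows[j]]
        for c in cand:
            labels.append((gene.gene_id, names[c]) in truth_pairs)
            dists.append(float(np.linalg.norm(emb.F[c] - g)))
    labels = np.asarray(labels)
    dists = np.asarray(dists)
    if labels.sum() == 0 or labels.all():
        raise ValueError("pair universe must contain both planted and decoy pairs")
    auroc = roc_auc_score(labels, -dists)
    return float(auroc), float(dists[labels].mean()), float(dists[~labels].mean())


def stability_correlations(result_a, result_b, shuffle_peaks: bool = False,
                           seed: int = 0) -> pd.Series:
    """Per-gene Spearman correlation of peak rankings between two fit results.

    Correlates each shared gene's vector of embedded peak distances between
    the two runs, over the peaks retained in both.  With
    ``shuffle_peaks=True`` the peak correspondence is permuted first, giving
    the chance-level (label-shuffled) control for the same pair of runs.
    """
    D0, genes0, peaks0 = _gene_peak_distance_matrix(result_a)
    D1, genes1, peaks1 = _gene_peak_distance_matrix(result_b)
    shared_genes = [g for g in genes0 if g in set(genes1)]
    shared_peaks = [pk for pk in peaks0 if pk in set(peaks1)]
    if not shared_genes or len(shared_peaks) < 3:
        raise RuntimeError("too few shared features between replicates")
    g0 = {g: i for i, g in enumerate(genes0)}
    g1 = {g: i for i, g in enumerate(genes1)}
    p0 = np.array([peaks0.index(pk) for pk in shared_peaks])
    p1 = np.array([peaks1.index(pk) for pk in shared_peaks])
    if shuffle_peaks:
        p1 = p1[np.random.default_rng(seed).permutation(len(p1))]
    corr = {}
    for g in shared_genes:
        rho = spearmanr(D0[g0[g], p0], D1[g1[g], p1]).statistic
        corr[g] = float(rho)
    return pd.Series(corr)


def subsample_stability(ds, model_kwargs=None, fraction: float = 0.9,
                        n_rep: int = 2, seed: int = 0, return_results: bool = False):
    """Per-gene Spearman correlation of peak rankings across cell subsamples.

    Runs the full pipeline on ``n_rep`` random ``fraction`` subsamples of
    cells, then correlates each shared gene's peak-distance ranking between
    the first two replicates, over the peaks retained in both.

    Returns ``(per_gene, median)``; with ``return_results=True`` the fitted
    replicate results are appended so controls can reuse them.
    """
    from .model import ScPOEM

    if not (0.0 < fraction <= 1.0):
        raise ValueError("fraction must be in (0, 1]")
    if n_rep < 2:
        raise ValueError("need at least two replicates")
    rng = np.random.default_rng(seed)
    n = ds.n_cells
    n_keep = max(2, int(round(fraction * n)))
    results = []
    for r in range(n_rep):
        idx = np.sort(rng.choice(n, size=n_keep, replace=False))
        sub = ds.subset_cells(idx)
        try:
            res = ScPOEM(sub, **(model_kwargs or {})).fit(seed=seed + 1 + r)
        except Exception as exc:
            raise RuntimeError(f"pipeline failed in stability replicate {r}") from exc
        results.append(res)

    per_gene = stability_correlations(results[0], results[1])
    if return_results:
        return per_gene, float(per_gene.median()), results
    return per_gene, float(per_gene.median())
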