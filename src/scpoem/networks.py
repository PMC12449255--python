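"""Construction of the joint heterogeneous peak-gene network.

Three edge sets are built from the preprocessed matrices:

* ``Wpp`` — peak-peak co-accessibility via the Cicero-style workflow:
  binarise, embed cells, aggregate k-nearest-neighbour metacells, then fit a
  graphical Lasso per overlapping genomic window and average the absolute
  partial correlations.
* ``Wgg`` — gene-gene association by principal-component regression: each
  gene is regressed on the leading principal components of all other genes,
  and the back-projected coefficients form the (thresholded) edge weights.
* ``Wpg`` — peak-gene weights from per-gene regressions of expression on the
  TF-IDF accessibility of peaks within +/-100 kb of the gene body, under
  three regressors (Lasso, random forest, XGBoost).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from sklearn.covariance import graphical_lasso
from sklearn.ensemble import RandomForestRegressor
from sklearn.linear_model import LassoCV
from sklearn.neighbors import NearestNeighbors

__all__ = [
    "CoAccessParams",
    "PeakGeneParams",
    "PCRegressionResult",
    "build_peak_peak",
    "pc_regress_gene",
    "build_gene_gene",
    "candidate_peaks",
    "build_peak_gene",
]

log = logging.getLogger(__name__)

PEAK_GENE_METHODS = ("lasso", "rf", "xgboost")


@dataclass
class CoAccessParams:
    """Knobs of the peak-peak co-accessibility workflow.

    ``knn_k`` is the metacell neighbourhood size.  Aggregation trades
    per-cell binary noise for effective sample size: at the default
    ``knn_k=1`` cells are used directly (appropriate for matrices with
    detection rates above a few percent, where overlapping-neighbourhood
    smoothing only autocorrelates the samples); for very sparse real
    scATAC matrices set it to ~50, Cicero's choice.
    """

    n_embed_dims: int = 10
    knn_k: int = 1
    glasso_penalty: float = 0.05
    window_bp: int = 500_000
    binarize: bool = True
    embed_method: str = "umap"  # "umap" (default) or "svd"

    def __post_init__(self):
        for name in ("n_embed_dims", "knn_k", "glasso_penalty", "window_bp"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class PeakGeneParams:
    """Per-gene regression settings shared by the three peak-gene methods."""

    window_bp: int = 100_000
    anchor: str = "body"  # "body": window around the gene body; "tss": around the TSS
    lasso_cv: int = 5
    n_estimators: int = 100
    max_depth: int = 6


@dataclass
class PCRegressionResult:
    """Principal-component regression of one gene on all others.

    ``U`` holds the scores of the leading components of the remaining genes,
    ``V_j`` the orthonormal loadings, ``alpha_hat`` the OLS coefficients on
    the scores and ``beta_hat = V_j @ alpha_hat`` the back-projected
    per-gene effects.
    """

    U: np.ndarray
    V_j: np.ndarray
    alpha_hat: np.ndarray
    beta_hat: np.ndarray


# ---------------------------------------------------------------------------
# peak-peak co-accessibility
# ---------------------------------------------------------------------------

def _embed_cells(B: sp.csr_matrix, params: CoAccessParams, seed: int) -> np.ndarray:
    if params.embed_method == "svd":
        from sklearn.utils.extmath import randomized_svd

        U, s, _ = randomized_svd(B.astype(float), n_components=params.n_embed_dims,
                                 random_state=seed)
        return U * s
    import umap

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        reducer = umap.UMAP(
            n_components=params.n_embed_dims,
            metric="cosine",
            random_state=seed,
        )
        return reducer.fit_transform(B)


def _metacell_profiles(B: sp.csr_matrix, emb: np.ndarray, k: int) -> np.ndarray:
    """Sum each cell's k-nearest-neighbour binary profiles into a metacell."""
    n = B.shape[0]
    k = min(k, n)
    nn = NearestNeighbors(n_neighbors=k).fit(emb)
    _, idx = nn.kneighbors(emb)
    A = sp.lil_matrix((n, n))
    for i, nbrs in enumerate(idx):
        A[i, nbrs] = 1.0
    return np.asarray((sp.csr_matrix(A) @ B).todense())


def _window_partial_corr(M: np.ndarray, alpha: float) -> np.ndarray:
    """Absolute partial correlations from a graphical-Lasso precision matrix."""
    sd = M.std(axis=0)
    corr = np.corrcoef(M, rowvar=False)
    corr = np.nan_to_num(corr, nan=0.0)
    np.fill_diagonal(corr, 1.0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # tolerate small residual dual gaps
        try:
            _, prec = graphical_lasso(corr, alpha=alpha, max_iter=200)
        except Exception:  # singular / non-converged: ridge-stabilise
            log.info("graphical lasso failed; retrying with ridge-stabilised covariance")
            corr = corr + 1e-3 * np.eye(corr.shape[0])
            _, prec = graphical_lasso(corr, alpha=alpha, max_iter=200)
    d = np.sqrt(np.outer(np.diag(prec), np.diag(prec)))
    pc = np.abs(-prec / d)
    np.fill_diagonal(pc, 0.0)
    pc[sd == 0, :] = 0.0  # constant peaks carry no co-accessibility signal
    pc[:, sd == 0] = 0.0
    return pc


def build_peak_peak(X, peaks, params: CoAccessParams | None = None, seed: int = 0) -> sp.csr_matrix:
    """Peak-peak co-accessibility matrix (symmetric, nonnegative, zero diagonal).

    Windows of ``window_bp`` tile each chromosome with 50% overlap; peaks are
    assigned to windows by midpoint, and per-window absolute partial
    correlations are averaged wherever windows overlap.  Cross-chromosome
    entries are exactly zero.
    """
    params = params or CoAccessParams()
    X = sp.csr_matrix(X)
    p = X.shape[1]
    B = X.copy()
    if params.binarize:
        B.data = np.ones_like(B.data)

    if params.knn_k <= 1:
        # aggregation disabled: metacells are the cells themselves, so the
        # low-dimensional cell embedding is not needed
        M = np.asarray(B.todense(), dtype=float)
    else:
        emb = _embed_cells(B, params, seed)
        M = _metacell_profiles(B, emb, params.knn_k)

    mid = ((peaks["start"].to_numpy() + peaks["end"].to_numpy()) // 2).astype(np.int64)
    chrom = peaks["chrom"].to_numpy()

    acc = sp.lil_matrix((p, p))
    cnt = sp.lil_matrix((p, p))
    step = params.window_bp // 2
    for c in np.unique(chrom):
        on_c = np.flatnonzero(chrom == c)
        if on_c.size < 2:
            continue
        lo, hi = mid[on_c].min(), mid[on_c].max()
        starts = np.arange(lo - step, hi + 1, step)
        for w0 in starts:
            members = on_c[(mid[on_c] >= w0) & (mid[on_c] < w0 + params.window_bp)]
            if members.size < 2:
                continue
            pc = _window_partial_corr(M[:, members], params.glasso_penalty)
            ix = np.ix_(members, members)
            acc[ix] = acc[ix] + pc
            cnt[ix] = cnt[ix] + (np.ones_like(pc) - np.eye(len(members)))
    acc = sp.csr_matrix(acc)
    cnt = sp.csr_matrix(cnt)
    cnt.data = 1.0 / cnt.data
    W = acc.multiply(cnt)
    W = W.maximum(W.T)  # numerically symmetrise
    W.setdiag(0)
    W.eliminate_zeros()
    return sp.csr_matrix(np.abs(W))


# ---------------------------------------------------------------------------
# gene-gene PC regression
# ---------------------------------------------------------------------------

def pc_regress_gene(Y_hvg: np.ndarray, j: int, K: int = 5) -> PCRegressionResult:
    """Regress gene ``j`` on the leading principal components of the others.

    Uses K' = min(K, q-1, n-1) components.  ``Y_hvg`` is globally
    column-centred before the PCA of the leave-one-out matrix.
    """
    Y = np.asarray(Y_hvg, dtype=float)
    n, q = Y.shape
    if q < 2:
        raise ValueError("need at least two genes")
    Yc = Y - Y.mean(axis=0)
    Y_mj = np.delete(Yc, j, axis=1)
    Kp = min(K, q - 1, n - 1)

    if min(Y_mj.shape) <= 400:
        _, s, Vt = np.linalg.svd(Y_mj, full_matrices=False)
    else:
        from sklearn.utils.extmath import randomized_svd

        _, s, Vt = randomized_svd(Y_mj, n_components=Kp, random_state=0)
    # drop numerically-null directions so the score covariance stays invertible
    Kp = min(Kp, int((s > s[0] * 1e-9).sum())) if s.size else 0
    if Kp == 0:
        raise np.linalg.LinAlgError(f"rank-zero predictor matrix for gene index {j}")
    V = Vt[:Kp].T
    U = Y_mj @ V
    G = U.T @ U
    if np.linalg.cond(G) > 1e12:
        raise np.linalg.LinAlgError(f"singular score covariance for gene index {j}")
    alpha = np.linalg.solve(G, U.T @ Y[:, j])
    beta = V @ alpha
    return PCRegressionResult(U=U, V_j=V, alpha_hat=alpha, beta_hat=beta)


def build_gene_gene(Y_hvg: np.ndarray, K: int = 5, percentile: float = 95.0,
                    nonzero_only: bool = False) -> sp.csr_matrix:
    """Gene-gene association graph from per-gene PC regressions.

    Column ``j`` holds ``|beta_hat_j|``; the matrix is symmetrised by the
    elementwise maximum and only entries strictly above the ``percentile``-th
    percentile of all off-diagonal values (symmetric copies included, zeros
    included unless ``nonzero_only``) are kept.
    """
    Y = np.asarray(Y_hvg, dtype=float)
    q = Y.shape[1]
    W = np.zeros((q, q))
    for j in range(q):
        try:
            res = pc_regress_gene(Y, j, K=K)
        except np.linalg.LinAlgError as exc:
            raise np.linalg.LinAlgError(f"gene-gene network failed at gene {j}: {exc}") from exc
        col = np.insert(res.beta_hat, j, 0.0)
        W[:, j] = col
    W = np.abs(W)
    W = np.maximum(W, W.T)
    off = W[~np.eye(q, dtype=bool)]
    if nonzero_only:
        off = off[off > 0]
    # "higher" keeps the retained fraction at or below (100 - percentile)%
    thr = np.quantile(off, percentile / 100.0, method="higher") if off.size else 0.0
    W[W <= thr] = 0.0
    np.fill_diagonal(W, 0.0)
    return sp.csr_matrix(W)


# ---------------------------------------------------------------------------
# peak-gene regressions
# ---------------------------------------------------------------------------

def candidate_peaks(gene, peaks, window_bp: int = 100_000, anchor: str = "body") -> np.ndarray:
    """Indices of peaks overlapping the gene window (half-open test).

    The window is [gene.start - window_bp, gene.end + window_bp) around the
    gene body, or around the strand-aware TSS when ``anchor == "tss"``.
    """
    if anchor == "tss":
        tss = gene.start if gene.strand == "+" else gene.end - 1
        lo, hi = tss - window_bp, tss + 1 + window_bp
    else:
        lo, hi = gene.start - window_bp, gene.end + window_bp
    chrom = peaks["chrom"].to_numpy()
    start = peaks["start"].to_numpy()
    end = peaks["end"].to_numpy()
    mask = (chrom == gene.chrom) & (start < hi) & (end > lo)
    return np.flatnonzero(mask)


def _xgb_gain_importances(model, n_features: int) -> np.ndarray:
    scores = model.get_booster().get_score(importance_type="gain")
    out = np.zeros(n_features)
    for key, val in scores.items():
        out[int(key[1:])] = val
    return out


def _fit_one_gene(method: str, Xc: np.ndarray, y: np.ndarray, hyper: PeakGeneParams,
                  seed: int) -> np.ndarray:
    if method == "lasso":
        mu, sd = Xc.mean(axis=0), Xc.std(axis=0)
        sd[sd == 0] = 1.0
        Z = (Xc - mu) / sd
        model = LassoCV(cv=hyper.lasso_cv, alphas=30, max_iter=5000, random_state=seed)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model.fit(Z, y)
        return np.abs(model.coef_)
    if method == "rf":
        model = RandomForestRegressor(
            n_estimators=hyper.n_estimators, max_depth=hyper.max_depth,
            random_state=seed, n_jobs=1,
        )
        model.fit(Xc, y)
        return model.feature_importances_
    if method == "xgboost":
        from xgboost import XGBRegressor

        model = XGBRegressor(
            n_estimators=hyper.n_estimators, max_depth=hyper.max_depth,
            random_state=seed, n_jobs=1, tree_method="hist", verbosity=0,
        )
        model.fit(Xc, y)
        return _xgb_gain_importances(model, Xc.shape[1])
    raise ValueError(f"unknown peak-gene method {method!r}; expected one of {PEAK_GENE_METHODS}")


def build_peak_gene(X_tfidf, Y_hvg, genes, peaks, method: str,
                    hyper: PeakGeneParams | None = None, seed: int = 0) -> sp.csr_matrix:
    """Peak-gene weight matrix (p x q) under one regression method.

    For each gene, expression is regressed on the TF-IDF values of its
    candidate window peaks; the per-peak score (|coefficient| or importance)
    fills the gene's column.  Genes without candidate peaks, or whose
    regression fails, get an all-zero column.
    """
    if method not in PEAK_GENE_METHODS:
        raise ValueError(f"unknown peak-gene method {method!r}; expected one of {PEAK_GENE_METHODS}")
    hyper = hyper or PeakGeneParams()
    X_tfidf = sp.csc_matrix(X_tfidf)
    Y = np.asarray(Y_hvg, dtype=float)
    p = X_tfidf.shape[1]
    gene_rows = list(genes.itertuples(index=False))
    q = len(gene_rows)
    if Y.shape[1] != q:
        raise ValueError("gene table and expression matrix disagree on gene count")

    W = sp.lil_matrix((p, q))
    for j, gene in enumerate(gene_rows):
        cand = candidate_peaks(gene, peaks, window_bp=hyper.window_bp, anchor=hyper.anchor)
        if cand.size == 0:
            continue
        Xc = np.asarray(X_tfidf[:, cand].todense())
        gene_seed = int((seed * 1_000_003 + j) % (2**31 - 1))
        try:
            scores = _fit_one_gene(method, Xc, Y[:, j], hyper, gene_seed)
        except Exception as exc:  # one bad gene must not abort the pipeline
            warnings.warn(f"{method} regression failed for gene {j}: {exc}")
            continue
        nz = scores > 0
        if nz.any():
            W[cand[nz], j] = scores[nz]
    return sp.csr_matrix(W)
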