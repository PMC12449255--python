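"""Skip-gram embedding of the joint peak-gene node set.

All peaks and genes share one embedding table F of shape (p+q, d).  Training
maximises the weighted negative-sampling objective

    O(F) = sum_r w_r [ log sigma(F_vr . F_ur)
                       + sum_{m=1..M} log sigma(-F_crm . F_ur) ]

over the training pairs (u_r, v_r, w_r) emitted by the meta-path walks, with
M uniform negatives per pair, by minibatch stochastic gradient ascent.
Euclidean distance in the trained space ranks candidate peak-gene links.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = [
    "TrainConfig",
    "EmbeddingMatrix",
    "logsigmoid",
    "objective",
    "objective_grad",
    "negative_sample",
    "train",
    "pairwise_distance",
    "nearest_peaks",
]


@dataclass
class TrainConfig:
    d: int = 100
    batch_size: int = 32
    learning_rate: float = 0.1
    max_epochs: int = 100
    M: int = 5                      # negatives per pair
    paths_per_node: int = 5
    init_scale: Optional[float] = None  # default 0.5 / d (word2vec convention)
    lr_decay: str = "linear"        # "linear" (to 0 over max_epochs) or "constant"
    resample_paths: bool = True     # fresh meta-path sample every epoch
    tol: float = 1e-4
    patience: int = 5
    early_stopping: bool = False    # optional plateau stop (tol/patience)

    def __post_init__(self):
        if self.lr_decay not in ("linear", "constant"):
            raise ValueError("lr_decay must be 'linear' or 'constant'")
        for name in ("d", "batch_size", "max_epochs", "M", "paths_per_node"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.init_scale is None:
            self.init_scale = 0.5 / self.d


@dataclass
class EmbeddingMatrix:
    """Trained embedding: one d-dimensional row per peak and per gene."""

    F: np.ndarray
    node_ids: list
    node_types: np.ndarray  # "peak" / "gene" per row
    training_log: list = field(default_factory=list)  # (epoch, mean objective)

    def __post_init__(self):
        self.node_index = {nid: i for i, nid in enumerate(self.node_ids)}
        if len(self.node_index) != len(self.node_ids):
            raise ValueError("node ids must be unique")
        if not np.all(np.isfinite(self.F)):
            raise ValueError("non-finite values in embedding matrix")

    @property
    def d(self) -> int:
        return self.F.shape[1]

    def row(self, node) -> np.ndarray:
        return self.F[self._idx(node)]

    def _idx(self, node) -> int:
        if isinstance(node, (int, np.integer)):
            return int(node)
        try:
            return self.node_index[node]
        except KeyError:
            raise KeyError(f"unknown node id {node!r}") from None

    def peak_rows(self) -> np.ndarray:
        return np.flatnonzero(self.node_types == "peak")

    def gene_rows(self) -> np.ndarray:
        return np.flatnonzero(self.node_types == "gene")


def logsigmoid(x):
    """Numerically stable log(sigma(x))."""
    return -np.logaddexp(0.0, -np.asarray(x, dtype=float))


def _check_ids(n_nodes, *arrays):
    for a in arrays:
        a = np.asarray(a)
        if a.size and (a.min() < 0 or a.max() >= n_nodes):
            raise ValueError("node id outside the embedding table")


def objective(F: np.ndarray, E, negative_draws: np.ndarray) -> float:
    """Evaluate O(F) for fixed negative draws (shape |E| x M)."""
    u, v, w = (np.asarray(E[0]), np.asarray(E[1]), np.asarray(E[2], dtype=float))
    negs = np.asarray(negative_draws)
    _check_ids(F.shape[0], u, v, negs)
    pos = np.einsum("ij,ij->i", F[u], F[v])
    neg = np.einsum("imj,ij->im", F[negs], F[u])
    return float(np.sum(w * (logsigmoid(pos) + logsigmoid(-neg).sum(axis=1))))


def objective_grad(F: np.ndarray, E, negative_draws: np.ndarray) -> np.ndarray:
    """Full-batch gradient of O(F) with fixed negatives (for testing/analysis)."""
    u, v, w = (np.asarray(E[0]), np.asarray(E[1]), np.asarray(E[2], dtype=float))
    negs = np.asarray(negative_draws)
    _check_ids(F.shape[0], u, v, negs)
    G = np.zeros_like(F)
    s_pos = _sigmoid(np.einsum("ij,ij->i", F[u], F[v]))
    c = (w * (1.0 - s_pos))[:, None]
    np.add.at(G, u, c * F[v])
    np.add.at(G, v, c * F[u])
    s_neg = _sigmoid(np.einsum("imj,ij->im", F[negs], F[u]))
    coef = -w[:, None] * s_neg  # |E| x M
    np.add.at(G, u, np.einsum("im,imj->ij", coef, F[negs]))
    M = negs.shape[1]
    flat_negs = negs.ravel()
    flat_coef = np.repeat(coef, 1, axis=0).ravel()[:, None] * np.repeat(F[u], M, axis=0)
    np.add.at(G, flat_negs, flat_coef)
    return G


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-np.clip(x, -500, 500)))


def negative_sample(rng: np.random.Generator, M: int, vocab_size: int, exclude) -> np.ndarray:
    """Draw M uniform node ids with replacement, avoiding ``exclude``."""
    exclude = set(int(e) for e in exclude)
    if vocab_size <= M or vocab_size <= len(exclude):
        raise ValueError("vocabulary too small for negative sampling")
    out = rng.integers(0, vocab_size, size=M)
    bad = np.array([o in exclude for o in out])
    while bad.any():
        out[bad] = rng.integers(0, vocab_size, size=int(bad.sum()))
        bad = np.array([o in exclude for o in out])
    return out


def _batch_negatives(rng, M, vocab_size, u, v):
    """Vectorised uniform negatives excluding each pair's own endpoints."""
    B = len(u)
    negs = rng.integers(0, vocab_size, size=(B, M))
    bad = (negs == u[:, None]) | (negs == v[:, None])
    while bad.any():
        negs[bad] = rng.integers(0, vocab_size, size=int(bad.sum()))
        bad = (negs == u[:, None]) | (negs == v[:, None])
    return negs


def train(E, n_nodes: int, cfg: TrainConfig, rng: np.random.Generator,
          pair_sampler=None):
    """Fit the embedding table by minibatch SGD ascent on O(F).

    Parameters
    ----------
    E : tuple of arrays (u, v, w)
        Directed weighted training pairs over global node ids.
    n_nodes : total number of peaks + genes.
    rng : numpy Generator; drives initialisation, shuffling and negatives.
    pair_sampler : callable rng -> (u, v, w), optional
        When given and ``cfg.resample_paths`` is set, a fresh pair set is
        drawn each epoch (five meta-paths per node per epoch); otherwise the
        static ``E`` is reused.

    Returns
    -------
    F : (n_nodes, d) array
    log : list of (epoch, mean per-pair objective) entries
    """
    u_all, v_all, w_all = (np.asarray(E[0]), np.asarray(E[1]), np.asarray(E[2], dtype=float))
    if len(u_all) == 0:
        raise ValueError("empty training pair set")
    _check_ids(n_nodes, u_all, v_all)

    F = rng.uniform(-cfg.init_scale, cfg.init_scale, size=(n_nodes, cfg.d))
    history = []
    best, stall = -np.inf, 0

    for epoch in range(cfg.max_epochs):
        if pair_sampler is not None and cfg.resample_paths and epoch > 0:
            u_all, v_all, w_all = pair_sampler(rng)
            u_all, v_all = np.asarray(u_all), np.asarray(v_all)
            w_all = np.asarray(w_all, dtype=float)
        R = len(u_all)
        if cfg.lr_decay == "linear":
            lr = cfg.learning_rate * (1.0 - epoch / cfg.max_epochs)
        else:
            lr = cfg.learning_rate
        order = rng.permutation(R)
        total = 0.0
        for s in range(0, R, cfg.batch_size):
            b = order[s:s + cfg.batch_size]
            u, v, w = u_all[b], v_all[b], w_all[b]
            negs = _batch_negatives(rng, cfg.M, n_nodes, u, v)

            Fu, Fv = F[u], F[v]
            pos = np.einsum("ij,ij->i", Fu, Fv)
            s_pos = _sigmoid(pos)
            Fn = F[negs]                                   # B x M x d
            neg = np.einsum("imj,ij->im", Fn, Fu)
            s_neg = _sigmoid(neg)

            total += float(np.sum(w * (logsigmoid(pos) + logsigmoid(-neg).sum(axis=1))))

            c_pos = (w * (1.0 - s_pos))[:, None]
            c_neg = -w[:, None] * s_neg                    # B x M
            g_u = c_pos * Fv + np.einsum("im,imj->ij", c_neg, Fn)
            g_v = c_pos * Fu
            g_n = c_neg[:, :, None] * Fu[:, None, :]       # B x M x d

            np.add.at(F, u, lr * g_u)
            np.add.at(F, v, lr * g_v)
            np.add.at(F, negs.ravel(), lr * g_n.reshape(-1, cfg.d))

        if not np.all(np.isfinite(F)):
            raise FloatingPointError(
                f"embedding diverged at epoch {epoch}; reduce the learning rate"
            )
        mean_obj = total / R
        history.append((epoch, mean_obj))
        if cfg.early_stopping:
            if mean_obj > best + cfg.tol:
                best, stall = mean_obj, 0
            else:
                stall += 1
                if stall >= cfg.patience:
                    break
    return F, history


def pairwise_distance(emb: EmbeddingMatrix, u, v) -> float:
    """Euclidean distance between two node embeddings."""
    return float(np.linalg.norm(emb.row(u) - emb.row(v)))


def nearest_peaks(emb: EmbeddingMatrix, gene, K: int):
    """The K peaks nearest to ``gene``, ascending by distance.

    Ties break by peak row index so the ranking is deterministic.
    """
    g = emb.row(gene)
    rows = emb.peak_rows()
    if K > rows.size:
        raise ValueError(f"K={K} exceeds the {rows.size} peaks available")
    dist = np.linalg.norm(emb.F[rows] - g, axis=1)
    order = np.lexsort((rows, dist))[:K]
    return [(emb.node_ids[rows[i]], float(dist[i])) for i in order]
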