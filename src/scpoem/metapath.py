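"""Transition matrices and meta-path random walks.

The joint network is converted into four row-stochastic transition matrices
(peak->peak, gene->gene, peak->gene, gene->peak).  Walks follow the fixed
length-six scheme P3-P2-P1-G1-G2-G3: from every peak root P1 a gene chain
G1, G2, G3 and a peak chain P2, P3 are sampled, and symmetrically from every
gene root.  Each walk emits five weighted training pairs whose weight decays
as exp(-0.1 k) with the number k of intermediate nodes separating the pair
in the path.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

__all__ = [
    "DeadEndError",
    "TransitionMatrix",
    "TransitionSet",
    "WalkResult",
    "clip_quantiles",
    "row_normalize",
    "ensemble_transition",
    "sample_node",
    "build_transition_set",
    "generate_training_pairs",
]

log = logging.getLogger(__name__)

W_STEP1 = 1.0
W_STEP2 = float(np.exp(-0.1))
W_STEP3 = float(np.exp(-0.2))
PAIR_WEIGHTS = (W_STEP1, W_STEP2, W_STEP3)


class DeadEndError(RuntimeError):
    """Sampling was requested from a node with no outgoing transitions."""


def clip_quantiles(W, lo: float = 0.10, hi: float = 0.90):
    """Winsorise the *nonzero* entries of ``W`` into their [lo, hi] quantiles.

    Quantiles use linear interpolation over the sorted nonzero values; zeros
    are untouched, so the sparsity pattern is preserved.
    """
    W = sp.csr_matrix(W, dtype=float)
    if W.nnz == 0:
        warnings.warn("clip_quantiles: all-zero matrix returned unchanged")
        return W
    if W.data.min() < 0:
        raise ValueError("clip_quantiles expects a nonnegative matrix")
    q_lo, q_hi = np.quantile(W.data, [lo, hi])
    W = W.copy()
    W.data = np.clip(W.data, q_lo, q_hi)
    return W


def row_normalize(W):
    """Divide each nonzero row by its sum; report all-zero rows.

    Returns ``(P, dead_rows)`` where ``P`` is row-stochastic on the live rows
    and ``dead_rows`` is a sorted int array of all-zero row indices.
    """
    W = sp.csr_matrix(W, dtype=float)
    if W.nnz and W.data.min() < 0:
        raise ValueError("row_normalize expects a nonnegative matrix")
    sums = np.asarray(W.sum(axis=1)).ravel()
    dead = np.flatnonzero(sums == 0)
    inv = np.ones_like(sums)
    inv[sums > 0] = 1.0 / sums[sums > 0]
    P = sp.diags(inv) @ W
    return sp.csr_matrix(P), dead


def ensemble_transition(P_lasso, P_rf, P_xgb, dead_sets=None):
    """Average three row-stochastic matrices into one transition matrix.

    A row is dead only if it is dead in all three inputs; rows that were
    dead in a strict subset are renormalised so live rows still sum to one.
    """
    mats = [sp.csr_matrix(P, dtype=float) for P in (P_lasso, P_rf, P_xgb)]
    shape = mats[0].shape
    if any(M.shape != shape for M in mats):
        raise ValueError("ensemble inputs must share one shape")
    P = (mats[0] + mats[1] + mats[2]) / 3.0
    return row_normalize(P)


class TransitionMatrix:
    """Row-stochastic sparse matrix with fast per-row categorical sampling."""

    def __init__(self, P: sp.csr_matrix, dead_rows: np.ndarray):
        self.P = sp.csr_matrix(P)
        self.dead_rows = np.asarray(dead_rows, dtype=int)
        self._dead = set(self.dead_rows.tolist())
        # per-row cumulative probabilities over the CSR data
        self._cum = np.zeros_like(self.P.data)
        indptr = self.P.indptr
        for r in range(self.P.shape[0]):
            s, e = indptr[r], indptr[r + 1]
            if e > s:
                self._cum[s:e] = np.cumsum(self.P.data[s:e])

    @property
    def shape(self):
        return self.P.shape

    def is_dead(self, i: int) -> bool:
        return i in self._dead

    def sample(self, i: int, rng: np.random.Generator) -> int:
        if i in self._dead:
            raise DeadEndError(f"row {i} has no outgoing transitions")
        s, e = self.P.indptr[i], self.P.indptr[i + 1]
        u = rng.random() * self._cum[e - 1]
        k = int(np.searchsorted(self._cum[s:e], u, side="right"))
        k = min(k, e - s - 1)
        return int(self.P.indices[s + k])


def sample_node(i: int, P, rng: np.random.Generator) -> int:
    """Draw the next node j with probability P[i, j]."""
    if not isinstance(P, TransitionMatrix):
        P = TransitionMatrix(*row_normalize(P))
    return P.sample(i, rng)


@dataclass
class TransitionSet:
    """The four walk-guiding matrices; peaks indexed 0..p-1, genes 0..q-1."""

    Ppp: TransitionMatrix
    Pgg: TransitionMatrix
    Ppg: TransitionMatrix
    Pgp: TransitionMatrix

    @property
    def p(self) -> int:
        return self.Ppp.shape[0]

    @property
    def q(self) -> int:
        return self.Pgg.shape[0]

    def dead_rows(self) -> dict:
        return {
            "Ppp": self.Ppp.dead_rows,
            "Pgg": self.Pgg.dead_rows,
            "Ppg": self.Ppg.dead_rows,
            "Pgp": self.Pgp.dead_rows,
        }

    def has_dead_rows(self) -> bool:
        return any(len(v) for v in self.dead_rows().values())


def build_transition_set(Wpp, Wgg, Wpg_by_method: dict, lo: float = 0.10,
                         hi: float = 0.90) -> TransitionSet:
    """Clip each weight matrix and assemble the four transition matrices.

    ``Wpg_by_method`` maps {"lasso", "rf", "xgboost"} to p x q weight
    matrices; the peak->gene and gene->peak transitions average the three
    row-normalised (transposed, for gene->peak) method matrices.
    """
    Wpp_c = clip_quantiles(Wpp, lo, hi)
    Wgg_c = clip_quantiles(Wgg, lo, hi)
    Ppp = TransitionMatrix(*row_normalize(Wpp_c))
    Pgg = TransitionMatrix(*row_normalize(Wgg_c))

    pg, gp = [], []
    for m in ("lasso", "rf", "xgboost"):
        Wc = clip_quantiles(Wpg_by_method[m], lo, hi)
        pg.append(row_normalize(Wc)[0])
        gp.append(row_normalize(Wc.T)[0])
    Ppg = TransitionMatrix(*ensemble_transition(*pg))
    Pgp = TransitionMatrix(*ensemble_transition(*gp))
    return TransitionSet(Ppp=Ppp, Pgg=Pgg, Ppg=Ppg, Pgp=Pgp)


@dataclass
class WalkResult:
    """Sampled meta-paths and the weighted training pairs they emit.

    Node ids are global: peaks are 0..p-1 and genes are p..p+q-1.  Path rows
    are (P3, P2, P1, G1, G2, G3) with -1 marking steps truncated at a dead
    row.  ``E`` is a multiset of directed (u, v, w) pairs stored as parallel
    arrays, u being the walk root.
    """

    Lpeak: np.ndarray  # (T*p, 6) int
    Lgene: np.ndarray  # (T*q, 6) int
    E_u: np.ndarray
    E_v: np.ndarray
    E_w: np.ndarray
    p: int
    q: int

    @property
    def n_pairs(self) -> int:
        return len(self.E_u)


def generate_training_pairs(ts: TransitionSet, T: int, rng: np.random.Generator) -> WalkResult:
    """Run T sweeps of the meta-path walk over every peak and gene root.

    For each peak root P1: G1 ~ Ppg(P1), G2 ~ Pgg(G1), G3 ~ Pgg(G2),
    P2 ~ Ppp(P1), P3 ~ Ppp(P2); pairs (P1,G1,1), (P1,P2,1),
    (P1,G2,e^-0.1), (P1,P3,e^-0.1), (P1,G3,e^-0.2).  Symmetrically for gene
    roots.  Chains stop at dead rows and only realised pairs are emitted.
    """
    if T < 1:
        raise ValueError("T must be at least 1")
    p, q = ts.p, ts.q
    Lpeak, Lgene = [], []
    E_u, E_v, E_w = [], [], []
    n_truncated = 0

    def chain(start: int, first: TransitionMatrix, then: TransitionMatrix):
        """Sample up to three hops: start -> a (first) -> b (then) -> c (then)."""
        out = []
        mats = (first, then, then)
        node = start
        for M in mats:
            if M.is_dead(node):
                break
            node = M.sample(node, rng)
            out.append(node)
        return out

    for _ in range(T):
        for P1 in range(p):
            g_chain = chain(P1, ts.Ppg, ts.Pgg)       # G1, G2, G3 (gene-local ids)
            p_chain = chain(P1, ts.Ppp, ts.Ppp)[:2]   # P2, P3
            if len(g_chain) < 3 or len(p_chain) < 2:
                n_truncated += 1
            row = [-1] * 6
            row[2] = P1
            for i, g in enumerate(g_chain):
                row[3 + i] = p + g
            if len(p_chain) > 0:
                row[1] = p_chain[0]
            if len(p_chain) > 1:
                row[0] = p_chain[1]
            Lpeak.append(row)
            pairs = []
            if len(g_chain) > 0:
                pairs.append((p + g_chain[0], W_STEP1))
            if len(p_chain) > 0:
                pairs.append((p_chain[0], W_STEP1))
            if len(g_chain) > 1:
                pairs.append((p + g_chain[1], W_STEP2))
            if len(p_chain) > 1:
                pairs.append((p_chain[1], W_STEP2))
            if len(g_chain) > 2:
                pairs.append((p + g_chain[2], W_STEP3))
            for v, w in pairs:
                E_u.append(P1)
                E_v.append(v)
                E_w.append(w)

        for G1 in range(q):
            g_chain = chain(G1, ts.Pgg, ts.Pgg)[:2]   # G2, G3
            p_chain = chain(G1, ts.Pgp, ts.Ppp)       # P1, P2, P3
            if len(g_chain) < 2 or len(p_chain) < 3:
                n_truncated += 1
            row = [-1] * 6
            row[3] = p + G1
            for i, pk in enumerate(p_chain):
                row[2 - i] = pk
            if len(g_chain) > 0:
                row[4] = p + g_chain[0]
            if len(g_chain) > 1:
                row[5] = p + g_chain[1]
            Lgene.append(row)
            pairs = []
            if len(p_chain) > 0:
                pairs.append((p_chain[0], W_STEP1))
            if len(g_chain) > 0:
                pairs.append((p + g_chain[0], W_STEP1))
            if len(p_chain) > 1:
                pairs.append((p_chain[1], W_STEP2))
            if len(g_chain) > 1:
                pairs.append((p + g_chain[1], W_STEP2))
            if len(p_chain) > 2:
                pairs.append((p_chain[2], W_STEP3))
            for v, w in pairs:
                E_u.append(p + G1)
                E_v.append(v)
                E_w.append(w)

    if n_truncated:
        log.info("generate_training_pairs: %d of %d walks truncated at dead rows",
                 n_truncated, T * (p + q))
    return WalkResult(
        Lpeak=np.asarray(Lpeak, dtype=np.int64).reshape(-1, 6),
        Lgene=np.asarray(Lgene, dtype=np.int64).reshape(-1, 6),
        E_u=np.asarray(E_u, dtype=np.int64),
        E_v=np.asarray(E_v, dtype=np.int64),
        E_w=np.asarray(E_w, dtype=float),
        p=p,
        q=q,
    )
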