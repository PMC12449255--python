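"""Joint-network construction: co-accessibility, PC regression, peak-gene."""

import itertools
from types import SimpleNamespace

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
from sklearn.metrics import roc_auc_score

from scpoem.networks import (
    CoAccessParams,
    PeakGeneParams,
    build_gene_gene,
    build_peak_gene,
    build_peak_peak,
    candidate_peaks,
    pc_regress_gene,
)


def gene(chrom="chr1", start=50_000, end=52_000, strand="+"):
    return SimpleNamespace(gene_id="g", symbol="G", chrom=chrom, start=start,
                           end=end, strand=strand)


def peak_table(rows):
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


class TestCandidatePeaks:
    def test_far_upstream_peak_excluded(self):
        peaks = peak_table([("chr1", 50_000 - 150_000, 50_000 - 149_500)])
        assert candidate_peaks(gene(), peaks, 100_000).size == 0

    def test_peak_overlapping_gene_body_included(self):
        peaks = peak_table([("chr1", 50_500, 51_000)])
        assert list(candidate_peaks(gene(), peaks, 100_000)) == [0]

    def test_half_open_abutment_excluded(self):
        # peak ends exactly at window start -> no overlap under half-open test
        g = gene(start=200_000, end=202_000)
        peaks = peak_table([("chr1", 99_000, 100_000)])  # window starts at 100_000
        assert candidate_peaks(g, peaks, 100_000).size == 0
        peaks2 = peak_table([("chr1", 99_000, 100_001)])
        assert list(candidate_peaks(g, peaks2, 100_000)) == [0]

    def test_wrong_chromosome_excluded(self):
        peaks = peak_table([("chr2", 50_000, 50_500)])
        assert candidate_peaks(gene(), peaks, 100_000).size == 0


class TestPCRegression:
    def test_beta_matches_dense_oracle(self):
        rng = np.random.default_rng(0)
        Y = rng.normal(size=(20, 8))
        for j in (0, 3, 7):
            res = pc_regress_gene(Y, j, K=5)
            Yc = Y - Y.mean(axis=0)
            Y_mj = np.delete(Yc, j, axis=1)
            _, _, Vt = np.linalg.svd(Y_mj, full_matrices=False)
            V = Vt[:5].T
            U = Y_mj @ V
            beta_oracle = V @ np.linalg.solve(U.T @ U, U.T @ Y[:, j])
            # loadings are sign/rotation-ambiguous; beta is not
            np.testing.assert_allclose(np.abs(res.beta_hat), np.abs(beta_oracle), atol=1e-10)
            np.testing.assert_allclose(res.V_j.T @ res.V_j, np.eye(5), atol=1e-8)
            np.testing.assert_allclose(res.beta_hat, res.V_j @ res.alpha_hat, atol=1e-12)

    def test_exact_linear_combination_has_zero_residual(self):
        rng = np.random.default_rng(1)
        Y = rng.normal(size=(30, 6))
        res0 = pc_regress_gene(Y, 0, K=5)
        # overwrite gene 0 with an exact combination of the top PC scores
        Y2 = Y.copy()
        Y2[:, 0] = res0.U @ np.array([1.0, -2.0, 0.5, 0.0, 3.0])
        res = pc_regress_gene(Y2, 0, K=5)
        resid = Y2[:, 0] - res.U @ res.alpha_hat
        np.testing.assert_allclose(resid, 0, atol=1e-9)

    def test_two_genes_forces_single_component(self):
        rng = np.random.default_rng(2)
        Y = rng.normal(size=(15, 2))
        res = pc_regress_gene(Y, 1, K=5)
        assert res.V_j.shape == (1, 1)
        assert abs(np.linalg.norm(res.V_j) - 1) < 1e-12


class TestGeneGene:
    def test_duplicate_genes_edge_survives_thresholding(self):
        rng = np.random.default_rng(3)
        n = 100
        a = rng.normal(size=n)
        Y = np.column_stack(
            [a, a + 1e-4 * rng.normal(size=n)] + [rng.normal(size=n) for _ in range(6)]
        )
        W = build_gene_gene(Y).toarray()
        assert W[0, 1] > 0
        assert W[0, 1] == W.max()

    def test_symmetric_zero_diagonal(self):
        rng = np.random.default_rng(4)
        W = build_gene_gene(rng.normal(size=(40, 15)))
        A = W.toarray()
        np.testing.assert_array_equal(A, A.T)
        assert np.all(np.diag(A) == 0)

    def test_at_most_five_percent_offdiag_nonzero(self):
        rng = np.random.default_rng(5)
        q = 20
        W = build_gene_gene(rng.normal(size=(60, q))).toarray()
        off = W[~np.eye(q, dtype=bool)]
        assert (off > 0).sum() <= np.ceil(0.05 * (q * q - q))

    def test_planted_modules_dominate_between_module_weights(self):
        # within-module edges should stochastically dominate between-module
        rng = np.random.default_rng(6)
        n, q, m = 500, 50, 5
        f = rng.normal(size=(n, m))
        module = np.arange(q) % m
        Y = 1.2 * f[:, module] + rng.normal(size=(n, q))
        W = build_gene_gene(Y).toarray()
        within, between = [], []
        for i, j in itertools.combinations(range(q), 2):
            (within if module[i] == module[j] else between).append(W[i, j])
        from scipy.stats import mannwhitneyu

        stat = mannwhitneyu(within, between, alternative="greater")
        assert stat.pvalue < 0.01


class TestPeakPeak:
    def test_block_structure_recovered(self, synthetic_default):
        ds, truth = synthetic_default
        W = build_peak_peak(ds.X, ds.peaks, CoAccessParams(), seed=7).toarray()
        blk = -np.ones(ds.n_peaks, dtype=int)
        for b, members in enumerate(truth.peak_blocks):
            blk[members] = b
        chrom = ds.peaks["chrom"].to_numpy()
        labels, scores = [], []
        for i, j in itertools.combinations(range(ds.n_peaks), 2):
            if chrom[i] != chrom[j]:
                continue
            labels.append(blk[i] >= 0 and blk[i] == blk[j])
            scores.append(W[i, j])
        assert roc_auc_score(labels, scores) > 0.9

    def test_symmetric_nonnegative_zero_diagonal(self, small_synthetic):
        ds, _ = small_synthetic
        W = build_peak_peak(ds.X, ds.peaks, CoAccessParams(), seed=8)
        A = W.toarray()
        np.testing.assert_array_equal(A, A.T)
        assert np.all(np.diag(A) == 0)
        assert A.min() >= 0

    def test_cross_chromosome_entries_zero(self, small_synthetic):
        ds, _ = small_synthetic
        W = build_peak_peak(ds.X, ds.peaks, CoAccessParams(), seed=9).toarray()
        chrom = ds.peaks["chrom"].to_numpy()
        cross = chrom[:, None] != chrom[None, :]
        assert np.all(W[cross] == 0)

    def test_identical_profiles_stronger_than_independent(self):
        rng = np.random.default_rng(10)
        n, p = 300, 6
        base = (rng.random((n, 1)) < 0.4).astype(int)
        X = np.column_stack([
            base[:, 0], base[:, 0],                     # identical pair
            *(rng.random((n, p - 2)) < 0.4).astype(int).T,
        ])
        keep = X.sum(axis=1) > 0
        X = X[keep]
        peaks = peak_table([("chr1", 1000 * (i + 1), 1000 * (i + 1) + 200)
                            for i in range(p)])
        W = build_peak_peak(sp.csr_matrix(X), peaks, CoAccessParams(), seed=11).toarray()
        others = [W[i, j] for i, j in itertools.combinations(range(p), 2)
                  if (i, j) != (0, 1)]
        assert W[0, 1] > max(others)


class TestPeakGene:
    @pytest.mark.parametrize("method", ["lasso", "rf", "xgboost"])
    def test_planted_peak_gets_largest_score(self, method):
        rng = np.random.default_rng(12)
        n, p = 300, 31
        X = rng.random((n, p))
        y = 3.0 * X[:, 7] + 0.3 * rng.normal(size=n)
        peaks = peak_table([("chr1", 1000 * (i + 1), 1000 * (i + 1) + 200)
                            for i in range(p)])
        genes = pd.DataFrame([
            {"gene_id": "g0", "symbol": "G0", "chrom": "chr1",
             "start": 15_000, "end": 17_000, "strand": "+"},
        ])
        W = build_peak_gene(sp.csr_matrix(X), y[:, None], genes, peaks, method,
                            seed=13).toarray()
        assert np.argmax(W[:, 0]) == 7

    def test_gene_without_candidates_gets_zero_column(self):
        rng = np.random.default_rng(14)
        X = rng.random((50, 3))
        peaks = peak_table([("chr1", 1000, 1200), ("chr1", 2000, 2200),
                            ("chr1", 3000, 3200)])
        genes = pd.DataFrame([
            {"gene_id": "g0", "symbol": "G0", "chrom": "chr9",
             "start": 1000, "end": 2000, "strand": "+"},
        ])
        W = build_peak_gene(sp.csr_matrix(X), rng.normal(size=(50, 1)), genes,
                            peaks, "rf", seed=15)
        assert W.nnz == 0

    def test_scores_nonnegative_and_support_in_window(self, small_synthetic):
        ds, _ = small_synthetic
        from scpoem.preprocess import preprocess

        proc = preprocess(ds)
        dsf = proc.dataset
        W = build_peak_gene(proc.X_tfidf, proc.Y_norm, dsf.genes, dsf.peaks,
                            "xgboost", seed=16)
        assert W.min() >= 0
        A = W.toarray()
        for j, g in enumerate(dsf.genes.itertuples(index=False)):
            cand = set(candidate_peaks(g, dsf.peaks, 100_000))
            nz = set(np.flatnonzero(A[:, j]))
            assert nz <= cand

    def test_unknown_method_raises(self):
        with pytest.raises(ValueError):
            build_peak_gene(sp.csr_matrix(np.ones((3, 2))), np.ones((3, 1)),
                            pd.DataFrame(), pd.DataFrame(), "svm")
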