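"""Transition matrices and Algorithm-style meta-path walks."""

import numpy as np
import pytest
import scipy.sparse as sp
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import chisquare

from scpoem.metapath import (
    PAIR_WEIGHTS,
    DeadEndError,
    TransitionMatrix,
    build_transition_set,
    clip_quantiles,
    ensemble_transition,
    generate_training_pairs,
    row_normalize,
    sample_node,
)

W1, W2, W3 = PAIR_WEIGHTS


class TestClipQuantiles:
    def test_matches_sort_based_oracle(self):
        vals = np.arange(1.0, 11.0)
        W = sp.random(6, 6, density=0.28, random_state=0)
        W.data = vals[: W.nnz]
        lo, hi = np.quantile(np.sort(W.data), [0.10, 0.90])
        out = clip_quantiles(W, 0.10, 0.90)
        np.testing.assert_allclose(out.data, np.clip(W.tocsr().data, lo, hi))

    def test_equal_nonzeros_unchanged(self):
        W = sp.csr_matrix(np.array([[0.0, 3.0], [3.0, 0.0]]))
        out = clip_quantiles(W)
        np.testing.assert_array_equal(out.toarray(), W.toarray())

    def test_zeros_stay_exactly_zero(self):
        W = sp.csr_matrix(np.array([[0.0, 5.0, 0.0], [1.0, 0.0, 9.0], [0, 0, 0]]))
        out = clip_quantiles(W).toarray()
        assert (out[W.toarray() == 0] == 0).all()

    def test_all_zero_matrix_warns_and_returns(self):
        with pytest.warns(UserWarning):
            out = clip_quantiles(sp.csr_matrix((3, 3)))
        assert out.nnz == 0

    @given(st.floats(min_value=0.01, max_value=1e6))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_clip_then_normalize_scale_invariant(self, c):
        W = sp.csr_matrix(np.array([[0.0, 1.0, 4.0], [2.0, 0.0, 8.0], [1.0, 1.0, 0.0]]))
        P1, _ = row_normalize(clip_quantiles(W))
        P2, _ = row_normalize(clip_quantiles(W * c))
        np.testing.assert_allclose(P1.toarray(), P2.toarray(), atol=1e-12)


class TestRowNormalize:
    def test_simple_example(self):
        P, dead = row_normalize(np.array([[2.0, 2.0], [0.0, 4.0]]))
        np.testing.assert_allclose(P.toarray(), [[0.5, 0.5], [0.0, 1.0]])
        assert dead.size == 0

    def test_dead_row_reported_and_left_zero(self):
        P, dead = row_normalize(np.array([[0.0, 0.0], [1.0, 3.0]]))
        np.testing.assert_allclose(P.toarray(), [[0.0, 0.0], [0.25, 0.75]])
        assert list(dead) == [0]

    def test_stochastic_matrix_unchanged(self):
        M = np.array([[0.3, 0.7], [1.0, 0.0]])
        P, _ = row_normalize(M)
        np.testing.assert_allclose(P.toarray(), M, atol=1e-12)

    def test_negative_entry_rejected(self):
        with pytest.raises(ValueError):
            row_normalize(np.array([[1.0, -0.5]]))


class TestEnsemble:
    def test_identical_inputs_passthrough(self):
        P = sp.csr_matrix(np.array([[0.2, 0.8], [1.0, 0.0]]))
        out, dead = ensemble_transition(P, P, P)
        np.testing.assert_allclose(out.toarray(), P.toarray(), atol=1e-12)
        assert dead.size == 0

    def test_mean_of_one_hot_rows(self):
        A = sp.csr_matrix(np.array([[1.0, 0.0]]))
        B = sp.csr_matrix(np.array([[0.0, 1.0]]))
        out, _ = ensemble_transition(A, B, B)
        np.testing.assert_allclose(out.toarray(), [[1 / 3, 2 / 3]], atol=1e-12)

    def test_partially_dead_row_renormalized(self):
        live = sp.csr_matrix(np.array([[0.25, 0.75]]))
        dead = sp.csr_matrix((1, 2))
        out, dead_rows = ensemble_transition(live, live, dead)
        np.testing.assert_allclose(out.toarray().sum(axis=1), [1.0], atol=1e-12)
        np.testing.assert_allclose(out.toarray(), [[0.25, 0.75]], atol=1e-12)
        assert dead_rows.size == 0

    def test_row_dead_everywhere_stays_dead(self):
        dead = sp.csr_matrix((1, 2))
        out, dead_rows = ensemble_transition(dead, dead, dead)
        assert list(dead_rows) == [0]

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            ensemble_transition(sp.eye(2), sp.eye(2), sp.eye(3))


class TestSampleNode:
    def test_one_hot_row_is_deterministic(self):
        P = TransitionMatrix(*row_normalize(np.array([[0, 0, 0, 1.0], [1.0, 0, 0, 0]])))
        rng = np.random.default_rng(0)
        assert all(sample_node(0, P, rng) == 3 for _ in range(20))

    def test_frequencies_match_row_within_3_sigma(self):
        P = TransitionMatrix(*row_normalize(np.array([[0.2, 0.8]])))
        rng = np.random.default_rng(1)
        n = 10_000
        draws = np.array([P.sample(0, rng) for _ in range(n)])
        phat = (draws == 1).mean()
        sigma = np.sqrt(0.8 * 0.2 / n)
        assert abs(phat - 0.8) < 3 * sigma

    def test_dead_row_raises(self):
        P = TransitionMatrix(*row_normalize(np.array([[0.0, 0.0], [1.0, 0.0]])))
        with pytest.raises(DeadEndError):
            P.sample(0, np.random.default_rng(2))

    def test_first_hop_distribution_chisquare(self):
        rng = np.random.default_rng(3)
        probs = np.array([0.1, 0.2, 0.3, 0.4])
        P = TransitionMatrix(*row_normalize(probs[None, :]))
        n = 10_000
        draws = np.array([P.sample(0, rng) for _ in range(n)])
        counts = np.bincount(draws, minlength=4)
        assert chisquare(counts, probs * n).pvalue > 0.01


class TestWalks:
    def test_emission_count_and_weights_no_dead_rows(self, example):
        ts = build_transition_set(example.Wpp, example.Wgg, example.Wpg_by_method)
        assert not ts.has_dead_rows()
        T = 3
        walk = generate_training_pairs(ts, T, np.random.default_rng(0))
        assert walk.n_pairs == T * (example.p + example.q) * 5
        assert walk.Lpeak.shape == (T * example.p, 6)
        assert walk.Lgene.shape == (T * example.q, 6)
        uniq = np.unique(walk.E_w)
        np.testing.assert_allclose(np.sort(uniq), sorted(PAIR_WEIGHTS), atol=1e-12)

    def test_weight_equals_exp_decay_of_path_separation(self, example):
        """Replay each stored path: w == e^(-0.1 k) for k intermediate nodes."""
        ts = build_transition_set(example.Wpp, example.Wgg, example.Wpg_by_method)
        walk = generate_training_pairs(ts, 2, np.random.default_rng(1))
        p, q, T = example.p, example.q, 2
        # path layout (P3 P2 P1 G1 G2 G3); the far-node column fixes the
        # number k of intermediate nodes, hence the weight e^(-0.1 k)
        r = 0
        for t in range(T):
            for row in walk.Lpeak[t * p:(t + 1) * p]:
                P1 = row[2]
                for col, w_expect in ((3, W1), (1, W1), (4, W2), (0, W2), (5, W3)):
                    if row[col] < 0:
                        continue
                    assert walk.E_u[r] == P1
                    assert walk.E_v[r] == row[col]
                    assert walk.E_w[r] == pytest.approx(w_expect, abs=1e-12)
                    r += 1
            for row in walk.Lgene[t * q:(t + 1) * q]:
                G1 = row[3]
                for col, w_expect in ((2, W1), (4, W1), (1, W2), (5, W2), (0, W3)):
                    if row[col] < 0:
                        continue
                    assert walk.E_u[r] == G1
                    assert walk.E_v[r] == row[col]
                    assert walk.E_w[r] == pytest.approx(w_expect, abs=1e-12)
                    r += 1
        assert r == walk.n_pairs

    def test_fixed_seed_reproducible(self, example):
        ts = build_transition_set(example.Wpp, example.Wgg, example.Wpg_by_method)
        w1 = generate_training_pairs(ts, 2, np.random.default_rng(7))
        w2 = generate_training_pairs(ts, 2, np.random.default_rng(7))
        np.testing.assert_array_equal(w1.E_u, w2.E_u)
        np.testing.assert_array_equal(w1.E_v, w2.E_v)
        np.testing.assert_array_equal(w1.E_w, w2.E_w)
        np.testing.assert_array_equal(w1.Lpeak, w2.Lpeak)

    def test_one_hot_transitions_fully_deterministic(self):
        # ring one-hot transitions: every path is forced
        p = q = 3
        Ppp = np.roll(np.eye(p), 1, axis=1)
        Pgg = np.roll(np.eye(q), 1, axis=1)
        Ppg = np.eye(p)
        ts = build_transition_set(
            sp.csr_matrix(Ppp), sp.csr_matrix(Pgg),
            {m: sp.csr_matrix(Ppg) for m in ("lasso", "rf", "xgboost")},
        )
        a = generate_training_pairs(ts, 1, np.random.default_rng(0))
        b = generate_training_pairs(ts, 1, np.random.default_rng(123))
        np.testing.assert_array_equal(a.E_v, b.E_v)

    def test_dead_rows_truncate_walks(self):
        # gene 1 has no outgoing gene-gene edges: chains through it stop there
        Wpp = sp.csr_matrix(np.array([[0.0, 1.0], [1.0, 0.0]]))
        Wgg = sp.csr_matrix(np.array([[0.0, 1.0], [0.0, 0.0]]))
        Wpg = sp.csr_matrix(np.array([[1.0, 0.0], [0.0, 1.0]]))
        ts = build_transition_set(Wpp, Wgg, {m: Wpg for m in ("lasso", "rf", "xgboost")})
        walk = generate_training_pairs(ts, 4, np.random.default_rng(0))
        # every emitted pair still has a valid node and an allowed weight
        assert (walk.E_v >= 0).all()
        assert walk.n_pairs < 4 * 4 * 5
        for w in walk.E_w:
            assert min(abs(w - x) for x in PAIR_WEIGHTS) < 1e-12

    def test_invalid_T_rejected(self, example):
        ts = build_transition_set(example.Wpp, example.Wgg, example.Wpg_by_method)
        with pytest.raises(ValueError):
            generate_training_pairs(ts, 0, np.random.default_rng(0))
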