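"""Graph attention layer: normalization, equivariance, closed forms, oracle."""

import math

import numpy as np
import pytest

from kgner import GatParams, attention_scores, gat_backward, gat_forward

from conftest import random_adjacency


def scalar_attention_oracle(V, A, W, a, slope):
    """Independent per-element recomputation of the attention softmax."""
    m, d_h = V.shape[0], W.shape[1]
    U = [[sum(V[i][p] * W[p][q] for p in range(V.shape[1])) for q in range(d_h)] for i in range(m)]

    def leaky(x):
        return x if x > 0 else slope * x

    alpha = np.zeros((m, m))
    for i in range(m):
        nbrs = [j for j in range(m) if A[i][j]]
        logits = {}
        for j in nbrs:
            cat = U[i] + U[j]
            logits[j] = leaky(sum(a[t] * cat[t] for t in range(2 * d_h)))
        mx = max(logits.values())
        Z = sum(math.exp(v - mx) for v in logits.values())
        for j in nbrs:
            alpha[i, j] = math.exp(logits[j] - mx) / Z
    return alpha


def make_params(d, d_h, K, seed=0, dropout=0.0):
    return GatParams.init(d=d, d_h=d_h, K=K, seed=seed, dropout=dropout)


class TestAttentionScores:
    def test_self_loop_only_gives_unit_attention(self):
        p = make_params(3, 3, 1)
        V = np.random.default_rng(0).normal(size=(4, 3))
        alpha = attention_scores(V, np.eye(4, dtype=int), p, head=0).alpha
        assert np.allclose(alpha, np.eye(4))

    def test_zero_attention_vector_gives_uniform_scores(self):
        p = make_params(3, 3, 1)
        p.a[:] = 0.0
        rng = np.random.default_rng(1)
        A = random_adjacency(rng, 5)
        alpha = attention_scores(rng.normal(size=(5, 3)), A, p, head=0).alpha
        for i in range(5):
            nbrs = A[i] > 0
            assert np.allclose(alpha[i, nbrs], 1.0 / nbrs.sum())
            assert np.allclose(alpha[i, ~nbrs], 0.0)

    def test_path_graph_matches_scalar_oracle(self):
        """3-node path, hand-set inputs, every defined entry re-derived."""
        d = d_h = 2
        W = np.eye(2)
        a = np.array([1.0, 0.0, 0.0, 0.0])
        p = GatParams(K=1, d=d, d_h=d_h, W=W[None], a=a[None], dropout=0.0)
        V = np.array([[0.5, -1.0], [2.0, 0.3], [-0.7, 0.9]])
        A = np.array([[1, 1, 0], [1, 1, 1], [0, 1, 1]])
        alpha = attention_scores(V, A, p, head=0).alpha
        oracle = scalar_attention_oracle(V, A, W, a, p.leaky_slope)
        assert np.allclose(alpha, oracle, atol=1e-12)

    def test_rows_sum_to_one_over_support(self):
        """Row-stochastic on the neighborhood support, 100 random graphs."""
        rng = np.random.default_rng(42)
        for _ in range(100):
            m = int(rng.integers(1, 8))
            d, d_h, K = 5, 3, 2
            p = GatParams.init(d=d, d_h=d_h, K=K, seed=rng, dropout=0.0)
            A = random_adjacency(rng, m)
            V = rng.normal(size=(m, d))
            for k in range(K):
                alpha = attention_scores(V, A, p, head=k).alpha
                assert np.all(alpha >= 0)
                assert np.allclose(alpha.sum(axis=1), 1.0, atol=1e-6)
                assert np.allclose(alpha[A == 0], 0.0)


class TestGatForward:
    def test_zero_message_reduces_to_leaky_relu_of_input(self):
        """K=1, d_h=d, W=0, identity residual: forward == LeakyReLU(V)."""
        d = 4
        p = make_params(d, d, 1)
        p.W[:] = 0.0
        V = np.random.default_rng(2).normal(size=(3, d))
        H, _ = gat_forward(V, np.eye(3, dtype=int), p)
        expected = np.where(V > 0, V, p.leaky_slope * V)
        assert np.allclose(H, expected)

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(3)
        p = make_params(5, 4, 3)
        m = 6
        A = random_adjacency(rng, m)
        V = rng.normal(size=(m, 5))
        H, _ = gat_forward(V, A, p)
        perm = rng.permutation(m)
        Hp, _ = gat_forward(V[perm], A[np.ix_(perm, perm)], p)
        assert np.allclose(Hp, H[perm], atol=1e-12)

    def test_two_node_clique_matches_elementwise_oracle(self):
        """Hand-set params, every output element recomputed by scalars."""
        d, d_h, K = 2, 2, 2
        rng = np.random.default_rng(4)
        p = GatParams(
            K=K,
            d=d,
            d_h=d_h,
            W=rng.normal(size=(K, d, d_h)),
            a=rng.normal(size=(K, 2 * d_h)),
            dropout=0.0,
        )
        V = rng.normal(size=(2, d))
        A = np.ones((2, 2), dtype=int)
        H, _ = gat_forward(V, A, p)

        def leaky(x):
            return x if x > 0 else p.leaky_slope * x

        for k in range(K):
            alpha = scalar_attention_oracle(V, A, p.W[k], p.a[k], p.leaky_slope)
            for i in range(2):
                msg = [
                    sum(alpha[i, j] * sum(V[j][q] * p.W[k][q][c] for q in range(d)) for j in range(2))
                    for c in range(d_h)
                ]
                for c in range(d_h):
                    expected = leaky(msg[c] + V[i][c])
                    assert abs(H[i, k * d_h + c] - expected) < 1e-9

    def test_output_depends_only_on_first_order_neighborhood(self):
        rng = np.random.default_rng(5)
        p = make_params(4, 4, 2)
        A = np.eye(4, dtype=int)
        A[0, 1] = A[1, 0] = 1  # node 3 is isolated from node 0
        V = rng.normal(size=(4, 4))
        H1, _ = gat_forward(V, A, p)
        V2 = V.copy()
        V2[3] += 10.0
        H2, _ = gat_forward(V2, A, p)
        assert np.allclose(H1[0], H2[0])
        assert not np.allclose(H1[3], H2[3])

    def test_residual_projection_used_when_widths_differ(self):
        p = make_params(6, 3, 2)
        assert p.Wr is not None
        V = np.random.default_rng(6).normal(size=(3, 6))
        H, _ = gat_forward(V, np.eye(3, dtype=int), p)
        assert H.shape == (3, 6)  # K * d_h
        assert np.all(np.isfinite(H))

    def test_shape_mismatch_raises(self):
        p = make_params(4, 4, 1)
        with pytest.raises(ValueError):
            gat_forward(np.zeros((2, 3)), np.eye(2, dtype=int), p)

    def test_dropout_requires_rng_and_changes_training_output(self):
        p = make_params(4, 4, 1, dropout=0.5)
        V = np.random.default_rng(7).normal(size=(3, 4))
        A = np.eye(3, dtype=int)
        with pytest.raises(ValueError):
            gat_forward(V, A, p, training=True)
        H_inf, _ = gat_forward(V, A, p, training=False)
        H_tr, _ = gat_forward(V, A, p, training=True, rng=np.random.default_rng(0))
        assert not np.allclose(H_inf, H_tr)


class TestGatBackward:
    def test_gradients_match_finite_differences(self):
        rng = np.random.default_rng(8)
        p = make_params(4, 3, 2, dropout=0.0)
        m = 5
        A = random_adjacency(rng, m)
        V = rng.normal(size=(m, 4))
        target = rng.normal(size=(m, p.out_width))

        def loss():
            H, _ = gat_forward(V, A, p)
            return 0.5 * float(((H - target) ** 2).sum())

        H, cache = gat_forward(V, A, p)
        dV, grads = gat_backward(H - target, cache)

        eps = 1e-6
        for arr, g in [(V, dV), (p.W, grads["W"]), (p.a, grads["a"]), (p.Wr, grads["Wr"])]:
            flat, gflat = arr.reshape(-1), g.reshape(-1)
            for idx in rng.choice(flat.size, size=min(15, flat.size), replace=False):
                old = flat[idx]
                flat[idx] = old + eps
                lp = loss()
                flat[idx] = old - eps
                lm = loss()
                flat[idx] = old
                num = (lp - lm) / (2 * eps)
                assert abs(num - gflat[idx]) < 1e-5 * max(1.0, abs(num))
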