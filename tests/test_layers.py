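"""Computational blocks: closed forms, scalar-loop oracles, invariants, grads."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import _oracles as orc
from dxpred import autograd as ag
from dxpred.autograd import Tensor
from dxpred import layers as L


def _gru_arrays(p):
    return {k: getattr(p, k).data for k in
            ("W_z", "W_r", "W_h", "U_z", "U_r", "U_h", "b_z", "b_r", "b_h")}


class TestFullyConnected:
    def test_zero_weights_return_bias(self):
        W = Tensor(np.zeros((3, 2)))
        b = Tensor(np.array([1.5, -2.0]))
        out = L.fully_connected(Tensor(np.array([9.0, 9.0, 9.0])), W, b)
        np.testing.assert_array_equal(out.data, [1.5, -2.0])

    def test_identity(self):
        v = np.array([0.3, -0.7, 2.0])
        out = L.fully_connected(Tensor(v), Tensor(np.eye(3)), Tensor(np.zeros(3)))
        np.testing.assert_array_equal(out.data, v)

    def test_random_case_matches_loop_and_shape_mismatch_errors(self):
        rng = np.random.default_rng(0)
        W, b, v = rng.normal(size=(3, 2)), rng.normal(size=2), rng.normal(size=3)
        out = L.fully_connected(Tensor(v), Tensor(W), Tensor(b))
        expected = [b[j] + sum(v[i] * W[i, j] for i in range(3)) for j in range(2)]
        np.testing.assert_allclose(out.data, expected, atol=1e-12)
        with pytest.raises(ValueError, match="mismatch"):
            L.fully_connected(Tensor(np.zeros(4)), Tensor(W), Tensor(b))


class TestGRU:
    def test_all_zero_params_halve_previous_state(self):
        rng = np.random.default_rng(1)
        p = L.init_gru(2, 3, rng)
        for t in p.parameters().values():
            t.data = np.zeros_like(t.data)
        h_prev = np.array([0.4, -0.8, 0.2])
        out = L.gru_step(Tensor(np.ones(2)), Tensor(h_prev), p)
        np.testing.assert_allclose(out.data, 0.5 * h_prev, atol=1e-12)

    def test_state_stays_in_open_unit_cube(self):
        rng = np.random.default_rng(2)
        p = L.init_gru(4, 5, rng)
        h = Tensor(np.zeros((1, 5)))
        for _ in range(30):
            h = L.gru_step(Tensor(rng.normal(size=(1, 4)) * 3), h, p)
            assert np.all(np.abs(h.data) < 1.0)

    def test_step_and_sequence_match_scalar_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            d, g = int(rng.integers(1, 5)), int(rng.integers(1, 5))
            p = L.init_gru(d, g, rng)
            for t in p.parameters().values():
                t.data = rng.normal(size=t.shape)
            vs = [rng.normal(size=d) for _ in range(4)]
            states = L.gru_sequence([Tensor(v) for v in vs], p)
            expected = orc.gru_sequence(vs, _gru_arrays(p), g)
            for s, e in zip(states, expected):
                np.testing.assert_allclose(s.data, e, atol=1e-6)

    def test_empty_sequence_rejected(self):
        p = L.init_gru(2, 2, np.random.default_rng(0))
        with pytest.raises(ValueError):
            L.gru_sequence([], p)


class TestLocationAttention:
    def test_identical_states_give_uniform_weights(self):
        rng = np.random.default_rng(4)
        p = L.init_attention(3, rng)
        h = rng.normal(size=3)
        w, c = L.location_attention([Tensor(h)] * 4, p)
        np.testing.assert_allclose(w.data, 0.25, atol=1e-12)
        np.testing.assert_allclose(c.data, h, atol=1e-12)

    def test_single_state_weight_one(self):
        p = L.init_attention(2, np.random.default_rng(5))
        h = np.array([1.0, -1.0])
        w, c = L.location_attention([Tensor(h)], p)
        assert w.data.shape == (1,) and w.data[0] == pytest.approx(1.0)
        np.testing.assert_allclose(c.data, h)

    def test_matches_scalar_oracle(self):
        rng = np.random.default_rng(6)
        for _ in range(20):
            g = int(rng.integers(1, 6))
            p = L.init_attention(g, rng)
            p.W_alpha.data = rng.normal(size=(g, 1))
            p.b_alpha.data = rng.normal(size=1)
            states = [rng.normal(size=g) for _ in range(3)]
            w, c = L.location_attention([Tensor(s) for s in states], p)
            ew, ec = orc.location_attention(states, p.W_alpha.data[:, 0],
                                            p.b_alpha.data[0])
            np.testing.assert_allclose(w.data, ew, atol=1e-8)
            np.testing.assert_allclose(c.data, ec, atol=1e-8)


class TestGraphAttention:
    def _toy(self, rng, n_leaves=4, n_internal=2, d=3, l=2):
        # leaves 0..3; internal 4 (covers 0,1), 5 = root-like (covers all)
        ancestors = {0: [0, 4, 5], 1: [1, 4, 5], 2: [2, 5], 3: [3, 5]}
        max_a = 3
        idx = np.zeros((n_leaves, max_a), dtype=np.int64)
        mask = np.zeros((n_leaves, max_a), dtype=bool)
        for i, a in ancestors.items():
            idx[i, :len(a)] = a
            mask[i, :len(a)] = True
        anc = L.AncestorIndex([f"n{i}" for i in range(6)], idx, mask)
        emb = Tensor(rng.normal(size=(6, d)), requires_grad=True)
        p = L.init_graph_attention(d, l, rng)
        p.u_a.data = rng.normal(size=(l, 1))
        p.W_a.data = rng.normal(size=(2 * d, l))
        p.b_a.data = rng.normal(size=l)
        return ancestors, anc, emb, p

    def test_singleton_ancestor_set_returns_own_embedding(self):
        rng = np.random.default_rng(7)
        anc = L.AncestorIndex(["a", "b"], np.array([[0], [1]]),
                              np.ones((2, 1), dtype=bool))
        emb = Tensor(rng.normal(size=(2, 3)))
        p = L.init_graph_attention(3, 2, rng)
        g = L.graph_attention_embed(anc, emb, p)
        np.testing.assert_allclose(g.data, emb.data, atol=1e-12)

    def test_zero_ua_gives_uniform_mixture(self):
        rng = np.random.default_rng(8)
        ancestors, anc, emb, p = self._toy(rng)
        p.u_a.data = np.zeros_like(p.u_a.data)
        g = L.graph_attention_embed(anc, emb, p)
        for i, a in ancestors.items():
            np.testing.assert_allclose(g.data[i], emb.data[a].mean(axis=0),
                                       atol=1e-12)

    def test_matches_explicit_loop_oracle(self):
        for seed in range(20):
            rng = np.random.default_rng(100 + seed)
            ancestors, anc, emb, p = self._toy(rng)
            g = L.graph_attention_embed(anc, emb, p)
            expected = orc.graph_attention(ancestors, emb.data,
                                           p.u_a.data[:, 0], p.W_a.data,
                                           p.b_a.data)
            np.testing.assert_allclose(g.data, expected, atol=1e-8)


class TestRetainContext:
    def test_zero_beta_annihilates(self):
        rng = np.random.default_rng(9)
        attn = L.init_attention(3, rng)
        rp = L.init_retain(3, 2, rng)
        rp.W_beta.data = np.zeros_like(rp.W_beta.data)
        rp.b_beta.data = np.zeros_like(rp.b_beta.data)
        ctx = L.retain_context([Tensor(rng.normal(size=2))] * 2,
                               [Tensor(rng.normal(size=3))] * 2,
                               [Tensor(rng.normal(size=3))] * 2, attn, rp)
        np.testing.assert_allclose(ctx.data, 0.0, atol=1e-12)

    def test_saturated_beta_passes_visit_through(self):
        rng = np.random.default_rng(10)
        attn = L.init_attention(2, rng)
        rp = L.init_retain(2, 3, rng)
        rp.W_beta.data = np.zeros_like(rp.W_beta.data)
        rp.b_beta.data = np.full(3, 50.0)  # tanh -> 1
        v = rng.normal(size=3)
        ctx = L.retain_context([Tensor(v)], [Tensor(rng.normal(size=2))],
                               [Tensor(rng.normal(size=2))], attn, rp)
        np.testing.assert_allclose(ctx.data, v, atol=1e-8)

    def test_matches_scalar_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            d, g = int(rng.integers(1, 4)), int(rng.integers(1, 4))
            attn = L.init_attention(g, rng)
            attn.W_alpha.data = rng.normal(size=(g, 1))
            rp = L.init_retain(g, d, rng)
            rp.W_beta.data = rng.normal(size=(g, d))
            rp.b_beta.data = rng.normal(size=d)
            vs = [rng.normal(size=d) for _ in range(2)]
            a_s = [rng.normal(size=g) for _ in range(2)]
            b_s = [rng.normal(size=g) for _ in range(2)]
            ctx = L.retain_context([Tensor(v) for v in vs],
                                   [Tensor(s) for s in a_s],
                                   [Tensor(s) for s in b_s], attn, rp)
            expected = orc.retain_context(vs, a_s, b_s, attn.W_alpha.data[:, 0],
                                          attn.b_alpha.data[0], rp.W_beta.data,
                                          rp.b_beta.data)
            np.testing.assert_allclose(ctx.data, expected, atol=1e-6)

    def test_length_mismatch_rejected(self):
        rng = np.random.default_rng(12)
        with pytest.raises(ValueError, match="equal length"):
            L.retain_context([Tensor(np.zeros(2))], [], [],
                             L.init_attention(2, rng), L.init_retain(2, 2, rng))


class TestVisitEmbedding:
    def test_single_code_and_range(self):
        rng = np.random.default_rng(13)
        E = Tensor(rng.normal(size=(5, 3)) * 4)
        b = Tensor(np.zeros(3))
        x = np.zeros(5)
        x[2] = 1.0
        v = L.visit_embedding(x, E, b)
        np.testing.assert_allclose(v.data, np.tanh(E.data[2]), atol=1e-12)
        assert np.all(np.abs(v.data) < 1.0)

    def test_multi_code_matches_column_sum(self):
        rng = np.random.default_rng(14)
        E, b = Tensor(rng.normal(size=(6, 4))), Tensor(rng.normal(size=4))
        x = np.zeros(6)
        x[[0, 3, 5]] = 1.0
        v = L.visit_embedding(x, E, b)
        np.testing.assert_allclose(
            v.data, np.tanh(E.data[[0, 3, 5]].sum(axis=0) + b.data), atol=1e-12)

    def test_empty_or_nonbinary_visit_rejected(self):
        E, b = Tensor(np.zeros((3, 2))), Tensor(np.zeros(2))
        with pytest.raises(ValueError, match="empty visit"):
            L.visit_embedding(np.zeros(3), E, b)
        with pytest.raises(ValueError, match="binary"):
            L.visit_embedding(np.array([0.0, 2.0, 0.0]), E, b)


class TestSoftmaxHead:
    def test_equal_logits_uniform(self):
        out = L.softmax_head(Tensor(np.zeros(3)), Tensor(np.zeros((3, 5))),
                             Tensor(np.zeros(5)))
        np.testing.assert_allclose(out.data, 0.2, atol=1e-12)

    def test_dominant_logit_saturates(self):
        b = Tensor(np.array([50.0, 0.0, 0.0]))
        out = L.softmax_head(Tensor(np.zeros(2)), Tensor(np.zeros((2, 3))), b)
        assert out.data[0] > 1 - 1e-9

    def test_matches_oracle_softmax(self):
        rng = np.random.default_rng(15)
        for _ in range(20):
            z = rng.normal(size=4)
            W, b = rng.normal(size=(4, 5)), rng.normal(size=5)
            out = L.softmax_head(Tensor(z), Tensor(W), Tensor(b))
            np.testing.assert_allclose(out.data, orc.softmax_vec(z @ W + b),
                                       atol=1e-10)


@settings(max_examples=100, derandomize=True, deadline=None)
@given(st.integers(0, 10_000), st.integers(1, 8), st.integers(1, 6))
def test_attention_and_softmax_weights_normalise(seed, t, g):
    """All attention weight vectors are non-negative and sum to 1 (1e-8)."""
    rng = np.random.default_rng(seed)
    p = L.init_attention(g, rng)
    p.W_alpha.data = rng.normal(size=(g, 1)) * 5
    states = [Tensor(rng.normal(size=g) * 5) for _ in range(t)]
    w, _ = L.location_attention(states, p)
    assert np.all(w.data >= 0)
    assert abs(w.data.sum() - 1.0) < 1e-8
    probs = L.softmax_head(Tensor(rng.normal(size=g) * 3),
                           Tensor(rng.normal(size=(g, 7))),
                           Tensor(rng.normal(size=7)))
    assert np.all(probs.data > 0)
    assert abs(probs.data.sum() - 1.0) < 1e-8


@settings(max_examples=50, derandomize=True, deadline=None)
@given(st.integers(0, 10_000))
def test_graph_attention_weights_normalise(seed):
    rng = np.random.default_rng(seed)
    d, l = 3, 2
    anc_sets = {0: [0, 2, 3], 1: [1, 3]}
    idx = np.array([[0, 2, 3], [1, 3, 0]])
    mask = np.array([[True, True, True], [True, True, False]])
    anc = L.AncestorIndex(["a", "b", "c", "d"], idx, mask)
    emb = Tensor(rng.normal(size=(4, d)) * 3)
    p = L.init_graph_attention(d, l, rng)
    p.u_a.data = rng.normal(size=(l, 1)) * 3
    g = L.graph_attention_embed(anc, emb, p)
    # reconstruct weights by solving against oracle: just check convexity via
    # the oracle weights directly
    expected = orc.graph_attention(anc_sets, emb.data, p.u_a.data[:, 0],
                                   p.W_a.data, p.b_a.data)
    np.testing.assert_allclose(g.data, expected, atol=1e-8)


class TestLayerGradients:
    """Analytic gradients vs central finite differences (1e-4 relative)."""

    @staticmethod
    def _check(loss_fn, params, tol=1e-4):
        out = loss_fn()
        for p in params:
            p.grad = None
        out.backward()
        for p in params:
            num = orc.numeric_grad(lambda: float(loss_fn().data), p.data)
            # mixed criterion: the absolute floor covers parameters the
            # output is invariant to (e.g. the attention bias, which softmax
            # shifts away), where `num` is pure finite-difference noise
            err = np.abs(p.grad - num).max()
            assert err <= tol * np.abs(num).max() + 1e-8

    def test_gru_gradients(self):
        rng = np.random.default_rng(20)
        p = L.init_gru(3, 4, rng)
        vs = [Tensor(rng.normal(size=(2, 3))) for _ in range(3)]
        target = rng.normal(size=(2, 4))

        def loss():
            h = L.gru_sequence(vs, p)[-1]
            diff = h - Tensor(target)
            return ag.tsum(diff * diff)

        self._check(loss, list(p.parameters().values()))

    def test_location_attention_gradients(self):
        rng = np.random.default_rng(21)
        p = L.init_attention(3, rng)
        states = [Tensor(rng.normal(size=(2, 3))) for _ in range(4)]

        def loss():
            _, c = L.location_attention(states, p)
            return ag.tsum(c * c)

        self._check(loss, [p.W_alpha, p.b_alpha])

    def test_graph_attention_gradients(self):
        rng = np.random.default_rng(22)
        idx = np.array([[0, 2, 3], [1, 3, 0]])
        mask = np.array([[True, True, True], [True, True, False]])
        anc = L.AncestorIndex(["a", "b", "c", "d"], idx, mask)
        emb = Tensor(rng.normal(size=(4, 3)), requires_grad=True)
        p = L.init_graph_attention(3, 2, rng)

        def loss():
            g = L.graph_attention_embed(anc, emb, p)
            return ag.tsum(g * g)

        self._check(loss, [emb, p.u_a, p.W_a, p.b_a])

    def test_retain_context_gradients(self):
        rng = np.random.default_rng(23)
        attn = L.init_attention(3, rng)
        rp = L.init_retain(3, 2, rng)
        vs = [Tensor(rng.normal(size=(1, 2))) for _ in range(3)]
        a_s = [Tensor(rng.normal(size=(1, 3))) for _ in range(3)]
        b_s = [Tensor(rng.normal(size=(1, 3))) for _ in range(3)]

        def loss():
            c = L.retain_context(vs, a_s, b_s, attn, rp)
            return ag.tsum(c * c)

        self._check(loss, [attn.W_alpha, attn.b_alpha, rp.W_beta, rp.b_beta])

    def test_softmax_head_gradients(self):
        rng = np.random.default_rng(24)
        W = Tensor(rng.normal(size=(3, 4)), requires_grad=True)
        b = Tensor(rng.normal(size=4), requires_grad=True)
        z = Tensor(rng.normal(size=(2, 3)))
        y = np.zeros((2, 4))
        y[0, 1] = y[1, 3] = 1.0

        def loss():
            p = L.softmax_head(z, W, b)
            return -ag.tsum(Tensor(y) * ag.log(p))

        self._check(loss, [W, b])
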