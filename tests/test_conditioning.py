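"""Condition-fusion math: linear extension, inner-product fusion, and
cross-attention."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from omicsdiff.conditioning import (
    AttentionParams,
    ConditionExtension,
    CrossAttention,
    cross_attention,
    extend_linear,
    inner_product_fuse,
    noisy_input,
)
from omicsdiff.nn import Tensor


def _params(rng, d_a=3, d_b=4, d_k=2, d_v=3, d_out=2):
    return AttentionParams(
        w_qa=rng.standard_normal((d_a, d_k)),
        w_kb=rng.standard_normal((d_b, d_k)),
        w_vb=rng.standard_normal((d_b, d_v)),
        w_ob=rng.standard_normal((d_v, d_out)),
    )


class TestExtendLinear:
    def test_zero_condition_zero_map(self, rng):
        w = rng.standard_normal((5, 16))
        out = extend_linear(np.zeros(5), w, None, 4)
        np.testing.assert_array_equal(out, np.zeros((4, 4)))

    def test_linearity(self, rng):
        w = rng.standard_normal((5, 9))
        t1, t2 = rng.standard_normal((2, 5))
        a, b = 2.5, -1.25
        lhs = extend_linear(a * t1 + b * t2, w, None, 3)
        rhs = a * extend_linear(t1, w, None, 3) + b * extend_linear(t2, w, None, 3)
        np.testing.assert_allclose(lhs, rhs, atol=1e-12)

    def test_hand_computed_entries(self):
        w = np.arange(8.0).reshape(2, 4)  # R=2 -> 2x2 map
        tau = np.array([1.0, 10.0])
        out = extend_linear(tau, w, None, 2)
        np.testing.assert_array_equal(out, [[40.0, 51.0], [62.0, 73.0]])

    def test_dimension_mismatch(self, rng):
        with pytest.raises(ValueError):
            extend_linear(np.zeros(3), rng.standard_normal((3, 8)), None, 4)


class TestInnerProductFuse:
    def test_identity_map(self, rng):
        p = rng.standard_normal((4, 4))
        np.testing.assert_array_equal(inner_product_fuse(np.eye(4), p), p)

    def test_zero_map(self, rng):
        p = rng.standard_normal((3, 3))
        np.testing.assert_array_equal(inner_product_fuse(np.zeros((3, 3)), p), 0 * p)

    def test_hand_matrix_multiplication(self):
        f = np.array([[1.0, 2.0], [3.0, 4.0]])
        p = np.array([[0.0, 1.0], [1.0, 0.0]])
        np.testing.assert_array_equal(
            inner_product_fuse(f, p), [[2.0, 1.0], [4.0, 3.0]]
        )

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_bilinearity(self, seed):
        r = np.random.default_rng(seed)
        f1, f2, p1, p2 = r.standard_normal((4, 3, 3))
        a, b = r.standard_normal(2)
        np.testing.assert_allclose(
            inner_product_fuse(a * f1 + b * f2, p1),
            a * inner_product_fuse(f1, p1) + b * inner_product_fuse(f2, p1),
            atol=1e-10,
        )
        np.testing.assert_allclose(
            inner_product_fuse(f1, a * p1 + b * p2),
            a * inner_product_fuse(f1, p1) + b * inner_product_fuse(f1, p2),
            atol=1e-10,
        )

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            inner_product_fuse(np.zeros((2, 2)), np.zeros((3, 3)))


class TestNoisyInput:
    def test_unconditional_limit(self, rng):
        p = rng.standard_normal((4, 4))
        np.testing.assert_array_equal(noisy_input(p, np.zeros_like(p)), p)

    def test_identity_fusion_doubles(self, rng):
        p = rng.standard_normal((4, 4))
        x = inner_product_fuse(np.eye(4), p)
        np.testing.assert_allclose(noisy_input(p, x), 2 * p)

    def test_matches_direct_computation(self, rng):
        f = rng.standard_normal((5, 5))
        p = rng.standard_normal((5, 5))
        expected = f @ p + p
        np.testing.assert_allclose(noisy_input(p, inner_product_fuse(f, p)), expected)


class TestCrossAttention:
    def test_identical_keys_give_uniform_weights(self, rng):
        params = _params(rng)
        x_b = np.tile(rng.standard_normal(4), (6, 1))  # 6 identical B tokens
        _, attn = cross_attention(
            rng.standard_normal((2, 3)), x_b, params, return_weights=True
        )
        np.testing.assert_allclose(attn, 1.0 / 6.0, atol=1e-12)

    def test_dominant_logit_saturates(self):
        params = AttentionParams(
            w_qa=np.array([[1.0]]), w_kb=np.array([[1.0]]),
            w_vb=np.array([[1.0]]), w_ob=np.array([[1.0]]),
        )
        x_b = np.array([[50.0], [0.0]])
        _, attn = cross_attention(np.array([[1.0]]), x_b, params,
                                  return_weights=True)
        assert attn[0, 0] > 1 - 1e-10

    def test_hand_softmax_two_tokens(self):
        """d_k=1, logits (1, 0) -> weights (e/(e+1), 1/(e+1)); FR is the
        weighted value sum times W_OB."""
        params = AttentionParams(
            w_qa=np.array([[1.0]]), w_kb=np.array([[1.0]]),
            w_vb=np.array([[1.0]]), w_ob=np.array([[2.0]]),
        )
        x_a = np.array([[1.0]])
        x_b = np.array([[1.0], [0.0]])
        fr, attn = cross_attention(x_a, x_b, params, return_weights=True)
        e = np.e
        np.testing.assert_allclose(attn, [[e / (e + 1), 1 / (e + 1)]], atol=1e-12)
        np.testing.assert_allclose(attn, [[0.7311, 0.2689]], atol=1e-4)
        np.testing.assert_allclose(fr, [[2 * e / (e + 1)]], atol=1e-12)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_rows_stochastic(self, seed):
        r = np.random.default_rng(seed)
        params = _params(r)
        _, attn = cross_attention(
            r.standard_normal((3, 3)), r.standard_normal((5, 4)), params,
            return_weights=True,
        )
        np.testing.assert_allclose(attn.sum(axis=-1), 1.0, atol=1e-6)
        assert np.all(attn > 0) and np.all(attn < 1)

    def test_key_permutation_leaves_fr_unchanged(self, rng):
        """Permuting B tokens (keys and values together) does not change FR."""
        params = _params(rng)
        x_a = rng.standard_normal((2, 3))
        x_b = rng.standard_normal((5, 4))
        perm = rng.permutation(5)
        fr1 = cross_attention(x_a, x_b, params)
        fr2 = cross_attention(x_a, x_b[perm], params)
        np.testing.assert_allclose(fr1, fr2, atol=1e-12)

    def test_stabilised_softmax_handles_large_logits(self, rng):
        params = _params(rng)
        fr = cross_attention(
            rng.standard_normal((2, 3)) * 300, rng.standard_normal((4, 4)) * 300,
            params,
        )
        assert np.all(np.isfinite(fr))

    def test_dimension_mismatch(self, rng):
        with pytest.raises(ValueError):
            cross_attention(np.zeros((2, 7)), np.zeros((3, 4)), _params(rng))

    def test_incompatible_params_rejected(self, rng):
        with pytest.raises(ValueError):
            AttentionParams(
                w_qa=np.zeros((3, 2)), w_kb=np.zeros((4, 5)),
                w_vb=np.zeros((4, 3)), w_ob=np.zeros((3, 2)),
            )


class TestConditionExtensionModule:
    def test_zero_gate_is_unconditional(self, rng):
        ext = ConditionExtension(8, 16, rng, gate_init=0.0)
        p = Tensor(rng.standard_normal((2, 1, 16, 16)))
        tau = Tensor(rng.standard_normal((2, 8)))
        np.testing.assert_array_equal(ext.fuse(p, tau).value, p.value)

    def test_fuse_matches_functional_ops(self, rng):
        ext = ConditionExtension(4, 8, rng, gate_init=1.0)
        p = rng.standard_normal((1, 1, 8, 8))
        tau = rng.standard_normal((1, 4))
        got = ext.fuse(Tensor(p), Tensor(tau)).value[0, 0]
        f = extend_linear(tau[0], ext.weight.value, ext.bias.value, 8)
        expected = noisy_input(p[0, 0], inner_product_fuse(f, p[0, 0]))
        np.testing.assert_allclose(got, expected, atol=1e-12)


class TestExtensionAndHeadOptions:
    def test_outer_extension_is_rank_one(self, rng):
        ext = ConditionExtension(4, 8, rng, gate_init=1.0, mode="outer")
        tau = Tensor(rng.standard_normal((1, 4)))
        f = ext.extend(tau).value[0]
        assert np.linalg.matrix_rank(f, tol=1e-10) <= 1

    def test_unknown_extension_mode_rejected(self, rng):
        import pytest as _pt
        with _pt.raises(ValueError):
            ConditionExtension(4, 8, rng, mode="conv")

    def test_multi_head_attention_shapes_and_grads(self, rng):
        attn = CrossAttention(4, 8, rng, n_tokens=2, n_heads=2)
        attn.gate.value = np.array(1.0)
        h = Tensor(rng.standard_normal((2, 8, 4, 4)), requires_grad=True)
        tau = Tensor(rng.standard_normal((2, 4)))
        out = attn(h, tau)
        assert out.shape == (2, 8, 4, 4)
        (out ** 2).mean().backward()
        assert all(p.grad is not None for p in attn.parameters())

    def test_head_count_must_divide_channels(self, rng):
        import pytest as _pt
        with _pt.raises(ValueError):
            CrossAttention(4, 8, rng, n_heads=3)
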