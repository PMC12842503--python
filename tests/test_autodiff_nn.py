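"""Engine-level checks: gradients against finite differences, fused layers
against their composite definitions."""

import numpy as np
import pytest

from ddrecon.autodiff import Tensor, concat, default_dtype, no_grad
from ddrecon.nn import (BiGRULayer, Conv2d, GRUCell, LayerNorm,
                        MultiHeadSelfAttention, TransformerBlock, avg_pool2d,
                        upsample2x)


def numerical_grad(f, t, eps=1e-6):
    num = np.zeros_like(t.data)
    it = np.nditer(t.data, flags=["multi_index"])
    for _ in it:
        i = it.multi_index
        orig = t.data[i]
        t.data[i] = orig + eps
        fp = f()
        t.data[i] = orig - eps
        fm = f()
        t.data[i] = orig
        num[i] = (fp - fm) / (2 * eps)
    return num


def check_grads(build_loss, tensors, tol=1e-6):
    loss = build_loss()
    loss.backward()
    saved = [t.grad.copy() for t in tensors]
    for t, g in zip(tensors, saved):
        num = numerical_grad(lambda: build_loss().data, t)
        assert np.abs(g - num).max() < tol, f"gradient mismatch for {t}"


class TestEnginePrimitives:
    def test_broadcast_arithmetic_grads(self, rng):
        a = Tensor(rng.standard_normal((3, 4)), requires_grad=True)
        b = Tensor(rng.standard_normal((4,)), requires_grad=True)
        check_grads(lambda: ((a * b + b) ** 2).sum(), [a, b])

    def test_batched_matmul_grads(self, rng):
        a = Tensor(rng.standard_normal((2, 3, 4)), requires_grad=True)
        w = Tensor(rng.standard_normal((4, 5)), requires_grad=True)
        check_grads(lambda: ((a @ w) ** 2).sum(), [a, w])

    def test_softmax_rows_sum_to_one_and_grads(self, rng):
        x = Tensor(rng.standard_normal((3, 5)), requires_grad=True)
        s = x.softmax(axis=-1)
        assert np.allclose(s.data.sum(axis=-1), 1.0)
        check_grads(lambda: (x.softmax(axis=-1) ** 3.0).sum(), [x])

    def test_slicing_concat_reshape_grads(self, rng):
        x = Tensor(rng.standard_normal((4, 6)), requires_grad=True)

        def loss():
            parts = concat([x[0:2], x[2:4] * 2.0], axis=0)
            return (parts.reshape(2, 12).abs()).sum()

        check_grads(loss, [x], tol=1e-5)

    def test_no_grad_blocks_graph(self, rng):
        x = Tensor(rng.standard_normal((2, 2)), requires_grad=True)
        with no_grad():
            y = (x * 3.0).sum()
        assert not y.requires_grad

    def test_dtype_context(self):
        with default_dtype(np.float32):
            t = Tensor(np.zeros(3))
            assert t.data.dtype == np.float32
        assert Tensor(np.zeros(3)).data.dtype == np.float64

    def test_pool_and_upsample_shapes_and_values(self):
        x = Tensor(np.arange(16.0).reshape(1, 4, 4, 1))
        p = avg_pool2d(x)
        assert p.shape == (1, 2, 2, 1)
        assert p.data[0, 0, 0, 0] == pytest.approx((0 + 1 + 4 + 5) / 4)
        u = upsample2x(p)
        assert u.shape == (1, 4, 4, 1)
        assert np.all(u.data[0, :2, :2, 0] == p.data[0, 0, 0, 0])


class TestLayers:
    def test_layernorm_matches_composite_formula(self, rng):
        ln = LayerNorm(7)
        ln.gamma.data = rng.standard_normal(7)
        ln.beta.data = rng.standard_normal(7)
        x = rng.standard_normal((4, 7))
        out = ln(Tensor(x)).data
        mu = x.mean(-1, keepdims=True)
        var = x.var(-1, keepdims=True)
        expect = (x - mu) / np.sqrt(var + ln.eps) * ln.gamma.data + ln.beta.data
        assert np.allclose(out, expect)

    def test_layernorm_grads(self, rng):
        ln = LayerNorm(5)
        x = Tensor(rng.standard_normal((2, 5)), requires_grad=True)
        check_grads(lambda: (ln(x) ** 3.0).sum(), [x, ln.gamma, ln.beta], tol=1e-5)

    def test_attention_grads_and_shape(self, rng):
        attn = MultiHeadSelfAttention(8, 2, rng)
        x = Tensor(rng.standard_normal((3, 8)), requires_grad=True)
        assert attn(x).shape == (3, 8)
        check_grads(lambda: (attn(x) ** 2).sum(), [x, attn.qkv.weight], tol=1e-5)

    def test_attention_rejects_bad_heads(self, rng):
        with pytest.raises(ValueError, match="divisible"):
            MultiHeadSelfAttention(8, 3, rng)

    def test_single_token_attention_is_value_path(self, rng):
        """Softmax over a singleton is exactly 1, so attention reduces to
        proj(v(x))."""
        attn = MultiHeadSelfAttention(4, 1, rng)
        x = Tensor(rng.standard_normal((1, 4)))
        out = attn(x).data
        qkv = x.data @ attn.qkv.weight.data + attn.qkv.bias.data
        v = qkv[:, 8:]
        expect = v @ attn.proj.weight.data + attn.proj.bias.data
        assert np.allclose(out, expect)

    def test_block_with_zeroed_sublayers_is_identity(self, rng):
        blk = TransformerBlock(8, 16, 2, rng)
        for lin in (blk.attn.qkv, blk.attn.proj, blk.mlp.fc1, blk.mlp.fc2):
            lin.weight.data[:] = 0
            lin.bias.data[:] = 0
        x = rng.standard_normal((5, 8))
        assert np.allclose(blk(Tensor(x)).data, x)

    def test_block_permutation_equivariance(self, rng):
        blk = TransformerBlock(6, 12, 2, rng)
        x = rng.standard_normal((3, 6))
        perm = [2, 0, 1]
        assert np.allclose(blk(Tensor(x[perm])).data, blk(Tensor(x)).data[perm],
                           atol=1e-10)

    def test_conv_matches_unfold_oracle_and_grads(self, rng):
        conv = Conv2d(3, 2, 3, rng)
        x = Tensor(rng.standard_normal((2, 5, 6, 3)), requires_grad=True)
        direct = conv(x)
        oracle = x.detach().pad2d(1).unfold2d(3) @ conv.weight.detach() \
            + conv.bias.detach()
        assert np.allclose(direct.data, oracle.data)
        check_grads(lambda: (conv(x) ** 2).sum(), [x, conv.weight, conv.bias],
                    tol=1e-5)

    def test_conv_identity_init_passes_through(self, rng):
        conv = Conv2d(4, 4, 3, rng, init="identity")
        x = rng.standard_normal((1, 6, 6, 4))
        assert np.allclose(conv(Tensor(x)).data, x)


class TestGRU:
    def test_step_gradcheck(self, rng):
        cell = GRUCell(5, 4, rng)
        x = Tensor(rng.standard_normal((2, 5)), requires_grad=True)
        h = Tensor(rng.standard_normal((2, 4)), requires_grad=True)
        check_grads(lambda: (cell(x, h) ** 2).sum(),
                    [x, h, cell.w_ih, cell.w_hh, cell.b_ih, cell.b_hh], tol=1e-5)

    def test_step_matches_gate_equations(self, rng):
        cell = GRUCell(3, 2, rng)
        x = rng.standard_normal((1, 3))
        h = rng.standard_normal((1, 2))
        out = cell(Tensor(x), Tensor(h)).data
        gi = x @ cell.w_ih.data + cell.b_ih.data
        gh = h @ cell.w_hh.data + cell.b_hh.data
        sig = lambda a: 1 / (1 + np.exp(-a))
        r = sig(gi[:, :2] + gh[:, :2])
        z = sig(gi[:, 2:4] + gh[:, 2:4])
        n = np.tanh(gi[:, 4:] + r * gh[:, 4:])
        assert np.allclose(out, (1 - z) * n + z * h)

    def test_bidirectional_layer_output_width(self, rng):
        layer = BiGRULayer(3, 4, rng)
        seq = Tensor(rng.standard_normal((5, 2, 3)))
        out = layer(seq)
        assert out.shape == (5, 2, 8)
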