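"""Trainable layers used by the reconstruction models.

Layout conventions: token sequences are ``[batch, n_tokens, width]``, images
are channel-last ``[batch, H, W, C]``. Parameters are
:class:`~ddrecon.autodiff.Tensor` objects in the active default dtype;
initialisation follows the usual fan-in uniform rule and is driven by an
explicit ``numpy.random.Generator`` so every model is a pure function of
its seed.
"""

from __future__ import annotations

import math

import numpy as np

from .autodiff import Tensor

__all__ = [
    "Module", "Parameter", "Linear", "LayerNorm", "MLP",
    "MultiHeadSelfAttention", "TransformerBlock", "Conv2d",
    "GRUCell", "BiGRULayer", "avg_pool2d", "upsample2x",
]


def Parameter(data) -> Tensor:
    return Tensor(data, requires_grad=True)


class Module:
    """Tiny registry: attributes that are Tensors/Modules/lists thereof are tracked."""

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        seen: set[int] = set()

        def visit(obj):
            if isinstance(obj, Tensor):
                if obj.requires_grad and id(obj) not in seen:
                    seen.add(id(obj))
                    params.append(obj)
            elif isinstance(obj, Module):
                for v in vars(obj).values():
                    visit(v)
            elif isinstance(obj, (list, tuple)):
                for v in obj:
                    visit(v)
            elif isinstance(obj, dict):
                for v in obj.values():
                    visit(v)

        visit(self)
        return params

    def num_params(self) -> int:
        return int(sum(p.size for p in self.parameters()))

    def named_submodules(self) -> dict[str, "Module"]:
        return {k: v for k, v in vars(self).items() if isinstance(v, Module)}

    def state_arrays(self) -> list[np.ndarray]:
        return [p.data for p in self.parameters()]

    def load_state_arrays(self, arrays) -> None:
        params = self.parameters()
        if len(arrays) != len(params):
            raise ValueError(f"state mismatch: {len(arrays)} arrays for {len(params)} parameters")
        for p, a in zip(params, arrays):
            if p.data.shape != a.shape:
                raise ValueError(f"shape mismatch {p.data.shape} vs {a.shape}")
            p.data = np.asarray(a, dtype=np.float64)

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def _uniform(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    bound = 1.0 / math.sqrt(max(fan_in, 1))
    return rng.uniform(-bound, bound, size=shape)


class Linear(Module):
    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator, bias: bool = True):
        self.weight = Parameter(_uniform(rng, (in_dim, out_dim), in_dim))
        self.bias = Parameter(_uniform(rng, (out_dim,), in_dim)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        y = x @ self.weight
        return y + self.bias if self.bias is not None else y


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-6):
        self.gamma = Parameter(np.ones(dim))
        self.beta = Parameter(np.zeros(dim))
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        # fused node; equivalent to (x - mean) / sqrt(var + eps) * gamma + beta
        gamma, beta = self.gamma, self.beta
        d = x.shape[-1]
        mu = x.data.mean(axis=-1, keepdims=True)
        xc = x.data - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = xc * inv
        out = xhat * gamma.data + beta.data

        def backward(g):
            dgamma = (g * xhat).reshape(-1, d).sum(axis=0)
            dbeta = g.reshape(-1, d).sum(axis=0)
            gx = g * gamma.data
            dx = inv * (gx - gx.mean(axis=-1, keepdims=True)
                        - xhat * (gx * xhat).mean(axis=-1, keepdims=True))
            return ((x, dx), (gamma, dgamma), (beta, dbeta))

        return Tensor._node(out, (x, gamma, beta), backward)


class MLP(Module):
    """Two-layer feed-forward block with tanh-approximate GELU activation."""

    def __init__(self, dim: int, hidden: int, rng: np.random.Generator, out_dim: int | None = None):
        self.fc1 = Linear(dim, hidden, rng)
        self.fc2 = Linear(hidden, out_dim if out_dim is not None else dim, rng)

    @staticmethod
    def gelu(x: Tensor) -> Tensor:
        # fused node; tanh approximation 0.5*x*(1 + tanh(c*(x + 0.044715 x^3)))
        c = math.sqrt(2.0 / math.pi)
        xd = x.data
        t = np.tanh(c * (xd + 0.044715 * xd ** 3))
        out = 0.5 * xd * (1.0 + t)

        def backward(g):
            dt = c * (1.0 + 3 * 0.044715 * xd ** 2) * (1.0 - t * t)
            return ((x, g * (0.5 * (1.0 + t) + 0.5 * xd * dt)),)

        return Tensor._node(out, (x,), backward)

    def forward(self, x: Tensor) -> Tensor:
        return self.fc2(self.gelu(self.fc1(x)))


class MultiHeadSelfAttention(Module):
    def __init__(self, dim: int, heads: int, rng: np.random.Generator):
        if dim % heads:
            raise ValueError(f"hidden size {dim} not divisible by {heads} heads")
        self.heads = heads
        self.head_dim = dim // heads
        self.qkv = Linear(dim, 3 * dim, rng)
        self.proj = Linear(dim, dim, rng)

    def forward(self, x: Tensor) -> Tensor:
        *lead, n, d = x.shape
        h, hd = self.heads, self.head_dim
        qkv = self.qkv(x).reshape(*lead, n, 3, h, hd)
        # -> [3, *lead, h, n, hd]
        perm = (x.ndim - 1,) + tuple(range(len(lead))) + (x.ndim, x.ndim - 2, x.ndim + 1)
        qkv = qkv.transpose(*perm)
        q, k, v = qkv[0], qkv[1], qkv[2]
        att = (q @ k.swapaxes(-1, -2)) * (1.0 / math.sqrt(hd))
        att = att.softmax(axis=-1)
        out = att @ v  # [*lead, h, n, hd]
        nd = out.ndim
        perm_back = tuple(range(nd - 3)) + (nd - 2, nd - 3, nd - 1)
        out = out.transpose(*perm_back).reshape(*lead, n, d)
        return self.proj(out)


class TransformerBlock(Module):
    """Pre-norm block: x + MSA(LN(x)), then + MLP(LN(.))."""

    def __init__(self, dim: int, mlp_size: int, heads: int, rng: np.random.Generator):
        self.ln1 = LayerNorm(dim)
        self.attn = MultiHeadSelfAttention(dim, heads, rng)
        self.ln2 = LayerNorm(dim)
        self.mlp = MLP(dim, mlp_size, rng)

    def forward(self, x: Tensor) -> Tensor:
        x = x + self.attn(self.ln1(x))
        return x + self.mlp(self.ln2(x))


class Conv2d(Module):
    """Channel-last 2-D convolution (cross-correlation) with same-size zero padding.

    ``init`` selects the weight initialisation: ``"uniform"`` (fan-in
    uniform), ``"identity"`` (delta kernel passing channel c to output c,
    for refinement convs that should start as a pass-through), or
    ``"zero"`` (for output convs so early gradients reach every input
    stream at equal scale).
    """

    def __init__(self, in_ch: int, out_ch: int, ksize: int, rng: np.random.Generator,
                 init: str = "uniform"):
        fan_in = ksize * ksize * in_ch
        if init == "uniform":
            w = _uniform(rng, (fan_in, out_ch), fan_in)
        elif init == "identity":
            w = np.zeros((ksize, ksize, in_ch, out_ch))
            centre = (ksize - 1) // 2
            for c in range(min(in_ch, out_ch)):
                w[centre, centre, c, c] = 1.0
            w = w.reshape(fan_in, out_ch)
        elif init == "zero":
            w = np.zeros((fan_in, out_ch))
        else:
            raise ValueError(f"unknown init {init!r}")
        self.weight = Parameter(w)
        self.bias = Parameter(np.zeros(out_ch))
        self.ksize = ksize

    def forward(self, x: Tensor) -> Tensor:
        """Fused same-padding convolution: one GEMM per kernel tap.

        Equivalent to ``x.pad2d(pad).unfold2d(k) @ weight + bias`` (the
        im2col route, kept as the oracle path) but without materialising
        the k*k-fold column copy.
        """
        k = self.ksize
        pad = (k - 1) // 2
        w, b = self.weight, self.bias
        *lead, H, W, C = x.shape
        xp = np.pad(x.data, [(0, 0)] * (x.ndim - 3) + [(pad, pad), (pad, pad), (0, 0)])
        wk = w.data.reshape(k, k, C, -1)
        out = np.broadcast_to(b.data, tuple(lead) + (H, W, b.data.shape[0])).copy()
        for di in range(k):
            for dj in range(k):
                out += xp[..., di:di + H, dj:dj + W, :] @ wk[di, dj]

        def backward(g):
            dxp = np.zeros_like(xp)
            dw = np.empty_like(wk)
            Cout = g.shape[-1]
            g2 = g.reshape(-1, Cout)
            for di in range(k):
                for dj in range(k):
                    patch = xp[..., di:di + H, dj:dj + W, :]
                    dw[di, dj] = patch.reshape(-1, C).T @ g2
                    dxp[..., di:di + H, dj:dj + W, :] += g @ wk[di, dj].T
            db = g2.sum(axis=0)
            dx = dxp[..., pad:pad + H, pad:pad + W, :] if pad else dxp
            return ((x, dx), (w, dw.reshape(w.data.shape)), (b, db))

        return Tensor._node(out, (x, w, b), backward)


def avg_pool2d(x: Tensor) -> Tensor:
    """2x2 average pooling on [..., H, W, C] (H, W even)."""
    *lead, H, W, C = x.shape
    x = x.reshape(*lead, H // 2, 2, W // 2, 2, C)
    return x.mean(axis=(x.ndim - 4, x.ndim - 2))


def upsample2x(x: Tensor) -> Tensor:
    """Nearest-neighbour 2x upsampling on [..., H, W, C]."""
    *lead, H, W, C = x.shape
    x = x.reshape(*lead, H, 1, W, 1, C)
    ones_h = Tensor(np.ones((1, 2, 1, 1, 1)))
    x = x * ones_h
    ones_w = Tensor(np.ones((1, 1, 1, 2, 1)))
    x = x * ones_w
    return x.reshape(*lead, 2 * H, 2 * W, C)


class GRUCell(Module):
    """Gated recurrent cell with update/reset gates and two bias vectors.

    Parameter layout mirrors the common deep-learning convention: stacked
    input weights W_ih [input, 3*hidden], recurrent weights W_hh
    [hidden, 3*hidden], biases b_ih and b_hh [3*hidden], gate order
    (reset, update, candidate); the reset gate scales the recurrent
    contribution of the candidate. Parameter count is therefore
    3*hidden*(input+hidden) + 2*3*hidden.
    """

    def __init__(self, input_size: int, hidden_size: int, rng: np.random.Generator):
        self.input_size = input_size
        self.hidden_size = hidden_size
        self.w_ih = Parameter(_uniform(rng, (input_size, 3 * hidden_size), hidden_size))
        self.w_hh = Parameter(_uniform(rng, (hidden_size, 3 * hidden_size), hidden_size))
        self.b_ih = Parameter(_uniform(rng, (3 * hidden_size,), hidden_size))
        self.b_hh = Parameter(_uniform(rng, (3 * hidden_size,), hidden_size))

    def forward(self, x: Tensor, h: Tensor) -> Tensor:
        return self.step(x @ self.w_ih + self.b_ih, h)

    def step(self, gi: Tensor, h: Tensor) -> Tensor:
        """One update given the precomputed input contribution ``gi = x@W_ih + b_ih``.

        Implemented as a single fused graph node (forward gates in raw
        numpy, hand-derived backward) because the recurrence is stepped
        hundreds of times per slice and per-op graph overhead dominates
        otherwise.
        """
        H = self.hidden_size
        w_hh, b_hh = self.w_hh, self.b_hh
        gh = h.data @ w_hh.data + b_hh.data
        r = _sigmoid(gi.data[..., 0:H] + gh[..., 0:H])
        z = _sigmoid(gi.data[..., H:2 * H] + gh[..., H:2 * H])
        ghn = gh[..., 2 * H:]
        n = np.tanh(gi.data[..., 2 * H:] + r * ghn)
        out = (1.0 - z) * n + z * h.data

        def backward(g):
            dn = g * (1.0 - z)
            dz = g * (h.data - n) * z * (1.0 - z)
            da_n = dn * (1.0 - n * n)
            dr = da_n * ghn * r * (1.0 - r)
            dgh = np.concatenate([dr, dz, da_n * r], axis=-1)
            dgi = np.concatenate([dr, dz, da_n], axis=-1)
            dh = g * z + dgh @ w_hh.data.T
            dw = h.data.reshape(-1, H).T @ dgh.reshape(-1, 3 * H)
            db = dgh.reshape(-1, 3 * H).sum(axis=0)
            return ((gi, dgi), (h, dh), (w_hh, dw), (b_hh, db))

        return Tensor._node(out, (gi, h, w_hh, b_hh), backward)


class BiGRULayer(Module):
    """Bidirectional gated layer: two independent cells sweep the sequence
    forward and backward from zero initial states; per-step outputs are the
    concatenation [h_fwd_i, h_bwd_i]."""

    def __init__(self, input_size: int, hidden_size: int, rng: np.random.Generator):
        self.fwd = GRUCell(input_size, hidden_size, rng)
        self.bwd = GRUCell(input_size, hidden_size, rng)

    def forward(self, seq: Tensor) -> Tensor:
        """seq: [T, ...batch, input] -> [T, ...batch, 2*hidden]."""
        from . import birnn_transform
        return birnn_transform.sweep(seq, self.fwd, self.bwd)
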