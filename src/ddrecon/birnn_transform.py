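"""Bidirectional recurrent k-space domain transform.

The undersampled k-space slice, packed as a real ``[H, W, 2C]`` array, is
read as a sequence of W column vectors (each the flattened vertical column
of all H rows and 2C channels). A first bidirectional gated layer sweeps
this sequence left-to-right and right-to-left with hidden width H*d per
direction; a second bidirectional layer consumes the per-step concatenated
features of width 2*H*d with the same hidden width. Interpreting each final
hidden vector as a (direction, H, d) block and moving H to the leading
image axis yields image-domain features ``I_RNN`` of shape ``[H, W, 2d]``
— a learned, globally-aware inverse-transform surrogate whose parameter
count grows with H*W rather than (H*W)^2 as a fully connected map would.

The cells are 3-gate gated recurrent cells (update/reset/candidate) with
two bias vectors per gate set; :func:`count_birnn_params` gives the exact
closed-form trainable-parameter count of the two-layer stack.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, concat, stack
from .nn import BiGRULayer, GRUCell, Module

__all__ = [
    "BiRNNConfig", "columns_of", "columns_to_packed", "sweep",
    "BiRNNStack", "count_birnn_params",
]


@dataclass(frozen=True)
class BiRNNConfig:
    """Dimensions of the two-layer bidirectional stack.

    ``d`` is the per-pixel feature width of the output; the hidden state of
    every direction of every layer has width H*d.
    """

    H: int
    in_channels: int  # 2C
    d: int = 10

    @property
    def step_input_1(self) -> int:
        return self.H * self.in_channels

    @property
    def hidden(self) -> int:
        return self.H * self.d

    @property
    def step_input_2(self) -> int:
        return 2 * self.hidden


def columns_of(k_packed: Tensor | np.ndarray) -> Tensor:
    """[H, W, 2C] (or batched [..., H, W, 2C]) -> column sequence [W, ..., H*2C].

    Column i is the flattened slice ``[:, i, :]`` in (height, channel)
    order; the mapping is lossless (see :func:`columns_to_packed`).
    """
    if not isinstance(k_packed, Tensor):
        k_packed = Tensor(k_packed)
    *lead, H, W, ch = k_packed.shape
    nd = k_packed.ndim
    # [..., H, W, ch] -> [W, ..., H, ch]
    x = k_packed.transpose(nd - 2, *range(nd - 3), nd - 3, nd - 1)
    return x.reshape(W, *lead, H * ch)


def columns_to_packed(seq: Tensor, H: int, ch: int) -> Tensor:
    """Inverse of :func:`columns_of`."""
    W, *lead, flat = seq.shape
    if flat != H * ch:
        raise ValueError(f"column width {flat} != H*ch = {H * ch}")
    x = seq.reshape(W, *lead, H, ch)
    nd = x.ndim
    return x.transpose(*range(1, nd - 2), nd - 2, 0, nd - 1)


def sweep(seq: Tensor, cell_fwd: GRUCell, cell_bwd: GRUCell) -> Tensor:
    """Bidirectional sweep: [T, ..., input] -> [T, ..., 2*hidden].

    Both recurrences start from zero hidden states; output step i is
    ``[h_fwd_i, h_bwd_i]`` where the backward recurrence has consumed the
    sequence from the far end down to step i.
    """
    T = seq.shape[0]
    if seq.shape[-1] != cell_fwd.input_size or seq.shape[-1] != cell_bwd.input_size:
        raise ValueError(
            f"step width {seq.shape[-1]} does not match cell input sizes "
            f"{cell_fwd.input_size}/{cell_bwd.input_size}")
    lead = seq.shape[1:-1]
    # precompute the input contributions for all steps at once
    gi_f = seq @ cell_fwd.w_ih + cell_fwd.b_ih
    gi_b = seq @ cell_bwd.w_ih + cell_bwd.b_ih
    h_f = Tensor(np.zeros(lead + (cell_fwd.hidden_size,)))
    h_b = Tensor(np.zeros(lead + (cell_bwd.hidden_size,)))
    fwd: list[Tensor] = []
    bwd: list[Tensor] = [None] * T  # type: ignore[list-item]
    for t in range(T):
        h_f = cell_fwd.step(gi_f[t], h_f)
        fwd.append(h_f)
    for t in reversed(range(T)):
        h_b = cell_bwd.step(gi_b[t], h_b)
        bwd[t] = h_b
    return stack([concat([f, b], axis=-1) for f, b in zip(fwd, bwd)], axis=0)


class BiRNNStack(Module):
    """Two stacked bidirectional gated layers mapping packed k-space to I_RNN."""

    def __init__(self, config: BiRNNConfig, rng: np.random.Generator):
        self.config = config
        self.layer1 = BiGRULayer(config.step_input_1, config.hidden, rng)
        self.layer2 = BiGRULayer(config.step_input_2, config.hidden, rng)

    def forward(self, k_packed: Tensor) -> Tensor:
        """[..., H, W, 2C] -> image-domain features [..., H, W, 2d]."""
        cfg = self.config
        *lead, H, W, ch = k_packed.shape
        if H * ch != cfg.step_input_1:
            raise ValueError(
                f"k-space column width {H * ch} != configured step input {cfg.step_input_1}")
        seq = columns_of(k_packed)                       # [W, ..., H*2C]
        h_hor = self.layer1(seq)                         # [W, ..., 2*H*d]
        g_ver = self.layer2(h_hor)                       # [W, ..., 2*H*d]
        # each hidden vector is a (direction, H, d) block; move H to the image axis
        x = g_ver.reshape(W, *lead, 2, H, cfg.d)
        nd = x.ndim
        # [W, ..., 2, H, d] -> [..., H, W, 2, d]
        x = x.transpose(*range(1, nd - 3), nd - 2, 0, nd - 3, nd - 1)
        return x.reshape(*lead, H, W, 2 * cfg.d)


def count_birnn_params(config: BiRNNConfig) -> int:
    """Closed-form trainable-parameter count of the two-layer stack.

    Per direction per layer a 3-gate gated cell holds
    ``3*hidden*(input+hidden)`` weights and ``2*(3*hidden)`` biases; the
    total sums over 2 directions x 2 layers.
    """
    def layer(inp: int, hid: int) -> int:
        return 2 * (3 * hid * (inp + hid) + 2 * 3 * hid)

    return layer(config.step_input_1, config.hidden) + \
        layer(config.step_input_2, config.hidden)
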