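"""Transformer decoder, upsampling tail and dual-domain fusion.

The encoder result is linearly re-embedded into the decoder hidden width,
run through M pre-norm transformer blocks, projected per token to a
``p*p*C_ViT`` patch by an MLP, reshaped onto the patch grid and refined by
one same-size convolution, giving image-domain features ``I_ViT`` of shape
``[H, W, C_ViT]``. Fusion concatenates ``I_ViT``, the recurrent k-space
features ``I_RNN`` and the folded input image ``x`` along channels and maps
them to the final single-channel magnitude image with one 2-D convolution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, concat
from .nn import Conv2d, Linear, Module, TransformerBlock
from .vit_encoder import unpatchify

__all__ = ["DecoderConfig", "ViTDecoder", "UpTail", "Fusion"]


@dataclass(frozen=True)
class DecoderConfig:
    layers: int
    hidden: int
    mlp_size: int
    heads: int
    tail_channels: int = 16  # C_ViT
    in_dim: int | None = None  # width of the encoder result; None -> hidden

    def __post_init__(self):
        if self.hidden % self.heads:
            raise ValueError(f"hidden {self.hidden} not divisible by heads {self.heads}")
        if self.tail_channels < 1:
            raise ValueError("tail_channels must be >= 1")


class ViTDecoder(Module):
    """Feature embedding followed by M pre-norm transformer blocks."""

    def __init__(self, config: DecoderConfig, rng: np.random.Generator):
        self.config = config
        in_dim = config.in_dim if config.in_dim is not None else config.hidden
        self.feature_embed = Linear(in_dim, config.hidden, rng)
        self.blocks = [TransformerBlock(config.hidden, config.mlp_size, config.heads, rng)
                       for _ in range(config.layers)]

    def forward(self, z_enc: Tensor) -> Tensor:
        t = self.feature_embed(z_enc)
        for blk in self.blocks:
            t = blk(t)
        return t


class UpTail(Module):
    """Per-token MLP to p*p*C_ViT, grid reshape, one refinement convolution."""

    def __init__(self, config: DecoderConfig, H: int, W: int, patch: int,
                 rng: np.random.Generator):
        self.H, self.W, self.patch = H, W, patch
        self.c_vit = config.tail_channels
        self.mlp = Linear(config.hidden, patch * patch * self.c_vit, rng)
        self.refine = Conv2d(self.c_vit, self.c_vit, 3, rng, init="identity")

    def forward(self, z_dec: Tensor) -> Tensor:
        n_expected = (self.H // self.patch) * (self.W // self.patch)
        if z_dec.shape[-2] != n_expected:
            raise ValueError(
                f"{z_dec.shape[-2]} tokens cannot fill the "
                f"{self.H // self.patch}x{self.W // self.patch} grid")
        tiles = self.mlp(z_dec)
        img = unpatchify(tiles, self.H, self.W, self.patch)
        return self.refine(img)


class Fusion(Module):
    """Concat(I_ViT, I_RNN, x) along channels -> one conv -> [H, W] image."""

    def __init__(self, in_channels: int, rng: np.random.Generator,
                 kernel: int = 3, out_channels: int = 1):
        self.conv = Conv2d(in_channels, out_channels, kernel, rng, init="zero")
        self.out_channels = out_channels

    def forward(self, streams: list[Tensor]) -> Tensor:
        shapes = {s.shape[-3:-1] for s in streams}
        if len(shapes) != 1:
            raise ValueError(f"fusion streams disagree on spatial dims: {shapes}")
        y = self.conv(concat(streams, axis=-1))
        if self.out_channels == 1:
            y = y.reshape(*y.shape[:-1])
        return y
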