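"""Vision-Transformer encoder over folded multi-channel images.

The packed input ``[H, W, 2C]`` (real/imaginary channel pairs of the
zero-filled per-coil images) is cut into non-overlapping p x p patches in
row-major order, each flattened patch is linearly projected into the hidden
width and given a learned position embedding, and the token sequence runs
through L pre-norm transformer blocks followed by a final linear map to the
encoder output width D. No class token is used: every token corresponds to
an image patch, as required for dense reconstruction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor
from .nn import Linear, Module, Parameter, TransformerBlock

__all__ = ["ViTConfig", "VIT_PRESETS", "patchify", "unpatchify", "ViTEncoder"]

# (layers, hidden, mlp, heads) of the standard ViT model family
VIT_PRESETS = {
    "base": (12, 768, 3072, 12),
    "large": (24, 1024, 4096, 16),
    "huge": (32, 1280, 5120, 16),
}


@dataclass(frozen=True)
class ViTConfig:
    layers: int
    hidden: int
    mlp_size: int
    heads: int
    patch: int = 12
    in_channels: int = 2
    out_dim: int | None = None  # encoder-result width D; None -> hidden

    @classmethod
    def preset(cls, name: str, patch: int = 12, in_channels: int = 2,
               out_dim: int | None = None) -> "ViTConfig":
        L, Dh, mlp, heads = VIT_PRESETS[name]
        return cls(L, Dh, mlp, heads, patch, in_channels, out_dim)

    @property
    def D(self) -> int:
        return self.out_dim if self.out_dim is not None else self.hidden

    def __post_init__(self):
        if self.hidden % self.heads:
            raise ValueError(f"hidden {self.hidden} not divisible by heads {self.heads}")


def _grid(H: int, W: int, p: int) -> tuple[int, int]:
    if H % p or W % p:
        raise ValueError(f"patch size {p} does not tile image {H}x{W}")
    return H // p, W // p


def patchify(x: Tensor | np.ndarray, p: int) -> Tensor:
    """[..., H, W, ch] -> row-major tokens [..., (H/p)*(W/p), p*p*ch]."""
    if not isinstance(x, Tensor):
        x = Tensor(x)
    *lead, H, W, ch = x.shape
    gh, gw = _grid(H, W, p)
    x = x.reshape(*lead, gh, p, gw, p, ch)
    nd = x.ndim
    x = x.transpose(*range(nd - 5), nd - 5, nd - 3, nd - 4, nd - 2, nd - 1)
    return x.reshape(*lead, gh * gw, p * p * ch)


def unpatchify(tokens: Tensor | np.ndarray, H: int, W: int, p: int) -> Tensor:
    """Inverse of :func:`patchify` for a known target image size."""
    if not isinstance(tokens, Tensor):
        tokens = Tensor(tokens)
    *lead, n, width = tokens.shape
    gh, gw = _grid(H, W, p)
    if n != gh * gw:
        raise ValueError(f"{n} tokens do not fill a {gh}x{gw} patch grid")
    ch = width // (p * p)
    x = tokens.reshape(*lead, gh, gw, p, p, ch)
    nd = x.ndim
    x = x.transpose(*range(nd - 5), nd - 5, nd - 3, nd - 4, nd - 2, nd - 1)
    return x.reshape(*lead, H, W, ch)


class PatchEmbed(Module):
    """Linear projection of flattened patches plus a learned position table."""

    def __init__(self, config: ViTConfig, n_tokens: int, rng: np.random.Generator):
        token_len = config.patch ** 2 * config.in_channels
        self.proj = Linear(token_len, config.hidden, rng)
        self.pos = Parameter(np.zeros((n_tokens, config.hidden)))

    def forward(self, tokens: Tensor) -> Tensor:
        return self.proj(tokens) + self.pos


class ViTEncoder(Module):
    """patchify -> embed -> L pre-norm blocks -> final linear to out_dim."""

    def __init__(self, config: ViTConfig, H: int, W: int, rng: np.random.Generator):
        gh, gw = _grid(H, W, config.patch)
        self.config = config
        self.grid = (gh, gw)
        self.H, self.W = H, W
        self.embed = PatchEmbed(config, gh * gw, rng)
        self.blocks = [TransformerBlock(config.hidden, config.mlp_size, config.heads, rng)
                       for _ in range(config.layers)]
        self.head = Linear(config.hidden, config.D, rng)

    def forward(self, x: Tensor) -> Tensor:
        """Packed image(s) [..., H, W, 2C] -> encoder tokens [..., n_tokens, D]."""
        if x.shape[-1] != self.config.in_channels:
            raise ValueError(
                f"input has {x.shape[-1]} channels, config expects {self.config.in_channels}")
        t = self.embed(patchify(x, self.config.patch))
        for blk in self.blocks:
            t = blk(t)
        return self.head(t)
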