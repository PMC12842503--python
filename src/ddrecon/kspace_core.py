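"""Fourier conventions, Cartesian undersampling and coil bookkeeping.

Multi-coil 2-D slices are complex arrays of shape ``[C, H, W]`` with the
frequency-encoding (FE) axis along H and the phase-encoding (PE) axis along
W; undersampling skips PE lines (columns). All transforms are centred
(DC at ``[H//2, W//2]``) and orthonormal, so the fully sampled central PE
lines of an auto-calibration (ACS) block are literally the centre columns
and Parseval's identity holds exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "SamplingMask", "fft2c", "ifft2c", "make_mask", "apply_mask",
    "rss", "pack_channels", "unpack_channels",
]


def _check_chw(a: np.ndarray, name: str) -> np.ndarray:
    a = np.asarray(a)
    if a.ndim != 3:
        raise ValueError(f"{name} must have shape [C, H, W], got {a.shape}")
    C, H, W = a.shape
    if C < 1 or H < 2 or W < 2:
        raise ValueError(f"{name} shape {a.shape} violates C>=1, H>=2, W>=2")
    if not np.all(np.isfinite(a)):
        raise ValueError(f"{name} contains non-finite entries")
    return a


def fft2c(images: np.ndarray) -> np.ndarray:
    """Centred orthonormal 2-D DFT per coil: image domain -> k-space."""
    images = _check_chw(images, "images")
    return np.fft.fftshift(
        np.fft.fft2(np.fft.ifftshift(images, axes=(-2, -1)), axes=(-2, -1), norm="ortho"),
        axes=(-2, -1),
    )


def ifft2c(kspace: np.ndarray) -> np.ndarray:
    """Inverse of :func:`fft2c`: k-space -> per-coil images."""
    kspace = _check_chw(kspace, "kspace")
    return np.fft.fftshift(
        np.fft.ifft2(np.fft.ifftshift(kspace, axes=(-2, -1)), axes=(-2, -1), norm="ortho"),
        axes=(-2, -1),
    )


def _round_half_away(x: float) -> int:
    return int(np.floor(x + 0.5)) if x >= 0 else -int(np.floor(-x + 0.5))


@dataclass(frozen=True)
class SamplingMask:
    """Binary pattern over PE lines; constant along the FE axis.

    ``lines[w] == 1`` means PE line ``w`` is acquired. The ACS block is a
    contiguous run of ``n_acs`` fully sampled lines centred at ``W//2``.
    """

    lines: np.ndarray
    pattern: str
    R: int
    n_acs: int
    seed: int | None = None

    @property
    def width(self) -> int:
        return self.lines.shape[0]

    @property
    def n_sampled(self) -> int:
        return int(self.lines.sum())

    def as_2d(self, H: int) -> np.ndarray:
        """Broadcast the line mask over the FE axis -> [H, W] array of 0/1."""
        return np.broadcast_to(self.lines[None, :], (H, self.width)).copy()


def make_mask(W: int, R: int, n_acs: int, pattern: str = "random",
              seed: int | None = None) -> SamplingMask:
    """Build a Cartesian PE-line undersampling mask.

    The total line budget is ``round(W/R)`` (half away from zero), ACS
    included, so the effective acceleration equals R exactly. Non-ACS lines
    are drawn uniformly at random without replacement (``random``) or placed
    equispaced over the ordered non-ACS index list at offsets
    ``floor(j*M/n_extra)`` (``regular``).
    """
    if pattern not in ("regular", "random"):
        raise ValueError(f"unknown pattern {pattern!r}")
    if R < 1 or R > W:
        raise ValueError(f"acceleration R={R} outside [1, W={W}]")
    if n_acs < 0 or n_acs > W:
        raise ValueError(f"n_acs={n_acs} outside [0, W={W}]")
    if R == 1:
        return SamplingMask(np.ones(W, dtype=np.int8), pattern, 1, n_acs, seed)
    n_total = _round_half_away(W / R)
    if n_acs > n_total:
        raise ValueError(
            f"infeasible mask: n_acs={n_acs} exceeds line budget round(W/R)={n_total}")
    lines = np.zeros(W, dtype=np.int8)
    acs_start = W // 2 - n_acs // 2
    lines[acs_start:acs_start + n_acs] = 1
    non_acs = np.flatnonzero(lines == 0)
    n_extra = n_total - n_acs
    if n_extra > 0:
        if pattern == "random":
            rng = np.random.default_rng(seed)
            chosen = rng.choice(non_acs, size=n_extra, replace=False)
        else:
            M = non_acs.size
            offsets = (np.arange(n_extra) * M) // n_extra
            chosen = non_acs[offsets]
        lines[chosen] = 1
    return SamplingMask(lines, pattern, R, n_acs, seed)


def apply_mask(kspace: np.ndarray, mask: SamplingMask) -> np.ndarray:
    """Zero the non-sampled PE lines; sampled lines pass through bit-identical."""
    kspace = np.asarray(kspace)
    if kspace.shape[-1] != mask.width:
        raise ValueError(
            f"mask length {mask.width} does not match k-space PE width {kspace.shape[-1]}")
    return kspace * mask.lines.astype(kspace.dtype)


def rss(images: np.ndarray) -> np.ndarray:
    """Root-sum-of-squares coil combination: [C, H, W] -> magnitude [H, W]."""
    images = _check_chw(images, "images")
    return np.sqrt((np.abs(images) ** 2).sum(axis=0))


def pack_channels(images: np.ndarray) -> np.ndarray:
    """Complex [C, H, W] -> real [H, W, 2C], channel order (Re c0, Im c0, Re c1, ...)."""
    images = _check_chw(images, "images")
    C, H, W = images.shape
    out = np.empty((H, W, 2 * C), dtype=np.float64)
    for c in range(C):
        out[:, :, 2 * c] = images[c].real
        out[:, :, 2 * c + 1] = images[c].imag
    return out


def unpack_channels(packed: np.ndarray) -> np.ndarray:
    """Inverse of :func:`pack_channels`."""
    packed = np.asarray(packed)
    if packed.ndim != 3:
        raise ValueError(f"packed image must have shape [H, W, 2C], got {packed.shape}")
    if packed.shape[-1] % 2:
        raise ValueError(f"channel count {packed.shape[-1]} is odd; expected 2C layout")
    H, W, twoC = packed.shape
    C = twoC // 2
    out = np.empty((C, H, W), dtype=np.complex128)
    for c in range(C):
        out[c] = packed[:, :, 2 * c] + 1j * packed[:, :, 2 * c + 1]
    return out
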