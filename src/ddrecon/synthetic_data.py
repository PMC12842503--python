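"""Multi-coil phantom simulation and fastMRI-layout HDF5 containers.

The generator emulates the statistical structure an accelerated-MRI
reconstruction model is trained on: piecewise-smooth anatomy (random
ellipse superpositions), spatially smooth complex coil sensitivities, and
i.i.d. complex Gaussian measurement noise added in k-space. Coil maps are
RSS-normalised per pixel so the phantom itself is the ground-truth
magnitude label of the fully sampled acquisition.

Containers follow the fastMRI layout: HDF5 datasets ``kspace``
(complex64, ``[slices, coils, H, W]``) and ``reconstruction_rss``
(float32, ``[slices, H, W]``), with acquisition metadata in attributes.
"""

from __future__ import annotations

from dataclasses import dataclass

import h5py
import numpy as np

from .kspace_core import fft2c

__all__ = [
    "PhantomSpec", "CoilMapSpec", "NoiseSpec",
    "gen_phantom", "gen_coil_maps", "simulate_kspace",
    "write_dataset", "read_dataset", "Volume", "make_volume",
]


@dataclass(frozen=True)
class PhantomSpec:
    H: int = 64
    W: int = 72
    n_ellipses: int = 8
    max_intensity: float = 1.0
    seed: int = 0


@dataclass(frozen=True)
class CoilMapSpec:
    C: int = 2
    smoothness: float | None = None  # Gaussian bump width in pixels; None -> half the diagonal
    seed: int = 0


@dataclass(frozen=True)
class NoiseSpec:
    sigma: float = 0.0  # k-space std per real component
    seed: int = 0


def gen_phantom(spec: PhantomSpec) -> np.ndarray:
    """Render a random-ellipse phantom in [0, max_intensity], deterministic per seed."""
    if spec.H < 1 or spec.W < 1:
        raise ValueError(f"zero-area canvas {spec.H}x{spec.W}")
    if spec.n_ellipses < 1:
        raise ValueError("need at least one ellipse")
    rng = np.random.default_rng(spec.seed)
    yy, xx = np.mgrid[0:spec.H, 0:spec.W].astype(np.float64)
    img = np.zeros((spec.H, spec.W))
    for _ in range(spec.n_ellipses):
        cy = rng.uniform(0.2, 0.8) * spec.H
        cx = rng.uniform(0.2, 0.8) * spec.W
        a = rng.uniform(0.08, 0.45) * spec.H
        b = rng.uniform(0.08, 0.45) * spec.W
        theta = rng.uniform(0.0, np.pi)
        amp = rng.uniform(-0.6, 1.0)
        img += amp * ellipse_mask(yy, xx, cy, cx, a, b, theta)
    img = np.clip(img, 0.0, None)
    peak = img.max()
    if peak > 0:
        img *= spec.max_intensity / peak
    return img


def ellipse_mask(yy: np.ndarray, xx: np.ndarray, cy: float, cx: float,
                 a: float, b: float, theta: float) -> np.ndarray:
    """Indicator of a rotated ellipse with semi-axes (a, b) centred at (cy, cx)."""
    dy, dx = yy - cy, xx - cx
    u = dy * np.cos(theta) + dx * np.sin(theta)
    v = -dy * np.sin(theta) + dx * np.cos(theta)
    return ((u / a) ** 2 + (v / b) ** 2 <= 1.0).astype(np.float64)


def gen_coil_maps(spec: CoilMapSpec, H: int, W: int) -> np.ndarray:
    """Smooth complex sensitivities [C, H, W] with per-pixel sum |s_c|^2 == 1.

    Each coil is a Gaussian magnitude bump anchored on the image border with
    a smooth linear phase ramp; pixel-wise RSS normalisation makes the RSS
    of (map x phantom) reproduce the phantom exactly.
    """
    if spec.C < 1:
        raise ValueError("need at least one coil")
    rng = np.random.default_rng(spec.seed)
    yy, xx = np.mgrid[0:H, 0:W].astype(np.float64)
    width = spec.smoothness if spec.smoothness is not None else 0.5 * np.hypot(H, W)
    width = max(width, 1.0)
    maps = np.empty((spec.C, H, W), dtype=np.complex128)
    for c in range(spec.C):
        # anchor on the border at angle spread around the circle, jittered
        ang = 2 * np.pi * (c + rng.uniform(-0.2, 0.2)) / spec.C
        ay = (0.5 + 0.55 * np.sin(ang)) * (H - 1)
        ax = (0.5 + 0.55 * np.cos(ang)) * (W - 1)
        mag = np.exp(-((yy - ay) ** 2 + (xx - ax) ** 2) / (2 * width ** 2)) + 0.05
        phase = rng.uniform(-np.pi, np.pi) + \
            rng.uniform(-2, 2) * np.pi * (yy / H) + rng.uniform(-2, 2) * np.pi * (xx / W)
        maps[c] = mag * np.exp(1j * phase)
    norm = np.sqrt((np.abs(maps) ** 2).sum(axis=0))
    return maps / norm


def simulate_kspace(phantom: np.ndarray, maps: np.ndarray, noise: NoiseSpec) -> np.ndarray:
    """Forward model: per-coil image = map x phantom, centred FFT, additive noise."""
    phantom = np.asarray(phantom)
    maps = np.asarray(maps)
    if maps.ndim != 3 or maps.shape[1:] != phantom.shape:
        raise ValueError(
            f"coil maps {maps.shape} incompatible with phantom {phantom.shape}")
    k = fft2c(maps * phantom[None])
    if noise.sigma > 0:
        rng = np.random.default_rng(noise.seed)
        k = k + noise.sigma * (rng.standard_normal(k.shape)
                               + 1j * rng.standard_normal(k.shape))
    return k


@dataclass
class Volume:
    """A stack of slices with its fully-sampled reference magnitudes."""

    kspace: np.ndarray            # complex [slices, C, H, W]
    reference: np.ndarray         # float [slices, H, W]
    attrs: dict

    @property
    def n_slices(self) -> int:
        return self.kspace.shape[0]

    @property
    def n_coils(self) -> int:
        return self.kspace.shape[1]

    @property
    def shape(self) -> tuple:
        return self.kspace.shape[-2:]


def make_volume(n_slices: int, C: int, H: int, W: int, sigma: float,
                seed: int, n_ellipses: int = 8) -> Volume:
    """Generate a phantom volume: fresh anatomy and coil maps per slice."""
    ks, refs = [], []
    for s in range(n_slices):
        base = (seed * 100003 + s * 977) % (2 ** 31)
        phantom = gen_phantom(PhantomSpec(H, W, n_ellipses=n_ellipses, seed=base))
        maps = gen_coil_maps(CoilMapSpec(C=C, seed=base + 1), H, W)
        k = simulate_kspace(phantom, maps, NoiseSpec(sigma=sigma, seed=base + 2))
        ks.append(k)
        refs.append(phantom)
    return Volume(np.stack(ks), np.stack(refs),
                  {"sigma": sigma, "seed": seed, "n_ellipses": n_ellipses})


def write_dataset(path, volume: Volume, acceleration: int = 1, num_acs: int = 0,
                  pattern: str = "random", seed: int = 0) -> None:
    """Write a volume to a fastMRI-layout HDF5 container."""
    k = np.asarray(volume.kspace)
    ref = np.asarray(volume.reference)
    if k.ndim != 4:
        raise ValueError(f"kspace must be [slices, coils, H, W], got {k.shape}")
    if ref.ndim != 3 or ref.shape[0] != k.shape[0] or ref.shape[1:] != k.shape[2:]:
        raise ValueError(
            f"reconstruction_rss {ref.shape} inconsistent with kspace {k.shape}")
    with h5py.File(path, "w") as f:
        f.create_dataset("kspace", data=k.astype(np.complex64))
        f.create_dataset("reconstruction_rss", data=ref.astype(np.float32))
        f.attrs["acceleration"] = acceleration
        f.attrs["num_acs"] = num_acs
        f.attrs["pattern"] = pattern
        f.attrs["seed"] = seed


def read_dataset(path) -> Volume:
    """Read a fastMRI-layout container; raises a named-field error if malformed."""
    with h5py.File(path, "r") as f:
        for name, rank in (("kspace", 4), ("reconstruction_rss", 3)):
            if name not in f:
                raise KeyError(f"container {path} lacks required dataset '{name}'")
            if f[name].ndim != rank:
                raise ValueError(
                    f"dataset '{name}' has rank {f[name].ndim}, expected {rank}")
        k = f["kspace"][()].astype(np.complex128)
        ref = f["reconstruction_rss"][()].astype(np.float64)
        attrs = dict(f.attrs)
    return Volume(k, ref, attrs)
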