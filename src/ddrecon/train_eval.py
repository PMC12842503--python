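"""Training harness, reconstruction runner and the scaled-down comparison.

Protocol: Adam (betas 0.9/0.999, eps 1e-8) on a pixel-wise L1 loss between
the predicted and reference magnitude images, with a cosine-annealed
learning rate over the epoch budget and no data augmentation. The desk
profile trains tiny variants on 64x72 two-coil phantom data; the full-scale
profile records the published settings (initial lr 1e-4, 50 epochs) and is
intended for GPU-class hardware.

Per-sample preprocessing: the folded image x = pack(ifft2c(masked k)) and
the reference are divided by the peak of the zero-filled RSS magnitude, and
the packed k-space input is divided by its own peak magnitude, so every
network sees O(1) inputs regardless of phantom scale; predictions are
rescaled back before metrics are computed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .autodiff import Tensor, default_dtype, no_grad
from .kspace_core import apply_mask, ifft2c, make_mask, pack_channels, rss
from .metrics import evaluate_pair, nmse
from .models import build, tiny_config
from .nn import Module
from .synthetic_data import Volume, make_volume

__all__ = [
    "TrainConfig", "SliceDataset", "l1_loss", "cosine_lr", "Adam",
    "build_dataset", "train", "reconstruct", "zero_filled", "run_comparison",
    "acs_lines", "DESK_PROFILE", "FULL_PROFILE",
]

# Desk profile: the small-problem study conditions (tiny widths, 10 epochs,
# 200 train / 40 val slices on 64x72 two-coil phantoms). The full profile
# records the published protocol for full-scale runs.
DESK_PROFILE = {
    "H": 64, "W": 72, "coils": 2, "sigma": 0.01, "n_train": 200, "n_val": 40,
    "epochs": 10, "batch_size": 2, "lr": 5e-3, "beta2": 0.99,
}
FULL_PROFILE = {
    "H": 384, "W": 396, "coils": 16, "epochs": 50, "lr": 1e-4,
}


@dataclass(frozen=True)
class TrainConfig:
    lr: float = 1e-4
    epochs: int = 50
    batch_size: int = 4
    seed: int = 0
    betas: tuple = (0.9, 0.999)
    # augmentation deliberately absent: none is used

    def __post_init__(self):
        if self.lr <= 0:
            raise ValueError("learning rate must be positive")
        if self.epochs < 1:
            raise ValueError("need at least one epoch")


def l1_loss(pred: Tensor, target: Tensor | np.ndarray) -> Tensor:
    """Mean absolute difference."""
    if not isinstance(target, Tensor):
        target = Tensor(target)
    if pred.shape != target.shape:
        raise ValueError(f"shape mismatch: pred {pred.shape} vs target {target.shape}")
    return (pred - target).abs().mean()


def cosine_lr(epoch: int, total: int, lr0: float) -> float:
    """Cosine annealing: lr0 * (1 + cos(pi * epoch / total)) / 2."""
    if total <= 0:
        raise ValueError("total epochs must be positive")
    if not 0 <= epoch <= total:
        raise ValueError(f"epoch {epoch} outside [0, {total}]")
    return lr0 * (1.0 + math.cos(math.pi * epoch / total)) / 2.0


class Adam:
    """Adam optimiser over the autodiff parameter list."""

    def __init__(self, params, lr: float = 1e-4, betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)


@dataclass
class SliceDataset:
    """Preprocessed (folded image, masked k-space, reference) triples."""

    x: np.ndarray        # [N, H, W, 2C] normalised folded images
    k: np.ndarray        # [N, H, W, 2C] normalised packed masked k-space
    ref: np.ndarray      # [N, H, W] references in the same normalised scale as x
    scale: np.ndarray    # [N] per-sample zero-filled peak magnitudes
    ref_raw: np.ndarray  # [N, H, W] references in physical scale

    def __len__(self) -> int:
        return self.x.shape[0]


def acs_lines(W: int, R: int) -> int:
    """ACS width scaled from the published 396-line protocol (32 at R=4, 16 at R=8)."""
    return max(1, round(W * (128 / R) / 396))


def build_dataset(volume: Volume, R: int, pattern: str, n_acs: int | None = None,
                  mask_seed: int = 0) -> SliceDataset:
    """Retrospectively undersample a volume and fold it into network inputs.

    Random masks are drawn fresh for every slice (seeded); the regular mask
    is shared by all slices.
    """
    n, C, H, W = volume.kspace.shape
    if n_acs is None:
        n_acs = acs_lines(W, R)
    xs, ks, refs, scales = [], [], [], []
    for s in range(n):
        seed = (mask_seed * 65537 + s) % (2 ** 31) if pattern == "random" else mask_seed
        mask = make_mask(W, R, n_acs, pattern, seed=seed)
        km = apply_mask(volume.kspace[s], mask)
        folded = ifft2c(km)
        zf = rss(folded)
        scale = float(zf.max())
        if scale == 0:
            scale = 1.0
        x = pack_channels(folded) / scale
        kp = pack_channels(km)
        kmax = float(np.abs(kp).max())
        kp = kp / (kmax if kmax > 0 else 1.0)
        xs.append(x)
        ks.append(kp)
        refs.append(volume.reference[s] / scale)
        scales.append(scale)
    return SliceDataset(np.stack(xs), np.stack(ks), np.stack(refs),
                        np.array(scales), volume.reference.copy())


def zero_filled(dataset: SliceDataset) -> np.ndarray:
    """Zero-filled RSS reconstructions in physical scale, [N, H, W]."""
    out = np.empty_like(dataset.ref_raw)
    for i in range(len(dataset)):
        mag = np.sqrt((dataset.x[i] ** 2).sum(axis=-1))
        out[i] = mag * dataset.scale[i]
    return out


@dataclass
class TrainResult:
    history: list = field(default_factory=list)
    best_state: list | None = None
    best_val_nmse: float = math.inf


def _forward(model: Module, x: np.ndarray, k: np.ndarray) -> Tensor:
    return model(Tensor(x), Tensor(k))


def train(model: Module, train_ds: SliceDataset, val_ds: SliceDataset,
          config: TrainConfig) -> TrainResult:
    """Train with Adam + cosine schedule; keep the best-val-nMSE checkpoint.

    Deterministic for a fixed config seed (single-threaded numpy). Aborts
    with diagnostics if the loss goes non-finite.
    """
    rng = np.random.default_rng(config.seed)
    opt = Adam(model.parameters(), lr=config.lr, betas=config.betas)
    result = TrainResult()
    n = len(train_ds)
    for epoch in range(config.epochs):
        lr = cosine_lr(epoch, config.epochs, config.lr)
        opt.lr = lr
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            pred = _forward(model, train_ds.x[idx], train_ds.k[idx])
            loss = l1_loss(pred, train_ds.ref[idx])
            if not np.isfinite(loss.data):
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch}, lr {lr:.3g}, "
                    f"batch start {start}, batch mean |x| "
                    f"{np.abs(train_ds.x[idx]).mean():.3g}")
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        val_nmse = _validate(model, val_ds, config.batch_size)
        result.history.append({"epoch": epoch, "lr": lr,
                               "train_loss": float(np.mean(losses)),
                               "val_nmse": val_nmse})
        if val_nmse < result.best_val_nmse:
            result.best_val_nmse = val_nmse
            result.best_state = [p.copy() for p in model.state_arrays()]
    if result.best_state is not None:
        model.load_state_arrays(result.best_state)
    return result


def _validate(model: Module, ds: SliceDataset, batch_size: int) -> float:
    preds = reconstruct(model, ds, batch_size)
    return float(np.mean([nmse(ds.ref_raw[i], preds[i]) for i in range(len(ds))]))


def reconstruct(model: Module, dataset: SliceDataset, batch_size: int = 8) -> np.ndarray:
    """Per-slice predictions in physical scale; deterministic in eval mode."""
    out = np.empty_like(dataset.ref_raw)
    with no_grad():
        for start in range(0, len(dataset), batch_size):
            sl = slice(start, start + batch_size)
            pred = _forward(model, dataset.x[sl], dataset.k[sl])
            out[sl] = pred.data * dataset.scale[sl, None, None]
    return out


SCENARIOS = {
    "R4-regular": (4, "regular"),
    "R4-random": (4, "random"),
    "R8-regular": (8, "regular"),
    "R8-random": (8, "random"),
}


def run_comparison(scenarios=("R4-random",), variants=("model1", "model2", "model3"),
                   profile: dict | None = None, seed: int = 0,
                   include_zero_filled: bool = True, with_vif_ssim: bool = True) -> dict:
    """Train each variant on each undersampling scenario and tabulate metrics.

    Returns ``{scenario: {variant: {metric: {mean, std}}}}`` in the layout
    of the published comparison tables, computed on synthetic phantoms at
    the requested profile (desk scale by default).
    """
    prof = dict(DESK_PROFILE)
    if profile:
        prof.update(profile)
    report: dict = {}
    train_vol = make_volume(prof["n_train"], prof["coils"], prof["H"], prof["W"],
                            prof["sigma"], seed=seed * 7919 + 1)
    val_vol = make_volume(prof["n_val"], prof["coils"], prof["H"], prof["W"],
                          prof["sigma"], seed=seed * 7919 + 2)
    for scen in scenarios:
        R, pattern = SCENARIOS[scen]
        train_ds = build_dataset(train_vol, R, pattern, mask_seed=seed * 31 + 3)
        val_ds = build_dataset(val_vol, R, pattern, mask_seed=seed * 31 + 4)
        report[scen] = {}
        candidates = list(variants)
        for variant in candidates:
            cfg = tiny_config(variant, prof["H"], prof["W"], prof["coils"],
                              seed=seed * 131 + 5)
            # float32 training profile: halves memory traffic on CPU
            with default_dtype(np.float32):
                model = build(cfg)
                tc = TrainConfig(lr=prof["lr"], epochs=prof["epochs"],
                                 batch_size=prof["batch_size"], seed=seed * 131 + 6,
                                 betas=(0.9, prof.get("beta2", 0.999)))
                train(model, train_ds, val_ds, tc)
                preds = reconstruct(model, val_ds)
            report[scen][variant] = _metric_block(val_ds, preds, with_vif_ssim)
        if include_zero_filled:
            report[scen]["zero_filled"] = _metric_block(
                val_ds, zero_filled(val_ds), with_vif_ssim)
    return report


def _metric_block(ds: SliceDataset, preds: np.ndarray, with_vif_ssim: bool) -> dict:
    records = []
    for i in range(len(ds)):
        if with_vif_ssim:
            records.append(evaluate_pair(ds.ref_raw[i], preds[i]))
        else:
            records.append({"nmse_pct": nmse(ds.ref_raw[i], preds[i])})
    block = {}
    for key in records[0]:
        vals = np.array([r[key] for r in records])
        block[key] = {"mean": float(vals.mean()),
                      "std": float(vals.std(ddof=1)) if vals.size > 1 else 0.0}
    return block
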