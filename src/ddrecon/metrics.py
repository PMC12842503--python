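"""Reconstruction quality metrics: nMSE (%), SSIM and pixel-domain VIF.

nMSE is the squared error normalised by the reference energy, in percent.
SSIM uses Gaussian-weighted 7x7 windows (K1=0.01, K2=0.03) with the data
range taken from the reference maximum. VIF is the pixel-domain visual
information fidelity: the ratio of the information the distorted image and
the reference each carry about the underlying scene under a Gaussian
scale-mixture source model, accumulated over a 4-level Gaussian pyramid
with stabilising noise variance 2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import correlate

__all__ = ["nmse", "ssim", "vif", "aggregate", "MetricsReport", "evaluate_pair"]


def _check_pair(ref: np.ndarray, rec: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    ref = np.asarray(ref, dtype=np.float64)
    rec = np.asarray(rec, dtype=np.float64)
    if ref.shape != rec.shape:
        raise ValueError(f"shape mismatch: ref {ref.shape} vs rec {rec.shape}")
    return ref, rec


def nmse(ref: np.ndarray, rec: np.ndarray) -> float:
    """100 * ||ref - rec||_F^2 / ||ref||_F^2."""
    ref, rec = _check_pair(ref, rec)
    denom = float((ref ** 2).sum())
    if denom == 0.0:
        raise ValueError("nMSE undefined for an all-zero reference")
    return 100.0 * float(((ref - rec) ** 2).sum()) / denom


def ssim(ref: np.ndarray, rec: np.ndarray) -> float:
    """Mean local SSIM, Gaussian-weighted 7x7 windows (sigma 1.5), K1=0.01,
    K2=0.03, data range = max(ref); the mean is taken over the interior map
    (3-pixel crop), reflect boundary handling.

    Implemented directly: library SSIMs tie the Gaussian kernel size to a
    fixed truncation radius and cannot realise an exact 7x7 window.
    """
    ref, rec = _check_pair(ref, rec)
    if min(ref.shape) < 7:
        raise ValueError(f"image {ref.shape} smaller than the 7x7 SSIM window")
    kern = _gaussian_kernel(7, 1.5)
    filt = lambda a: correlate(a, kern, mode="reflect")
    dr = float(ref.max())
    c1, c2 = (0.01 * dr) ** 2, (0.03 * dr) ** 2
    mu1, mu2 = filt(ref), filt(rec)
    s11 = filt(ref * ref) - mu1 * mu1
    s22 = filt(rec * rec) - mu2 * mu2
    s12 = filt(ref * rec) - mu1 * mu2
    smap = ((2 * mu1 * mu2 + c1) * (2 * s12 + c2)) / \
           ((mu1 * mu1 + mu2 * mu2 + c1) * (s11 + s22 + c2))
    return float(smap[3:-3, 3:-3].mean())


def _gaussian_kernel(n: int, sigma: float) -> np.ndarray:
    ax = np.arange(n) - (n - 1) / 2.0
    g = np.exp(-(ax ** 2) / (2 * sigma ** 2))
    k = np.outer(g, g)
    return k / k.sum()


def vif(ref: np.ndarray, rec: np.ndarray, sigma_nsq: float = 2.0) -> float:
    """Pixel-domain visual information fidelity over 4 pyramid scales.

    At each scale the images are low-passed and decimated; local means,
    variances and covariance over a Gaussian window give the gain g and
    residual variance sv of the distortion-channel fit rec = g*ref + v, and
    the mutual-information ratio sums log(1 + g^2 sigma_ref^2 / (sv +
    sigma_n^2)) over log(1 + sigma_ref^2 / sigma_n^2).
    """
    ref, rec = _check_pair(ref, rec)
    if float(ref.max() - ref.min()) == 0.0:
        raise ValueError("VIF undefined for a constant reference")
    # the stabilising variance is calibrated for 8-bit luminance, so map the
    # reference range onto 0..255 (same affine map for both images)
    scale = 255.0 / float(ref.max() - ref.min())
    offset = float(ref.min())
    ref = (ref - offset) * scale
    rec = (rec - offset) * scale
    num = 0.0
    den = 0.0
    for scale in range(1, 5):
        n = 2 ** (4 - scale + 1) + 1
        kernel = _gaussian_kernel(n, n / 5.0)
        if scale > 1:
            ref = correlate(ref, kernel, mode="nearest")[::2, ::2]
            rec = correlate(rec, kernel, mode="nearest")[::2, ::2]
        mu1 = correlate(ref, kernel, mode="nearest")
        mu2 = correlate(rec, kernel, mode="nearest")
        mu1_sq, mu2_sq, mu1_mu2 = mu1 * mu1, mu2 * mu2, mu1 * mu2
        sigma1_sq = correlate(ref * ref, kernel, mode="nearest") - mu1_sq
        sigma2_sq = correlate(rec * rec, kernel, mode="nearest") - mu2_sq
        sigma12 = correlate(ref * rec, kernel, mode="nearest") - mu1_mu2
        sigma1_sq = np.maximum(sigma1_sq, 0.0)
        sigma2_sq = np.maximum(sigma2_sq, 0.0)
        eps = 1e-10
        g = sigma12 / (sigma1_sq + eps)
        sv_sq = sigma2_sq - g * sigma12
        # degenerate-window clamps of the reference pixel-domain formulation:
        # no reference variance -> no information transfer; negative gain -> 0
        low1 = sigma1_sq < eps
        g[low1] = 0.0
        sv_sq[low1] = sigma2_sq[low1]
        sigma1_sq = np.where(low1, 0.0, sigma1_sq)
        low2 = sigma2_sq < eps
        g[low2] = 0.0
        sv_sq[low2] = 0.0
        neg = g < 0
        sv_sq[neg] = sigma2_sq[neg]
        g[neg] = 0.0
        sv_sq = np.maximum(sv_sq, eps)
        num += float(np.log10(1.0 + g ** 2 * sigma1_sq / (sv_sq + sigma_nsq)).sum())
        den += float(np.log10(1.0 + sigma1_sq / sigma_nsq).sum())
    return num / den


@dataclass
class MetricsReport:
    """Per-item metric records with mean +/- std aggregation."""

    records: list = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    def aggregate(self) -> dict:
        if not self.records:
            raise ValueError("cannot aggregate an empty report")
        out = {}
        for key in ("nmse_pct", "ssim", "vif"):
            vals = np.array([r[key] for r in self.records], dtype=np.float64)
            std = float(vals.std(ddof=1)) if vals.size > 1 else 0.0
            out[key] = {"mean": float(vals.mean()), "std": std, "n": int(vals.size)}
        return out

    def as_dict(self) -> dict:
        return {"records": self.records, "aggregate": self.aggregate(),
                "meta": {**self.meta, "vif_variant": "pixel-domain"}}


def evaluate_pair(ref: np.ndarray, rec: np.ndarray) -> dict:
    return {"nmse_pct": nmse(ref, rec), "ssim": ssim(ref, rec), "vif": vif(ref, rec)}


def aggregate(records: list[dict], meta: dict | None = None) -> MetricsReport:
    """Bundle per-item records into a report with mean +/- std per metric."""
    report = MetricsReport(records=list(records), meta=meta or {})
    report.aggregate()  # validate non-empty
    return report
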