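"""Reconstruction quality metrics: PSNR and windowed SSIM.

PSNR is reported in decibels against the peak of the *reference* image:

    PSNR(x_hat, x) = 10 log10( max(x)^2 / MSE(x_hat, x) )

SSIM is the classic luminance/contrast/structure product

    SSIM = (2 mu_x mu_y + c1)(2 sigma_xy + c2) /
           ((mu_x^2 + mu_y^2 + c1)(sigma_x^2 + sigma_y^2 + c2))

computed per sliding window and averaged. Defaults: a uniform (unweighted)
7x7 window, k1 = 0.01, k2 = 0.03, dynamic range L = 1 for [0, 1] images,
with c1 = (k1 L)^2 and c2 = (k2 L)^2. Only fully-interior windows
contribute (valid mode), and window variances/covariances use the unbiased
(n-1) normalization — the conventions of the standard scikit-image
implementation, so the two agree to numerical precision when configured
identically. A Gaussian-weighted window is available behind a flag.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from ._exceptions import ShapeError, ValidationError
from ._validate import same_shape

__all__ = ["MetricsReport", "psnr", "ssim", "evaluate"]


@dataclass
class MetricsReport:
    psnr_db: float
    ssim: float
    window: int = 7
    k1: float = 0.01
    k2: float = 0.03
    dynamic_range: float = 1.0

    def to_dict(self) -> dict:
        return {
            "psnr_db": self.psnr_db,
            "ssim": self.ssim,
            "window": self.window,
            "k1": self.k1,
            "k2": self.k2,
            "dynamic_range": self.dynamic_range,
        }


def psnr(x_hat, x_ref, data_range: float | None = None) -> float:
    """Peak signal-to-noise ratio in dB; ``inf`` for identical images.

    The peak is ``max(x_ref)`` by default; pass ``data_range`` to use a
    fixed dynamic range L instead.
    """
    a = np.asarray(x_hat, dtype=np.float64)
    b = np.asarray(x_ref, dtype=np.float64)
    same_shape(a, b)
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ValidationError("images contain non-finite values")
    mse = float(np.mean((a - b) ** 2))
    if mse == 0.0:
        return float("inf")
    peak = float(b.max()) if data_range is None else float(data_range)
    if peak <= 0.0:
        raise ValidationError("reference peak must be positive for a finite PSNR")
    return 10.0 * np.log10(peak * peak / mse)


def _gaussian_window(size: int, sigma: float = 1.5) -> np.ndarray:
    ax = np.arange(size) - (size - 1) / 2.0
    g = np.exp(-(ax**2) / (2.0 * sigma**2))
    k = np.outer(g, g)
    return k / k.sum()


def ssim(
    x_hat,
    x_ref,
    window: int = 7,
    k1: float = 0.01,
    k2: float = 0.03,
    L: float = 1.0,
    gaussian_weights: bool = False,
) -> float:
    """Mean structural similarity over all fully-interior windows."""
    a = np.asarray(x_hat, dtype=np.float64)
    b = np.asarray(x_ref, dtype=np.float64)
    same_shape(a, b)
    if a.ndim != 2:
        raise ShapeError(f"images must be 2-D, got shape {a.shape}")
    if window < 2 or window % 2 == 0:
        raise ValidationError("window must be an odd integer >= 3")
    if min(a.shape) < window:
        raise ShapeError(
            f"image shape {a.shape} is smaller than the {window}x{window} window"
        )
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ValidationError("images contain non-finite values")

    pa = sliding_window_view(a, (window, window))
    pb = sliding_window_view(b, (window, window))
    n = window * window
    if gaussian_weights:
        w = _gaussian_window(window)
        mu_a = np.einsum("hwij,ij->hw", pa, w)
        mu_b = np.einsum("hwij,ij->hw", pb, w)
        var_a = np.einsum("hwij,ij->hw", pa * pa, w) - mu_a**2
        var_b = np.einsum("hwij,ij->hw", pb * pb, w) - mu_b**2
        cov = np.einsum("hwij,ij->hw", pa * pb, w) - mu_a * mu_b
    else:
        mu_a = pa.mean(axis=(-1, -2))
        mu_b = pb.mean(axis=(-1, -2))
        # unbiased window moments, matching the standard implementation
        norm = n / (n - 1.0)
        var_a = norm * (np.mean(pa * pa, axis=(-1, -2)) - mu_a**2)
        var_b = norm * (np.mean(pb * pb, axis=(-1, -2)) - mu_b**2)
        cov = norm * (np.mean(pa * pb, axis=(-1, -2)) - mu_a * mu_b)

    c1 = (k1 * L) ** 2
    c2 = (k2 * L) ** 2
    num = (2.0 * mu_a * mu_b + c1) * (2.0 * cov + c2)
    den = (mu_a**2 + mu_b**2 + c1) * (var_a + var_b + c2)
    return float(np.mean(num / den))


def evaluate(
    x_hat,
    x_ref,
    window: int = 7,
    k1: float = 0.01,
    k2: float = 0.03,
    dynamic_range: float = 1.0,
    peak_from_reference: bool = True,
) -> MetricsReport:
    """PSNR + SSIM in one report with the configured constants."""
    return MetricsReport(
        psnr_db=psnr(x_hat, x_ref, None if peak_from_reference else dynamic_range),
        ssim=ssim(x_hat, x_ref, window=window, k1=k1, k2=k2, L=dynamic_range),
        window=window,
        k1=k1,
        k2=k2,
        dynamic_range=dynamic_range,
    )
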