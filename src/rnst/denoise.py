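"""Pluggable denoising engines for the reconstruction's regularizer term.

The reconstruction update pulls the iterate toward a denoised copy of
itself, in the spirit of regularization-by-denoising where the regularizer
is built from an off-the-shelf denoiser ``f`` via ``rho(x) = 1/2 x.T (x - f(x))``.
The denoiser is a stateless pure function: same image and spec give a
bit-identical result.

Engines:

``bm3d``
    Block-matching and 3-D collaborative filtering, wrapped from the
    optional ``bm3d`` package; ``sigma`` is the assumed noise standard
    deviation on the [0, 1] scale.
``gaussian``
    Gaussian smoothing fallback (no extra dependency); ``kernel`` is the
    blur standard deviation in pixels. Reflect boundary padding avoids
    dark-frame artifacts that would bias the reconstruction residual at
    image edges.
``median``
    Median filter; ``kernel`` is the (odd) window width.
``identity``
    Returns the input unchanged (disables the regularizer's pull).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from ._exceptions import ConfigurationError, DependencyError
from ._validate import as_image

__all__ = ["DenoiserSpec", "denoise"]

_NAMES = ("bm3d", "gaussian", "median", "identity")


@dataclass(frozen=True)
class DenoiserSpec:
    """Which denoiser to apply and its strength parameters."""

    name: str = "gaussian"
    sigma: float = 20.0 / 255.0
    kernel: float = 1.0

    def __post_init__(self):
        if self.name not in _NAMES:
            raise ConfigurationError(
                f"unknown denoiser {self.name!r}; supported: {_NAMES}"
            )
        if self.name == "bm3d" and self.sigma <= 0:
            raise ConfigurationError("bm3d requires sigma > 0")
        if self.name == "gaussian" and self.kernel <= 0:
            raise ConfigurationError("gaussian requires kernel > 0")
        if self.name == "median":
            k = int(self.kernel)
            if k != self.kernel or k < 1 or k % 2 == 0:
                raise ConfigurationError("median kernel must be an odd integer >= 1")


def denoise(image, spec: DenoiserSpec) -> np.ndarray:
    """Apply the denoiser described by ``spec``; output is clamped to [0, 1]."""
    img = as_image(image)
    if spec.name == "identity":
        return img.copy()
    if spec.name == "gaussian":
        out = ndimage.gaussian_filter(img, sigma=spec.kernel, mode="reflect")
    elif spec.name == "median":
        out = ndimage.median_filter(img, size=int(spec.kernel), mode="reflect")
    else:  # bm3d
        try:
            import bm3d  # noqa: PLC0415 -- optional dependency
        except ImportError as exc:
            raise DependencyError(
                "the 'bm3d' denoiser requires the optional bm3d package "
                "(pip install bm3d); use name='gaussian' for a "
                "dependency-light fallback"
            ) from exc
        out = np.asarray(bm3d.bm3d(img, sigma_psd=spec.sigma), dtype=np.float64)
    return np.clip(out, 0.0, 1.0)
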