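"""Synthetic paired low-field / high-field brain-like phantoms.

Real paired data for field-transfer reconstruction (e.g. 1.5 T scans with a
registered 3 T reference) is access-restricted, so the pipeline is
exercised on seeded geometric phantoms that carry the two degradations a
lower field strength introduces relative to a higher one: an altered tissue
contrast and a higher noise floor.

A phantom is a composition of nested/overlapping ellipses at chosen tissue
intensities on a dark background ("high-field" contrast). The low-field
counterpart applies a strictly monotone contrast remap
``y = gain * x ** gamma`` (monotone, so tissue ordering is preserved
between field strengths) followed by additive white Gaussian noise at
``noise_sigma`` (default 20/255, i.e. a 0.08 noise level on the [0, 1]
scale) and clamping to [0, 1].

``make_pair`` mirrors the two guidance protocols used in evaluation:
*frozen* guidance draws a different-anatomy phantom (seed + 1) at
high-field contrast — the guidance shares only the style, not the content —
while *matched* guidance reuses the same anatomy.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Tuple

import numpy as np
from scipy import ndimage
from skimage.draw import ellipse

from ._exceptions import ConfigurationError, ValidationError
from ._validate import as_image

__all__ = ["PhantomSpec", "make_phantom", "degrade_to_lowfield", "make_pair"]

_MAX_RETRIES = 50


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry, contrast and corruption parameters of a phantom pair.

    size:
        Square side in pixels (64 is the test default; 256 matches a
        typical acquisition matrix for demos).
    n_ellipses:
        Number of ellipses drawn; the first is a large centered "head"
        ellipse, later ones are random interior structures painted on top.
    tissue_levels:
        Intensities in [0, 1] cycled over the ellipses (high-field contrast).
    lowfield_gain, lowfield_gamma:
        Parameters of the monotone contrast remap emulating the field shift.
    noise_sigma:
        AWGN standard deviation on the [0, 1] scale (default 20/255).
    psf_sigma:
        Gaussian point-spread blur (pixels) applied to the painted
        composition: MR images are band-limited by the acquisition, so a
        realistic phantom has no perfect step edges. Set 0 to disable.
    seed:
        Fixes both geometry and noise; generation is fully deterministic.
    """

    size: int = 64
    n_ellipses: int = 6
    tissue_levels: Tuple[float, ...] = (0.85, 0.35, 0.55, 0.7, 0.45)
    lowfield_gain: float = 0.85
    lowfield_gamma: float = 1.3
    noise_sigma: float = 20.0 / 255.0
    psf_sigma: float = 0.8
    seed: int = 0

    def __post_init__(self):
        if self.size < 32:
            raise ConfigurationError("size must be >= 32")
        if self.n_ellipses < 1:
            raise ConfigurationError("n_ellipses must be >= 1")
        if not self.tissue_levels or any(
            not (0.0 <= v <= 1.0) for v in self.tissue_levels
        ):
            raise ConfigurationError("tissue_levels must be non-empty, in [0, 1]")
        if self.lowfield_gain <= 0 or self.lowfield_gamma <= 0:
            raise ConfigurationError("contrast remap parameters must be positive")
        if self.noise_sigma < 0:
            raise ValidationError("noise_sigma must be nonnegative")
        if self.psf_sigma < 0:
            raise ConfigurationError("psf_sigma must be nonnegative")


# Fixed head-ellipse geometry (fractions of the image side). Axis-aligned so
# its rasterized area can be checked against the analytic pi*a*b.
_HEAD_AXES = (0.40, 0.34)


def make_phantom(spec: PhantomSpec) -> np.ndarray:
    """Deterministic brain-like ellipse composition at high-field contrast."""
    rng = np.random.default_rng([spec.seed, 0x0E11])
    s = spec.size
    img = np.zeros((s, s), dtype=np.float64)
    levels = spec.tissue_levels

    # Head outline: centered, fixed axes, painted first.
    rr, cc = ellipse(s / 2.0, s / 2.0, _HEAD_AXES[0] * s, _HEAD_AXES[1] * s,
                     shape=img.shape)
    img[rr, cc] = levels[0]

    for k in range(1, spec.n_ellipses):
        level = levels[k % len(levels)]
        for _ in range(_MAX_RETRIES):
            cy = rng.uniform(0.30, 0.70) * s
            cx = rng.uniform(0.30, 0.70) * s
            ry = rng.uniform(0.05, 0.22) * s
            rx = rng.uniform(0.05, 0.22) * s
            rot = rng.uniform(0.0, np.pi)
            if ry < 2.0 or rx < 2.0:
                continue
            rr, cc = ellipse(cy, cx, ry, rx, shape=img.shape, rotation=rot)
            if rr.size > 0:
                img[rr, cc] = level
                break
        else:
            raise ValidationError(
                f"could not place ellipse {k} after {_MAX_RETRIES} attempts"
            )
    if spec.psf_sigma > 0:
        img = ndimage.gaussian_filter(img, spec.psf_sigma, mode="constant")
    return np.clip(img, 0.0, 1.0)


def degrade_to_lowfield(image, spec: PhantomSpec) -> np.ndarray:
    """Contrast-remap then add seeded AWGN; emulates the lower-field scan."""
    img = as_image(image)
    out = img
    if spec.lowfield_gamma != 1.0:
        out = out**spec.lowfield_gamma
    if spec.lowfield_gain != 1.0:
        out = out * spec.lowfield_gain
    if spec.noise_sigma > 0:
        rng = np.random.default_rng([spec.seed, 0x401])
        out = out + rng.normal(0.0, spec.noise_sigma, size=out.shape)
    return np.clip(out, 0.0, 1.0)


def remap_contrast(image, spec: PhantomSpec) -> np.ndarray:
    """The noise-free part of the low-field degradation (monotone remap only)."""
    return degrade_to_lowfield(image, replace(spec, noise_sigma=0.0))


def make_pair(
    spec: PhantomSpec, mode: str = "frozen"
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Build ``(content, guidance, clean_reference)`` for a reconstruction run.

    ``clean_reference`` is the high-field phantom; ``content`` is its
    low-field degradation; ``guidance`` is a high-field-contrast phantom —
    different anatomy (seed + 1) in ``frozen`` mode, same anatomy in
    ``matched`` mode.
    """
    if mode not in ("frozen", "matched"):
        raise ConfigurationError(f"mode must be 'frozen' or 'matched', got {mode!r}")
    clean = make_phantom(spec)
    content = degrade_to_lowfield(clean, spec)
    if mode == "matched":
        guidance = clean.copy()
    else:
        guidance = make_phantom(replace(spec, seed=spec.seed + 1))
    return content, guidance, clean
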