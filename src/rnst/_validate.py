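"""Input validation helpers for 2-D intensity images."""

from __future__ import annotations

import numpy as np

from ._exceptions import ShapeError, ValidationError

# Slack for images that drift marginally outside [0, 1] through float round-off.
_RANGE_TOL = 1e-9


def as_image(x, *, name: str = "image") -> np.ndarray:
    """Coerce ``x`` to a float64 2-D array in [0, 1] and validate it."""
    arr = np.asarray(x, dtype=np.float64)
    if arr.ndim != 2:
        raise ShapeError(f"{name} must be 2-D, got shape {arr.shape}")
    if arr.size == 0:
        raise ShapeError(f"{name} is empty")
    if not np.isfinite(arr).all():
        raise ValidationError(f"{name} contains non-finite pixels")
    if arr.min() < -_RANGE_TOL or arr.max() > 1.0 + _RANGE_TOL:
        raise ValidationError(
            f"{name} must lie in [0, 1]; got range "
            f"[{arr.min():.6g}, {arr.max():.6g}]"
        )
    return np.clip(arr, 0.0, 1.0)


def same_shape(a: np.ndarray, b: np.ndarray, *, what: str = "images") -> None:
    if a.shape != b.shape:
        raise ShapeError(f"{what} have mismatched shapes {a.shape} vs {b.shape}")
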