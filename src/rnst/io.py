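"""File I/O: slice loading from NIfTI volumes and 2-D rasters, intensity
normalization, 16-bit PNG round-tripping, and run manifests for exact replay.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import imageio.v3 as iio
import numpy as np

from ._exceptions import ConfigurationError, ValidationError
from ._validate import as_image

__all__ = [
    "load_slice",
    "normalize_intensity",
    "save_image",
    "load_image",
    "RunManifest",
]

_AXES = {"sagittal": 0, "coronal": 1, "axial": 2}
_NIFTI_SUFFIXES = (".nii", ".nii.gz")


def _is_nifti(path: Path) -> bool:
    name = path.name.lower()
    return any(name.endswith(s) for s in _NIFTI_SUFFIXES)


def normalize_intensity(
    image,
    method: str = "percentile",
    p_low: float = 0.5,
    p_high: float = 99.5,
) -> np.ndarray:
    """Map a raw raster to [0, 1].

    ``minmax`` maps [min, max] -> [0, 1] and rejects constant images;
    ``percentile`` maps [P(p_low), P(p_high)] -> [0, 1] with clipping,
    which is robust to the extreme outlier voxels MRI volumes routinely
    contain (the default for the pipeline).
    """
    arr = np.asarray(image, dtype=np.float64)
    if not np.isfinite(arr).all():
        raise ValidationError("image contains non-finite values")
    if method == "minmax":
        lo, hi = float(arr.min()), float(arr.max())
        if hi == lo:
            raise ValidationError(
                "constant image cannot be min-max normalized; use "
                "method='percentile' with explicit bounds"
            )
    elif method == "percentile":
        if not (0.0 <= p_low < p_high <= 100.0):
            raise ConfigurationError("need 0 <= p_low < p_high <= 100")
        lo, hi = (float(v) for v in np.percentile(arr, [p_low, p_high]))
        if hi == lo:
            raise ValidationError("degenerate percentile range; widen the bounds")
    else:
        raise ConfigurationError(f"unknown normalization method {method!r}")
    return np.clip((arr - lo) / (hi - lo), 0.0, 1.0)


def load_slice(
    path,
    slice_index: int = 0,
    axis: str = "axial",
    normalize: Optional[str] = "percentile",
    p_low: float = 0.5,
    p_high: float = 99.5,
) -> np.ndarray:
    """Load a 2-D image from a NIfTI volume (one plane) or a raster file.

    For volumes, the axis labels are resolved through the stored orientation
    metadata (the volume is reoriented to the closest RAS canonical form, so
    axial = third axis, coronal = second, sagittal = first), never raw array
    order. 4-D volumes are rejected: pre-select a 3-D volume first.
    ``normalize=None`` returns raw intensities.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"no such file: {path}")
    if _is_nifti(path):
        import nibabel as nib

        vol = nib.as_closest_canonical(nib.load(str(path)))
        data = np.asanyarray(vol.dataobj)
        if data.ndim == 4:
            if data.shape[3] == 1:
                data = data[..., 0]
            else:
                raise ValidationError(
                    f"{path} is 4-D with {data.shape[3]} frames; pre-select a "
                    "3-D volume before slicing"
                )
        if data.ndim != 3:
            raise ValidationError(f"{path}: expected a 3-D volume, got {data.shape}")
        if axis not in _AXES:
            raise ConfigurationError(
                f"axis must be one of {sorted(_AXES)}, got {axis!r}"
            )
        ax = _AXES[axis]
        n = data.shape[ax]
        if not (0 <= slice_index < n):
            raise ValidationError(
                f"slice_index {slice_index} out of range [0, {n}) along {axis}"
            )
        plane = np.take(data, slice_index, axis=ax).astype(np.float64)
    else:
        raw = iio.imread(path)
        if raw.ndim == 3:
            if raw.shape[2] in (3, 4):  # collapse RGB(A) written from grayscale
                raw = raw[..., :3].mean(axis=2)
            else:
                raise ValidationError(f"{path}: expected a 2-D grayscale raster")
        if raw.ndim != 2:
            raise ValidationError(f"{path}: expected a 2-D raster, got {raw.shape}")
        plane = np.asarray(raw, dtype=np.float64)
    if normalize is None:
        return plane
    return normalize_intensity(plane, method=normalize, p_low=p_low, p_high=p_high)


def save_image(path, image) -> None:
    """Write a [0, 1] raster; PNG is quantized to 16 bit, TIFF kept float."""
    path = Path(path)
    img = as_image(image)
    suffix = path.suffix.lower()
    if suffix == ".png":
        iio.imwrite(path, np.round(img * 65535.0).astype(np.uint16))
    elif suffix in (".tif", ".tiff"):
        import tifffile

        tifffile.imwrite(path, img.astype(np.float32))
    else:
        raise ConfigurationError(f"unsupported output format {suffix!r}")


def load_image(path) -> np.ndarray:
    """Read a raster written by :func:`save_image` back onto the [0, 1] scale."""
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix == ".png":
        raw = iio.imread(path)
        info = np.iinfo(raw.dtype) if np.issubdtype(raw.dtype, np.integer) else None
        arr = np.asarray(raw, dtype=np.float64)
        if info is not None:
            arr = arr / info.max
        return arr
    if suffix in (".tif", ".tiff"):
        return np.asarray(iio.imread(path), dtype=np.float64)
    raise ConfigurationError(f"unsupported input format {suffix!r}")


@dataclass
class RunManifest:
    """Everything needed to reproduce a reconstruction bit-identically."""

    content_path: str
    guidance_path: str
    content_slice: int = 0
    guidance_slice: int = 0
    axis: str = "axial"
    seed: int = 0
    backbone: dict = field(default_factory=dict)
    nst: dict = field(default_factory=dict)
    rnst: dict = field(default_factory=dict)
    denoiser: dict = field(default_factory=dict)
    normalization: dict = field(default_factory=dict)
    version: str = ""
    trace_path: Optional[str] = None

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, sort_keys=True))

    @classmethod
    def load(cls, path) -> "RunManifest":
        return cls(**json.loads(Path(path).read_text()))
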