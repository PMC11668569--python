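"""Raster containers and file round-tripping.

Conventions used throughout the package:

* coordinates are 0-based, row-major; rectangles are half-open
  ``[row0, row1) x [col0, col1)``;
* disease is the positive class and carries label 1 in every in-memory
  :class:`BinaryMask`; on disk the convention is inverted (gray value 0 =
  disease, 255 = healthy), matching common ground-truth map encodings where
  affected crowns are drawn black.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Union

import numpy as np
from PIL import Image

logger = logging.getLogger(__name__)

__all__ = [
    "RGBImage",
    "BinaryMask",
    "Region",
    "FormatError",
    "read_rgb",
    "read_ground_truth",
    "write_rgb",
    "write_mask",
    "crop",
]

_TIFF_SUFFIXES = {".tif", ".tiff", ".gtiff"}
# GeoTIFF tag codes carried opaquely through a read/write round trip.
_GEO_TAGS = (33550, 33922, 34264, 34735, 34736, 34737, 42112, 42113)


class FormatError(ValueError):
    """Raised when a raster file does not match the expected format."""


@dataclass(frozen=True)
class Region:
    """Half-open rectangle ``[row0, row1) x [col0, col1)``, 0-based."""

    row0: int
    col0: int
    row1: int
    col1: int

    def __post_init__(self) -> None:
        if not (0 <= self.row0 < self.row1 and 0 <= self.col0 < self.col1):
            raise ValueError(f"degenerate or negative region {self}")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.row1 - self.row0, self.col1 - self.col0)

    def check_within(self, shape: tuple[int, int]) -> None:
        if self.row1 > shape[0] or self.col1 > shape[1]:
            raise ValueError(f"region {self} exceeds image shape {shape}")

    @property
    def slices(self) -> tuple[slice, slice]:
        return (slice(self.row0, self.row1), slice(self.col0, self.col1))


@dataclass
class RGBImage:
    """8-bit three-band raster, shape ``(H, W, 3)``, values 0-255."""

    array: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        a = np.asarray(self.array)
        if a.ndim != 3 or a.shape[2] != 3:
            raise ValueError(f"expected (H, W, 3) array, got shape {a.shape}")
        if a.shape[0] < 1 or a.shape[1] < 1:
            raise ValueError("image must have at least one pixel")
        if a.dtype != np.uint8:
            if np.any(a < 0) or np.any(a > 255):
                raise ValueError("band values must lie in [0, 255]")
            a = a.astype(np.uint8)
        self.array = a

    @property
    def shape(self) -> tuple[int, int]:
        return self.array.shape[:2]

    @property
    def red(self) -> np.ndarray:
        return self.array[..., 0]

    @property
    def green(self) -> np.ndarray:
        return self.array[..., 1]

    @property
    def blue(self) -> np.ndarray:
        return self.array[..., 2]


@dataclass
class BinaryMask:
    """Label raster: 1 = diseased (positive), 0 = healthy."""

    array: np.ndarray

    def __post_init__(self) -> None:
        a = np.asarray(self.array)
        if a.ndim != 2:
            raise ValueError(f"mask must be 2-D, got shape {a.shape}")
        if a.size == 0:
            raise ValueError("empty mask")
        if not np.isin(a, (0, 1)).all():
            raise ValueError("mask labels must be 0 or 1")
        self.array = a.astype(np.uint8)

    @property
    def shape(self) -> tuple[int, int]:
        return self.array.shape


GrayImage = np.ndarray  # H x W float plane (raw index scale or [0, 1])
Raster = Union[RGBImage, BinaryMask, np.ndarray]


def _load_array(path: Path) -> tuple[np.ndarray, dict]:
    if path.suffix.lower() in _TIFF_SUFFIXES:
        import tifffile

        with tifffile.TiffFile(path) as tf:
            page = tf.pages[0]
            meta = {}
            for code in _GEO_TAGS:
                if code in page.tags:
                    tag = page.tags[code]
                    meta[code] = (tag.dtype, tag.count, tag.value)
            return page.asarray(), {"geotiff_tags": meta} if meta else {}
    with Image.open(path) as im:
        return np.asarray(im), {}


def read_rgb(path) -> RGBImage:
    """Read a 3-band 8-bit raster (PNG/JPEG/GeoTIFF).

    Extra bands (e.g. alpha) are dropped with a warning; non-8-bit files are
    rejected rather than silently rescaled.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    arr, meta = _load_array(path)
    if arr.ndim != 3 or arr.shape[2] < 3:
        raise FormatError(f"{path}: expected >= 3 bands, got shape {arr.shape}")
    if arr.dtype != np.uint8:
        raise FormatError(
            f"{path}: unsupported bit depth {arr.dtype.itemsize * 8}-bit "
            f"({arr.dtype}); expected 8-bit"
        )
    if arr.shape[2] > 3:
        logger.warning("%s: dropping %d extra band(s)", path, arr.shape[2] - 3)
        warnings.warn(f"{path}: dropping {arr.shape[2] - 3} extra band(s)")
        arr = arr[:, :, :3]
    return RGBImage(arr.copy(), meta)


def read_ground_truth(path) -> BinaryMask:
    """Read a black=disease / white=healthy truth image into a BinaryMask.

    File values below 128 map to disease (label 1), others to healthy; a
    warning is issued if any value is neither 0 nor 255.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    arr, _ = _load_array(path)
    if arr.ndim != 2:
        raise FormatError(f"{path}: ground truth must be single-band, got shape {arr.shape}")
    if arr.dtype != np.uint8:
        raise FormatError(f"{path}: ground truth must be 8-bit, got {arr.dtype}")
    if not np.isin(arr, (0, 255)).all():
        warnings.warn(
            f"{path}: truth image contains values other than 0/255; "
            "thresholding at 128"
        )
    return BinaryMask((arr < 128).astype(np.uint8))


def _save_array(arr: np.ndarray, path: Path, meta: dict | None = None) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    if path.suffix.lower() in _TIFF_SUFFIXES:
        import tifffile

        extratags = []
        if meta:
            for code, (dtype, count, value) in meta.get("geotiff_tags", {}).items():
                extratags.append((code, dtype, count, value, True))
        tifffile.imwrite(path, arr, extratags=extratags)
    else:
        Image.fromarray(arr).save(path)


def write_rgb(image: RGBImage, path) -> None:
    """Write an RGBImage as PNG or GeoTIFF (tags passed through)."""
    _save_array(image.array, Path(path), image.meta)


def write_mask(mask: BinaryMask, path) -> None:
    """Write a BinaryMask with the on-disk convention 0 = disease, 255 = healthy."""
    encoded = np.where(mask.array == 1, 0, 255).astype(np.uint8)
    _save_array(encoded, Path(path))


def crop(raster: Raster, region: Region) -> Raster:
    """Crop any raster type to a half-open rectangle, preserving its type."""
    if isinstance(raster, RGBImage):
        region.check_within(raster.shape)
        return RGBImage(raster.array[region.slices].copy(), dict(raster.meta))
    if isinstance(raster, BinaryMask):
        region.check_within(raster.shape)
        return BinaryMask(raster.array[region.slices].copy())
    arr = np.asarray(raster)
    region.check_within(arr.shape[:2])
    return arr[region.slices].copy()
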