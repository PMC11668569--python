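"""The 24 visible-band vegetation indices plus the raw R, G, B planes.

Each index is an arithmetic combination of the red, green and blue bands
designed to enhance the contrast between healthy (green) and stressed
(brown/gray) vegetation without any near-infrared information. Two band
conventions coexist in the literature and in the formula registry below:

* **raw bands** ``R, G, B`` — pixel values scaled to [0, 1] (value / 255);
* **chromatic coordinates** ``r, g, b`` — brightness-normalized values
  ``r = R / (R + G + B)`` etc., which remove overall illumination.

Indices printed with lower-case symbols (CIVE, GLI, VI) use chromatic
coordinates; word-form and upper-case formulas use raw bands. The registry
records the convention per index so it can be audited and, for the ambiguous
GLI, overridden.

All division uses a signed denominator guard ``max(|den|, eps)`` and any
residual non-finite pixels are replaced by the plane's finite median before
the plane is min-max normalized to [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .io import GrayImage, Region, RGBImage

__all__ = [
    "INDEX_NAMES",
    "ALL_FEATURES",
    "IndexStack",
    "ChromaticCoords",
    "chromatic_coords",
    "compute_raw_index",
    "normalize_plane",
    "compute_stack",
]

EPS = 1e-8
_VEG_A = 0.667


@dataclass(frozen=True)
class ChromaticCoords:
    """Brightness-normalized band planes; r + g + b = 1 where R+G+B > 0."""

    r: np.ndarray
    g: np.ndarray
    b: np.ndarray


def chromatic_coords(image: RGBImage) -> ChromaticCoords:
    """r = R/(R+G+B) etc.; black pixels (sum 0) map to (0, 0, 0)."""
    R = image.red.astype(np.float64)
    G = image.green.astype(np.float64)
    B = image.blue.astype(np.float64)
    total = R + G + B
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(total > 0, R / np.maximum(total, EPS), 0.0)
        g = np.where(total > 0, G / np.maximum(total, EPS), 0.0)
        b = np.where(total > 0, B / np.maximum(total, EPS), 0.0)
    return ChromaticCoords(r, g, b)


def _safe_div(num: np.ndarray, den: np.ndarray) -> np.ndarray:
    """Division with a signed denominator floor of EPS (zero counts as +)."""
    sign = np.where(den < 0, -1.0, 1.0)
    guarded = sign * np.maximum(np.abs(den), EPS)
    return num / guarded


# --- raw-band formulas (bands scaled to [0, 1]) ------------------------------

def _exg(R, G, B, r, g, b):
    return 2.0 * G - R - B


def _tgi(R, G, B, r, g, b):
    return G - 0.39 * R - 0.61 * B


def _gbdi(R, G, B, r, g, b):
    return G - B


def _mexg(R, G, B, r, g, b):
    return 1.26 * G - 0.884 * R - 0.311 * B


def _exr(R, G, B, r, g, b):
    return 1.4 * R - G


def _exgr(R, G, B, r, g, b):
    return _exg(R, G, B, r, g, b) - _exr(R, G, B, r, g, b)


def _veg(R, G, B, r, g, b):
    # band values 0 are lifted to EPS before exponentiation so the
    # denominator R^a * B^(1-a) stays finite and order-preserving
    Rs = np.clip(R, EPS, 1.0)
    Bs = np.clip(B, EPS, 1.0)
    return _safe_div(G, Rs ** _VEG_A * Bs ** (1.0 - _VEG_A))


def _vdvi(R, G, B, r, g, b):
    return _safe_div(2.0 * G - R - B, 2.0 * G + R + B)


def _cive(R, G, B, r, g, b):
    return 0.441 * r - 0.811 * g + 0.385 * b + 18.78745


def _ngrdi(R, G, B, r, g, b):
    return _safe_div(G - R, G + R)


def _rgri(R, G, B, r, g, b):
    return _safe_div(R, G)


def _vari(R, G, B, r, g, b):
    return _safe_div(G - R, G + R - B)


def _mgrvi(R, G, B, r, g, b):
    return _safe_div(G**2 - R**2, G**2 + R**2)


def _egrbdi(R, G, B, r, g, b):
    return _safe_div((2.0 * G) ** 2 - R * B, (2.0 * G) ** 2 + R * B)


def _rgbri(R, G, B, r, g, b):
    return _safe_div(G**2 - R * B, G**2 + R * B)


def _engbdi(R, G, B, r, g, b):
    return _safe_div(G**2 - B**2, G**2 + B**2)


def _gli(R, G, B, r, g, b):
    return _safe_div(2.0 * g - r - b, 2.0 * g + r + b)


def _exb(R, G, B, r, g, b):
    return _safe_div(1.4 * B - G, G + R + B)


def _ikaw(R, G, B, r, g, b):
    return _safe_div(R - B, R + B)


def _com1(R, G, B, r, g, b):
    return (
        _exg(R, G, B, r, g, b)
        + _cive(R, G, B, r, g, b)
        + _exgr(R, G, B, r, g, b)
        + _veg(R, G, B, r, g, b)
    )


def _com2(R, G, B, r, g, b):
    return (
        0.36 * _exg(R, G, B, r, g, b)
        + 0.47 * _cive(R, G, B, r, g, b)
        + 0.17 * _veg(R, G, B, r, g, b)
    )


def _gbri(R, G, B, r, g, b):
    return _safe_div(B, R)


def _wi(R, G, B, r, g, b):
    return _safe_div(G - B, R - G)


def _vi(R, G, B, r, g, b):
    return (2.0 * g - r - b) - (1.4 * r - g)


# name -> (formula, band convention). "raw" = [0,1]-scaled bands,
# "chromatic" = r,g,b coordinates, "mixed" = composite of both.
_REGISTRY: dict[str, tuple[Callable, str]] = {
    "ExG": (_exg, "raw"),
    "TGI": (_tgi, "raw"),
    "GBDI": (_gbdi, "raw"),
    "MExG": (_mexg, "raw"),
    "ExR": (_exr, "raw"),
    "ExGR": (_exgr, "raw"),
    "VEG": (_veg, "raw"),
    "VDVI": (_vdvi, "raw"),
    "CIVE": (_cive, "chromatic"),
    "NGRDI": (_ngrdi, "raw"),
    "RGRI": (_rgri, "raw"),
    "VARI": (_vari, "raw"),
    "MGRVI": (_mgrvi, "raw"),
    "EGRBDI": (_egrbdi, "raw"),
    "RGBRI": (_rgbri, "raw"),
    "E-NGBDI": (_engbdi, "raw"),
    "GLI": (_gli, "chromatic"),
    "ExB": (_exb, "raw"),
    "IKAW": (_ikaw, "raw"),
    "COM1": (_com1, "mixed"),
    "COM2": (_com2, "mixed"),
    "GBRI": (_gbri, "raw"),
    "WI": (_wi, "raw"),
    "VI": (_vi, "chromatic"),
}

INDEX_NAMES: tuple[str, ...] = tuple(_REGISTRY)
BAND_NAMES: tuple[str, ...] = ("R", "G", "B")
ALL_FEATURES: tuple[str, ...] = INDEX_NAMES + BAND_NAMES


def index_convention(name: str) -> str:
    """Band convention ('raw', 'chromatic' or 'mixed') of a registry index."""
    return _REGISTRY[name][1]


def compute_raw_index(image: RGBImage, name: str) -> GrayImage:
    """Evaluate one index formula on its raw scale (no normalization).

    Non-finite pixels left by degenerate denominators are replaced by the
    plane's finite median so that a handful of pathological pixels cannot
    dominate the later min-max normalization.
    """
    if name in BAND_NAMES:
        return image.array[..., BAND_NAMES.index(name)].astype(np.float64) / 255.0
    if name not in _REGISTRY:
        raise KeyError(f"unknown index {name!r}; known: {sorted(ALL_FEATURES)}")
    R = image.red.astype(np.float64) / 255.0
    G = image.green.astype(np.float64) / 255.0
    B = image.blue.astype(np.float64) / 255.0
    cc = chromatic_coords(image)
    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        plane = _REGISTRY[name][0](R, G, B, cc.r, cc.g, cc.b)
    plane = np.asarray(plane, dtype=np.float64)
    bad = ~np.isfinite(plane)
    if bad.any():
        finite = plane[~bad]
        fill = float(np.median(finite)) if finite.size else 0.0
        plane = plane.copy()
        plane[bad] = fill
    return plane


def normalize_plane(raw: GrayImage) -> GrayImage:
    """Min-max normalize a finite plane into [0, 1]; constant planes -> 0.5."""
    raw = np.asarray(raw, dtype=np.float64)
    lo = raw.min()
    hi = raw.max()
    if hi == lo:
        return np.full_like(raw, 0.5)
    return (raw - lo) / (hi - lo)


@dataclass
class IndexStack:
    """Ordered collection of normalized [0, 1] feature planes of one shape."""

    names: tuple[str, ...]
    planes: np.ndarray  # (n_features, H, W)

    def __post_init__(self) -> None:
        self.names = tuple(self.names)
        if len(self.names) != len(set(self.names)):
            raise ValueError("duplicate feature names")
        self.planes = np.asarray(self.planes, dtype=np.float64)
        if self.planes.ndim != 3 or self.planes.shape[0] != len(self.names):
            raise ValueError("planes must be (n_features, H, W) matching names")

    @property
    def shape(self) -> tuple[int, int]:
        return self.planes.shape[1:]

    def plane(self, name: str) -> GrayImage:
        return self.planes[self.names.index(name)]

    def subset(self, names: Sequence[str]) -> "IndexStack":
        idx = [self.names.index(n) for n in names]
        return IndexStack(tuple(names), self.planes[idx])

    def crop(self, region: Region) -> "IndexStack":
        region.check_within(self.shape)
        return IndexStack(self.names, self.planes[(slice(None),) + region.slices])

    def as_table(self) -> np.ndarray:
        """Pixels-by-features matrix (row-major pixel order)."""
        return self.planes.reshape(len(self.names), -1).T


def compute_stack(image: RGBImage, names: Sequence[str] | None = None) -> IndexStack:
    """Compute normalized feature planes for the named indices/bands.

    Index planes are min-max normalized per plane over the whole image; the
    R, G, B planes are the raw bands divided by 255.
    """
    if names is None:
        names = ALL_FEATURES
    names = tuple(names)
    if not names:
        raise ValueError("at least one feature name is required")
    if len(names) != len(set(names)):
        raise ValueError("duplicate feature names")
    unknown = [n for n in names if n not in ALL_FEATURES]
    if unknown:
        raise KeyError(f"unknown feature names {unknown}")
    planes = np.empty((len(names),) + image.shape, dtype=np.float64)
    for i, name in enumerate(names):
        raw = compute_raw_index(image, name)
        planes[i] = raw if name in BAND_NAMES else normalize_plane(raw)
    return IndexStack(names, planes)
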