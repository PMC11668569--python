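"""Nine automatic threshold-segmentation methods over normalized gray planes.

All methods operate on [0, 1] planes quantized to 256 gray levels
(``round(255 * x)``), the 8-bit convention of the source imagery. Global
methods return a threshold ``t`` on the 0-255 scale and classify a pixel as
the *low* class when its level is ``< t``; with the default polarity the low
(dark) class is disease. Local/adaptive methods (block Otsu, local dynamic,
Wellner) return a mask directly.

Deterministic tie-breaking: every argmax/argmin scan over candidate
thresholds picks the smallest gray level among the optima.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Literal

import numpy as np
from scipy.ndimage import uniform_filter
from scipy.signal import lfilter

from .io import BinaryMask, GrayImage

__all__ = [
    "METHODS",
    "ThresholdParams",
    "DegenerateImageError",
    "quantize",
    "binarize",
    "otsu",
    "block_otsu",
    "local_dynamic",
    "wellner_adaptive",
    "max_entropy",
    "double_peak",
    "min_error",
    "iterative_threshold",
    "combined_global_local",
    "segment",
]

METHODS = ("otsu", "botsu", "ldt", "wat", "met", "dpm", "mem", "itm", "cglt")

Polarity = Literal["low_is_positive", "high_is_positive", "auto"]


class DegenerateImageError(ValueError):
    """Raised when a thresholder's input has a single gray level."""


@dataclass(frozen=True)
class ThresholdParams:
    """Parameters for the nine methods; unused fields are ignored per method.

    block: cell size for block Otsu (pixels). window_r: neighborhood size for
    the local dynamic threshold (odd). k, R: its correction factor and
    standard-deviation dynamic range. s: Wellner running-average length
    (pixels; None = width / 8). t_pct: Wellner percentage margin. eps:
    stopping tolerance (gray levels) of the iterative methods.
    """

    method: str = "otsu"
    block: int = 100
    window_r: int = 15
    k: float = 0.2
    R: float = 128.0
    s: int | None = None
    t_pct: float = 15.0
    eps: float = 0.5
    polarity: Polarity = "auto"
    kittler: bool = False  # minimum-error: classical log criterion variant

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"unknown method {self.method!r}; known: {METHODS}")
        if not 0.0 < self.k < 1.0:
            raise ValueError("k must lie in (0, 1)")
        if self.block < 8:
            raise ValueError("block must be >= 8 pixels")
        if self.s is not None and self.s < 1:
            raise ValueError("s must be >= 1")
        if not 0.0 <= self.t_pct < 100.0:
            raise ValueError("t_pct must lie in [0, 100)")
        if self.window_r < 3 or self.window_r % 2 == 0:
            raise ValueError("window_r must be odd and >= 3")


def quantize(gray: GrayImage) -> np.ndarray:
    """[0, 1] plane -> integer gray levels 0..255."""
    return np.clip(np.rint(np.asarray(gray) * 255.0), 0, 255).astype(np.int64)


def _histogram(levels: np.ndarray) -> np.ndarray:
    return np.bincount(levels.ravel(), minlength=256).astype(np.float64)


def _check_nonconstant(levels: np.ndarray) -> None:
    if levels.min() == levels.max():
        raise DegenerateImageError("constant image: no threshold separates it")


def _first_max(crit: np.ndarray) -> int:
    """Smallest index attaining the maximum, with a relative tolerance so
    that exact criterion plateaus (empty-bin spans) are tie-broken
    identically regardless of floating-point summation order."""
    m = crit.max()
    tol = 1e-10 * max(1.0, abs(m))
    return int(np.argmax(crit >= m - tol))


def _first_min(crit: np.ndarray) -> int:
    m = crit.min()
    tol = 1e-10 * max(1.0, abs(m))
    return int(np.argmax(crit <= m + tol))


def binarize(gray: GrayImage, threshold, polarity: Polarity = "low_is_positive") -> BinaryMask:
    """Apply a global or per-pixel threshold on the 0-255 level scale.

    ``low_is_positive`` labels 1 where ``level < threshold`` (disease is
    dark); ``high_is_positive`` inverts; ``auto`` picks the orientation whose
    positive class has the lower mean gray level.
    """
    levels = quantize(gray)
    low = levels < np.asarray(threshold)
    if polarity == "high_is_positive":
        mask = ~low
    elif polarity == "auto":
        mask = _auto_orient(levels, low)
    else:
        mask = low
    return BinaryMask(mask.astype(np.uint8))


def _auto_orient(levels: np.ndarray, positive: np.ndarray) -> np.ndarray:
    """Flip the mask if its positive class is not the darker one."""
    n_pos = positive.sum()
    if n_pos == 0 or n_pos == positive.size:
        return positive
    if levels[positive].mean() > levels[~positive].mean():
        return ~positive
    return positive


# ---------------------------------------------------------------------------
# global histogram criteria
# ---------------------------------------------------------------------------

def _class_stats(hist: np.ndarray):
    """Cumulative weights/means for splits t=1..255 (low class = levels < t)."""
    p = hist / hist.sum()
    levels = np.arange(256, dtype=np.float64)
    w0 = np.cumsum(p)[:-1]  # w0[t-1] = P(level < t)
    w1 = 1.0 - w0
    cum_mean = np.cumsum(p * levels)[:-1]
    mu = (p * levels).sum()
    return p, w0, w1, cum_mean, mu


def otsu(gray: GrayImage) -> int:
    """Between-class-variance-maximizing threshold (ties -> smaller level)."""
    levels = quantize(gray)
    _check_nonconstant(levels)
    hist = _histogram(levels)
    _, w0, w1, cum_mean, mu = _class_stats(hist)
    with np.errstate(divide="ignore", invalid="ignore"):
        mu0 = cum_mean / w0
        mu1 = (mu - cum_mean) / w1
        bcv = w0 * (mu0 - mu) ** 2 + w1 * (mu1 - mu) ** 2
    bcv[~np.isfinite(bcv)] = -np.inf
    return _first_max(bcv) + 1


def max_entropy(gray: GrayImage) -> int:
    """Kapur-style threshold maximizing foreground + background entropy."""
    levels = quantize(gray)
    _check_nonconstant(levels)
    hist = _histogram(levels)
    p = hist / hist.sum()
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(p > 0, p * np.log(np.where(p > 0, p, 1.0)), 0.0)  # 0 log 0 := 0
    P0 = np.cumsum(p)[:-1]
    S0 = np.cumsum(plogp)[:-1]
    P1 = 1.0 - P0
    S1 = plogp.sum() - S0
    with np.errstate(divide="ignore", invalid="ignore"):
        H0 = np.log(P0) - S0 / P0
        H1 = np.log(P1) - S1 / P1
    crit = H0 + H1
    crit[(P0 <= 0) | (P1 <= 0)] = -np.inf
    crit[~np.isfinite(crit)] = -np.inf
    if not np.isfinite(crit).any():
        raise DegenerateImageError("entropy criterion undefined everywhere")
    return _first_max(crit) + 1


def double_peak(gray: GrayImage) -> int:
    """Histogram double-peak method: valley between the main peak p and the
    secondary peak argmax (x - p)^2 * hist(x)."""
    levels = quantize(gray)
    _check_nonconstant(levels)
    hist = _histogram(levels)
    p = int(np.argmax(hist))
    x = np.arange(256, dtype=np.float64)
    d = (x - p) ** 2 * hist
    q = int(np.argmax(d))
    lo, hi = min(p, q), max(p, q)
    if hi - lo < 2:  # adjacent peaks: no interior valley exists
        return hi
    between = hist[lo + 1 : hi]
    return lo + 1 + int(np.argmin(between))


def min_error(gray: GrayImage, kittler: bool = False) -> int:
    """Minimum-error threshold for a two-Gaussian mixture.

    Default criterion: weighted within-class variance E = w0*s0^2 + w1*s1^2.
    ``kittler=True`` switches to the classical Kittler-Illingworth log
    criterion J = 1 + 2(w0 ln s0 + w1 ln s1) - 2(w0 ln w0 + w1 ln w1).
    """
    levels = quantize(gray)
    _check_nonconstant(levels)
    hist = _histogram(levels)
    p, w0, w1, cum_mean, mu = _class_stats(hist)
    x = np.arange(256, dtype=np.float64)
    cum_sq = np.cumsum(p * x**2)[:-1]
    total_sq = (p * x**2).sum()
    with np.errstate(divide="ignore", invalid="ignore"):
        mu0 = cum_mean / w0
        mu1 = (mu - cum_mean) / w1
        var0 = cum_sq / w0 - mu0**2
        var1 = (total_sq - cum_sq) / w1 - mu1**2
        var0 = np.clip(var0, 0.0, None)
        var1 = np.clip(var1, 0.0, None)
        if kittler:
            crit = (
                1.0
                + 2.0 * (w0 * np.log(np.sqrt(var0)) + w1 * np.log(np.sqrt(var1)))
                - 2.0 * (w0 * np.log(w0) + w1 * np.log(w1))
            )
        else:
            crit = w0 * var0 + w1 * var1
    valid = (w0 > 0) & (w1 > 0) & np.isfinite(crit)
    crit = np.where(valid, crit, np.inf)
    if not valid.any():
        raise DegenerateImageError("minimum-error criterion undefined everywhere")
    crit = np.where(np.isfinite(crit), crit, np.inf)
    return _first_min(crit) + 1


def iterative_threshold(gray: GrayImage, eps: float = 0.5) -> float:
    """Mean-of-class-means fixed point: Th <- (m_low + m_high) / 2.

    Starts from the global mean and stops when the threshold moves by less
    than ``eps`` gray levels (iteration cap 256 with a warning).
    """
    levels = quantize(gray).astype(np.float64)
    _check_nonconstant(levels.astype(np.int64))
    th = levels.mean()
    for _ in range(256):
        low = levels < th
        m_a = levels[low].mean() if low.any() else th
        m_b = levels[~low].mean() if (~low).any() else th
        new = 0.5 * (m_a + m_b)
        if abs(new - th) < eps:
            return new
        th = new
    warnings.warn("iterative threshold hit the 256-iteration cap")
    return th


def combined_global_local(gray: GrayImage) -> int:
    """Same fixed point as the iterative method, with the stricter stopping
    rule that the quantized threshold is unchanged between iterations."""
    levels = quantize(gray).astype(np.float64)
    _check_nonconstant(levels.astype(np.int64))
    th = levels.mean()
    prev_q = -1
    for _ in range(256):
        q = int(round(th))
        if q == prev_q:
            return q
        prev_q = q
        low = levels < th
        m1 = levels[low].mean() if low.any() else th
        m2 = levels[~low].mean() if (~low).any() else th
        th = 0.5 * (m1 + m2)
    warnings.warn("combined global/local threshold hit the 256-iteration cap")
    return int(round(th))


# ---------------------------------------------------------------------------
# local / adaptive methods
# ---------------------------------------------------------------------------

def block_otsu(gray: GrayImage, params: ThresholdParams | None = None) -> BinaryMask:
    """Cell-by-cell Otsu on block x block tiles (edge tiles smaller).

    Near-constant cells (single gray level, or a between-class variance
    below 1e-12) fall back to the global Otsu threshold; a fully constant
    image falls back to its global mean.
    """
    params = params or ThresholdParams(method="botsu")
    levels = quantize(gray)
    h, w = levels.shape
    try:
        global_t: float = otsu(gray)
    except DegenerateImageError:
        global_t = levels.mean() if levels.size else 0.0
    low = np.zeros_like(levels, dtype=bool)
    b = params.block
    for r0 in range(0, h, b):
        for c0 in range(0, w, b):
            cell = levels[r0 : r0 + b, c0 : c0 + b]
            t = _cell_otsu(cell, global_t)
            low[r0 : r0 + b, c0 : c0 + b] = cell < t
    if params.polarity == "high_is_positive":
        low = ~low
    elif params.polarity == "auto":
        low = _auto_orient(levels, low)
    return BinaryMask(low.astype(np.uint8))


def _cell_otsu(cell: np.ndarray, fallback: float) -> float:
    if cell.min() == cell.max():
        return fallback
    hist = np.bincount(cell.ravel(), minlength=256).astype(np.float64)
    _, w0, w1, cum_mean, mu = _class_stats(hist)
    with np.errstate(divide="ignore", invalid="ignore"):
        mu0 = cum_mean / w0
        mu1 = (mu - cum_mean) / w1
        bcv = w0 * (mu0 - mu) ** 2 + w1 * (mu1 - mu) ** 2
    bcv[~np.isfinite(bcv)] = -np.inf
    best = float(np.max(bcv))
    if best < 1e-12:
        return fallback
    return float(_first_max(bcv)) + 1.0


def local_dynamic(gray: GrayImage, params: ThresholdParams | None = None) -> BinaryMask:
    """Sauvola-form local threshold T = m * (1 + k * (s / R - 1)) over an
    r x r neighborhood (reflective padding)."""
    params = params or ThresholdParams(method="ldt")
    levels = quantize(gray).astype(np.float64)
    size = params.window_r
    m = uniform_filter(levels, size=size, mode="reflect")
    m2 = uniform_filter(levels**2, size=size, mode="reflect")
    s = np.sqrt(np.clip(m2 - m**2, 0.0, None))
    t_plane = m * (1.0 + params.k * (s / params.R - 1.0))
    low = levels < t_plane
    if params.polarity == "high_is_positive":
        low = ~low
    elif params.polarity == "auto":
        low = _auto_orient(levels.astype(np.int64), low)
    return BinaryMask(low.astype(np.uint8))


def wellner_adaptive(gray: GrayImage, params: ThresholdParams | None = None) -> BinaryMask:
    """Wellner's moving-average adaptive threshold.

    A running average of the preceding s pixels is kept along a serpentine
    row-major scan (exponential approximation f(n) = f(n-1)*(1 - 1/s) + p_n);
    a pixel joins the dark class when it falls t_pct percent below the
    running mean f(n)/s.
    """
    params = params or ThresholdParams(method="wat")
    levels = quantize(gray).astype(np.float64)
    h, w = levels.shape
    s = params.s if params.s is not None else max(w // 8, 1)
    serp = levels.copy()
    serp[1::2] = serp[1::2, ::-1]  # serpentine: odd rows reversed
    flat = serp.ravel()
    # IIR recurrence f[n] = (1 - 1/s) * f[n-1] + p[n], f seeded with s * p[0]
    a = 1.0 - 1.0 / s
    zi = np.array([a * s * flat[0]])
    f, _ = lfilter([1.0], [1.0, -a], flat, zi=zi)
    low_flat = flat < (f / s) * ((100.0 - params.t_pct) / 100.0)
    low = low_flat.reshape(h, w)
    low[1::2] = low[1::2, ::-1]
    if params.polarity == "high_is_positive":
        low = ~low
    elif params.polarity == "auto":
        low = _auto_orient(levels.astype(np.int64), low)
    return BinaryMask(low.astype(np.uint8))


# ---------------------------------------------------------------------------
# dispatcher
# ---------------------------------------------------------------------------

_GLOBAL = {
    "otsu": lambda g, p: otsu(g),
    "met": lambda g, p: max_entropy(g),
    "dpm": lambda g, p: double_peak(g),
    "mem": lambda g, p: min_error(g, kittler=p.kittler),
    "itm": lambda g, p: iterative_threshold(g, eps=p.eps),
    "cglt": lambda g, p: combined_global_local(g),
}
_LOCAL = {"botsu": block_otsu, "ldt": local_dynamic, "wat": wellner_adaptive}


def segment(gray: GrayImage, params: ThresholdParams | str | None = None) -> BinaryMask:
    """Route a normalized plane through one of the nine thresholders.

    Degenerate (constant) inputs downgrade to an all-healthy mask with a
    warning so batch runs never crash.
    """
    if params is None:
        params = ThresholdParams()
    elif isinstance(params, str):
        params = ThresholdParams(method=params)
    gray = np.asarray(gray, dtype=np.float64)
    try:
        if params.method in _GLOBAL:
            t = _GLOBAL[params.method](gray, params)
            return binarize(gray, t, polarity=params.polarity)
        return _LOCAL[params.method](gray, params)
    except DegenerateImageError as exc:
        warnings.warn(f"{params.method}: {exc}; returning all-healthy mask")
        return BinaryMask(np.zeros(gray.shape, dtype=np.uint8))


def segment_all(gray: GrayImage, base: ThresholdParams | None = None) -> dict[str, BinaryMask]:
    """All nine methods on one plane; keys are method ids."""
    base = base or ThresholdParams()
    return {m: segment(gray, replace(base, method=m)) for m in METHODS}
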