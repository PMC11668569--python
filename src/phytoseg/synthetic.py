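"""Synthetic UAV-like canopy scenes with exact ground truth.

The generator emulates the statistics the detection pipeline cares about in
nadir RGB canopy mosaics of a pest/disease survey:

* a green-hued healthy canopy texture (default mean RGB (60, 110, 55)),
* spatially coherent brown/gray diseased crowns placed as random ellipses
  (default mean RGB (120, 95, 60)) until a target prevalence is reached,
* darkened shadow regions covering a configurable share of the scene,
* a smooth multiplicative texture field and additive Gaussian pixel noise.

It does not attempt radiometric or atmospheric realism; see the methods note
for what that implies about test coverage.
"""

from __future__ import annotations

from dataclasses import dataclass
import numpy as np
from scipy.ndimage import gaussian_filter

from .io import BinaryMask, GrayImage, RGBImage
from .selection import FeatureTable

__all__ = [
    "SceneConfig",
    "generate_scene",
    "generate_bimodal_gray",
    "generate_feature_table",
]


@dataclass(frozen=True)
class SceneConfig:
    """Scene geometry, color statistics and degradation levels."""

    height: int = 512
    width: int = 512
    disease_fraction: float = 0.15
    blob_radius_range: tuple[int, int] = (8, 24)
    healthy_color_mean: tuple[float, float, float] = (60.0, 110.0, 55.0)
    healthy_color_sd: float = 12.0
    disease_color_mean: tuple[float, float, float] = (120.0, 95.0, 60.0)
    disease_color_sd: float = 12.0
    shadow_fraction: float = 0.1
    shadow_multiplier: float = 0.35
    noise_sd: float = 5.0
    texture_scale: float = 24.0
    texture_strength: float = 0.08
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.disease_fraction < 0.5:
            raise ValueError("disease_fraction must lie in [0, 0.5)")
        if not 0.0 <= self.shadow_fraction < 1.0:
            raise ValueError("shadow_fraction must lie in [0, 1)")
        lo, hi = self.blob_radius_range
        if not 1 <= lo <= hi:
            raise ValueError("invalid blob_radius_range")
        if hi * 2 > min(self.height, self.width):
            raise ValueError("blobs larger than the scene are infeasible")
        for mean in (self.healthy_color_mean, self.disease_color_mean):
            if any(not 0 <= c <= 255 for c in mean):
                raise ValueError("color means must lie in [0, 255]")
        if not 0 <= self.healthy_color_sd <= 64 or not 0 <= self.disease_color_sd <= 64:
            raise ValueError("color sds must lie in [0, 64]")


def _fill_ellipses(
    shape: tuple[int, int],
    target_fraction: float,
    radius_range: tuple[int, int],
    rng: np.random.Generator,
    max_attempts: int = 100_000,
) -> np.ndarray:
    """Union of random rotated ellipses until the target pixel fraction."""
    h, w = shape
    mask = np.zeros(shape, dtype=bool)
    if target_fraction <= 0:
        return mask
    target = target_fraction * h * w
    rows, cols = np.mgrid[0:h, 0:w]
    attempts = 0
    while mask.sum() < target:
        attempts += 1
        if attempts > max_attempts:
            raise RuntimeError(
                "could not reach the requested fraction with the given geometry"
            )
        cy = rng.uniform(0, h)
        cx = rng.uniform(0, w)
        ry = rng.uniform(*radius_range)
        rx = rng.uniform(*radius_range)
        theta = rng.uniform(0, np.pi)
        dy = rows - cy
        dx = cols - cx
        u = dy * np.cos(theta) + dx * np.sin(theta)
        v = -dy * np.sin(theta) + dx * np.cos(theta)
        mask |= (u / ry) ** 2 + (v / rx) ** 2 <= 1.0
    return mask


def generate_scene(config: SceneConfig | None = None) -> tuple[RGBImage, BinaryMask]:
    """Deterministic (seeded) scene plus its exact ground-truth mask."""
    config = config or SceneConfig()
    rng = np.random.default_rng(config.seed)
    h, w = config.height, config.width

    truth = _fill_ellipses((h, w), config.disease_fraction,
                           config.blob_radius_range, rng)

    healthy = rng.normal(config.healthy_color_mean, config.healthy_color_sd,
                         size=(h, w, 3))
    diseased = rng.normal(config.disease_color_mean, config.disease_color_sd,
                          size=(h, w, 3))
    img = np.where(truth[..., None], diseased, healthy)

    if config.texture_strength > 0:
        texture = gaussian_filter(rng.standard_normal((h, w)), config.texture_scale)
        sd = texture.std()
        if sd > 0:
            texture *= config.texture_strength / sd
        img *= (1.0 + texture)[..., None]

    if config.shadow_fraction > 0:
        shadow = _fill_ellipses(
            (h, w), config.shadow_fraction,
            (config.blob_radius_range[0] * 2, config.blob_radius_range[1] * 3), rng,
        )
        img[shadow] *= config.shadow_multiplier

    if config.noise_sd > 0:
        img += rng.normal(0.0, config.noise_sd, size=img.shape)

    img = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    return RGBImage(img), BinaryMask(truth.astype(np.uint8))


def generate_bimodal_gray(
    levels: tuple[float, float] = (0.2, 0.8),
    weight: float = 0.5,
    noise_sd: float = 0.0,
    size: tuple[int, int] = (64, 64),
    seed: int | None = None,
) -> GrayImage:
    """Two-level mixture plane in [0, 1] with optional noise — the standard
    fixture for thresholder oracles. ``weight`` is the share of the first
    level; weight 1 gives a constant plane (degenerate-input fixture)."""
    lo, hi = levels
    if lo == hi:
        raise ValueError("levels must be distinct")
    rng = np.random.default_rng(seed)
    pick = rng.uniform(size=size) < weight
    plane = np.where(pick, lo, hi).astype(np.float64)
    if noise_sd > 0:
        plane += rng.normal(0.0, noise_sd, size=size)
    return np.clip(plane, 0.0, 1.0)


def generate_feature_table(
    n_rows: int = 2000,
    n_noise_features: int = 9,
    label_noise: float = 0.0,
    duplicate_informative: bool = False,
    duplicate_sd: float = 0.02,
    seed: int | None = None,
) -> FeatureTable:
    """Table with one planted informative feature for selector tests.

    Feature ``signal`` drives the label (1 where it exceeds 0.5, flipped with
    probability ``label_noise``); ``signal_dup``, when requested, is the
    signal plus small Gaussian noise (a near-duplicate, |rho| >= 0.95 at the
    default sd); the rest are independent uniform noise.
    """
    rng = np.random.default_rng(seed)
    signal = rng.uniform(size=n_rows)
    y = (signal > 0.5).astype(np.int8)
    if label_noise > 0:
        flip = rng.uniform(size=n_rows) < label_noise
        y = np.where(flip, 1 - y, y).astype(np.int8)
    columns = [signal]
    names = ["signal"]
    if duplicate_informative:
        columns.append(signal + rng.normal(0.0, duplicate_sd, size=n_rows))
        names.append("signal_dup")
    for i in range(n_noise_features):
        columns.append(rng.uniform(size=n_rows))
        names.append(f"noise{i}")
    return FeatureTable(np.column_stack(columns), y, tuple(names))
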