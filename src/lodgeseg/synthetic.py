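"""Procedural wheat-field scenes: RGB + DSM + 3-class mask.

The generator reproduces the two statistical handles a lodging segmenter
exploits in real UAV data:

* height: the lodged canopy sits ``lodging_drop_m`` (default 0.2 m) below
  the standing canopy in the DSM, on top of smooth terrain undulation and
  per-pixel surface noise;
* color: lodged wheat is brighter in red and green than standing wheat
  (flattened stems expose more reflective canopy), so its excess-green
  index is higher under both the printed and the classical formula.

``color_overlap`` interpolates the lodging color model toward the wheat
one: at 1.0 the two classes are color-identical and only the DSM carries
the distinction — the constructed premise for measuring the benefit of
RGB+DSM fusion. Lodging patches are contiguous irregular blobs obtained
by quantile-thresholding Gaussian-smoothed noise inside the field area,
so realized class fractions hit their targets up to discretization.
Scenes are bitwise-reproducible from the seed.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .fusion import exg, fuse, normalize_dsm
from .raster_io import LabelMask, Raster, tile_pairs

__all__ = ["ColorModel", "SceneConfig", "SyntheticScene", "SyntheticDataset",
           "generate_scene", "generate_dataset"]


@dataclass(frozen=True)
class ColorModel:
    """Per-class mean RGB (unit scale) and a shared per-pixel spread."""

    background: tuple = (0.45, 0.38, 0.30)  # bare soil
    wheat: tuple = (0.20, 0.35, 0.25)       # standing green canopy
    lodging: tuple = (0.35, 0.50, 0.20)     # flattened, brighter canopy
    sd: float = 0.05


@dataclass(frozen=True)
class SceneConfig:
    height: int = 256
    width: int = 256
    lodging_fraction: float = 0.3      # share of field (wheat) area lodged
    background_fraction: float = 0.15  # share of non-field pixels
    color_model: ColorModel = field(default_factory=ColorModel)
    color_overlap: float = 0.0         # 0 = full separation, 1 = identical colors
    canopy_height_m: float = 0.8
    lodging_drop_m: float = 0.2
    terrain_amplitude_m: float = 0.1
    blob_smoothness: float = 12.0      # correlation length of lodging patches, px
    noise_sd: float = 0.03             # per-pixel DSM noise, meters
    seed: int = 0

    def __post_init__(self):
        for name in ("lodging_fraction", "background_fraction", "color_overlap"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0,1], got {v}")
        if self.background_fraction >= 1.0:
            raise ValueError("background_fraction must leave room for the field")
        if self.lodging_drop_m <= 0:
            raise ValueError("lodging_drop_m must be positive")
        if self.height <= 0 or self.width <= 0:
            raise ValueError("scene dimensions must be positive")


@dataclass
class SyntheticScene:
    rgb: Raster
    dsm: np.ndarray  # H×W, meters
    mask: LabelMask
    config: SceneConfig


def _smooth_noise(rng: np.random.Generator, shape, sigma: float) -> np.ndarray:
    """Gaussian random field, unit-variance after smoothing."""
    f = ndimage.gaussian_filter(rng.standard_normal(shape), sigma, mode="wrap")
    sd = f.std()
    return f / sd if sd > 0 else f


def _threshold_to_fraction(fld: np.ndarray, where: np.ndarray, fraction: float) -> np.ndarray:
    """Boolean blob mask covering `fraction` of the True area of `where`."""
    out = np.zeros(fld.shape, dtype=bool)
    if fraction <= 0 or not where.any():
        return out
    vals = fld[where]
    if fraction >= 1:
        out[where] = True
        return out
    thresh = np.quantile(vals, 1.0 - fraction)
    out[where] = vals > thresh
    return out


def generate_scene(config: SceneConfig) -> SyntheticScene:
    """Render one field scene (RGB raster, DSM in meters, class mask)."""
    rng = np.random.default_rng(config.seed)
    shape = (config.height, config.width)

    # layout: coarse blobs for field-vs-background, finer blobs for lodging
    bg_field = _smooth_noise(rng, shape, 2.0 * config.blob_smoothness)
    background = _threshold_to_fraction(bg_field, np.ones(shape, dtype=bool),
                                        config.background_fraction)
    in_field = ~background
    lodge_field = _smooth_noise(rng, shape, config.blob_smoothness)
    lodging = _threshold_to_fraction(lodge_field, in_field, config.lodging_fraction)
    labels = np.zeros(shape, dtype=np.int64)
    labels[in_field] = 1
    labels[lodging] = 2

    # DSM: terrain + canopy; lodged canopy sits lodging_drop_m lower
    terrain = 100.0 + config.terrain_amplitude_m * _smooth_noise(
        rng, shape, 4.0 * config.blob_smoothness
    )
    dsm = terrain.copy()
    dsm[labels == 1] += config.canopy_height_m
    dsm[labels == 2] += config.canopy_height_m - config.lodging_drop_m
    dsm += rng.normal(0.0, config.noise_sd, shape)

    # RGB: per-class truncated-normal color; overlap pulls lodging toward wheat
    cm = config.color_model
    w_mean = np.array(cm.wheat)
    l_mean = w_mean + (1.0 - config.color_overlap) * (np.array(cm.lodging) - w_mean)
    means = np.array([cm.background, w_mean, l_mean])
    rgb = means[labels] + rng.normal(0.0, cm.sd, shape + (3,))
    rgb = np.clip(rgb, 0.0, 1.0)

    return SyntheticScene(
        rgb=Raster(rgb, ("R", "G", "B")),
        dsm=dsm,
        mask=LabelMask(labels),
        config=config,
    )


@dataclass
class SyntheticDataset:
    """Tiled dataset in the three channel variants, sharing identical masks."""

    rgb: list
    rgb_exg: list
    rgb_dsm: list


def generate_dataset(config: SceneConfig, n_scenes: int, tile: int = 256) -> SyntheticDataset:
    """Generate scenes with derived per-scene seeds, fuse, and tile.

    DSM normalization and the excess-green index are computed per scene
    (before tiling) so the absolute height gap within a scene is preserved.
    """
    if n_scenes < 1:
        raise ValueError("n_scenes must be >= 1")
    seeds = [int(s) for s in
             np.random.SeedSequence(config.seed).generate_state(n_scenes) % (2**31)]
    out = SyntheticDataset([], [], [])
    for s in seeds:
        scene = generate_scene(replace(config, seed=s))
        out.rgb.extend(tile_pairs(scene.rgb, scene.mask, tile))
        fused_exg = fuse(scene.rgb, exg(scene.rgb), "rgb_exg")
        out.rgb_exg.extend(tile_pairs(fused_exg.image, scene.mask, tile))
        fused_dsm = fuse(scene.rgb, normalize_dsm(scene.dsm), "rgb_dsm")
        out.rgb_dsm.extend(tile_pairs(fused_dsm.image, scene.mask, tile))
    return out
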