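"""Raster and label-mask I/O, tiling, and the class palette.

Rasters are H×W×C float arrays with named channels from {R, G, B, DSM,
ExG}. Eight-bit color channels are scaled to [0,1] on load (DN/255); DSM
values stay in meters. TIFF (including the GeoTIFF pixel-scale/tiepoint
tags for an axis-aligned geotransform) is handled through tifffile, PNG
through Pillow. Masks are 3-class indexed PNGs: background=0 (black),
wheat=1 (green), lodging=2 (red).

Coordinate convention throughout: row-major, origin top-left, 0-based,
half-open tile windows.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import tifffile
from PIL import Image

__all__ = [
    "CLASS_NAMES",
    "DEFAULT_PALETTE",
    "DEFAULT_TILE",
    "Raster",
    "LabelMask",
    "TilePair",
    "load_raster",
    "write_raster",
    "load_mask",
    "write_mask",
    "tile_pairs",
]

CLASS_NAMES = ("background", "wheat", "lodging")
DEFAULT_PALETTE = {0: (0, 0, 0), 1: (0, 255, 0), 2: (255, 0, 0)}
DEFAULT_TILE = 256
COLOR_CHANNELS = {"R", "G", "B"}
KNOWN_CHANNELS = {"R", "G", "B", "DSM", "ExG", "DSMnorm"}


@dataclass
class Raster:
    """Multi-channel image with named channels and optional placement.

    ``geotransform`` is the GDAL-style affine (x0, dx, rx, y0, ry, dy);
    only axis-aligned transforms (rx = ry = 0) survive a TIFF round trip.
    ``nodata`` marks DSM gaps.
    """

    pixels: np.ndarray  # H×W×C float
    channel_names: tuple
    geotransform: Optional[tuple] = None
    nodata: Optional[float] = None

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim == 2:
            self.pixels = self.pixels[:, :, None]
        self.channel_names = tuple(self.channel_names)
        if self.pixels.shape[2] != len(self.channel_names):
            raise ValueError(
                f"{self.pixels.shape[2]} bands but {len(self.channel_names)} channel names"
            )
        unknown = set(self.channel_names) - KNOWN_CHANNELS
        if unknown:
            raise ValueError(f"unknown channel names: {sorted(unknown)}")

    @property
    def shape(self):
        return self.pixels.shape[:2]

    def channel(self, name: str) -> np.ndarray:
        if name not in self.channel_names:
            raise KeyError(f"raster has no channel {name!r} (has {self.channel_names})")
        return self.pixels[:, :, self.channel_names.index(name)]

    def select(self, names: Sequence[str]) -> "Raster":
        idx = [self.channel_names.index(n) for n in names]
        return Raster(self.pixels[:, :, idx].copy(), tuple(names), self.geotransform, self.nodata)


@dataclass
class LabelMask:
    """H×W integer mask over (background, wheat, lodging)."""

    labels: np.ndarray
    class_names: tuple = CLASS_NAMES

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("labels must be integer")
        if self.labels.ndim != 2:
            raise ValueError("labels must be H×W")
        if self.labels.size and (self.labels.min() < 0 or self.labels.max() > 2):
            raise ValueError("labels must lie in {0,1,2}")

    @property
    def shape(self):
        return self.labels.shape


@dataclass
class TilePair:
    image: Raster
    mask: LabelMask

    def __post_init__(self):
        if self.image.shape != self.mask.shape:
            raise ValueError("image and mask dimensions differ")


def _read_geotags(tif: tifffile.TiffFile) -> Optional[tuple]:
    page = tif.pages[0]
    scale = page.tags.get("ModelPixelScaleTag")
    tie = page.tags.get("ModelTiepointTag")
    if scale is None or tie is None:
        return None
    sx, sy = scale.value[0], scale.value[1]
    i, j, _, x, y, _ = tie.value[:6]
    # GeoTIFF raster-space tiepoint (i,j) maps to model (x,y); dy is negative
    return (x - i * sx, sx, 0.0, y + j * sy, 0.0, -sy)


def load_raster(path, channel_names: Sequence[str]) -> Raster:
    """Read a TIFF or PNG raster and attach channel names.

    Color channels (R, G, B) stored as integers are scaled to [0,1]
    (DN / type max); DSM/ExG bands pass through unscaled.
    """
    path = Path(path)
    channel_names = tuple(channel_names)
    geotransform = None
    if path.suffix.lower() in (".tif", ".tiff"):
        with tifffile.TiffFile(path) as tif:
            data = tif.asarray()
            geotransform = _read_geotags(tif)
        if data.ndim == 3 and data.shape[0] == len(channel_names) and data.shape[-1] != len(channel_names):
            data = np.moveaxis(data, 0, -1)
    else:
        with Image.open(path) as im:
            data = np.asarray(im)
    if data.ndim == 2:
        data = data[:, :, None]
    if data.shape[2] != len(channel_names):
        raise ValueError(
            f"{path.name}: {data.shape[2]} bands do not match channel names {channel_names}"
        )
    out = np.empty(data.shape, dtype=np.float64)
    for c, name in enumerate(channel_names):
        band = data[:, :, c]
        if name in COLOR_CHANNELS and np.issubdtype(band.dtype, np.integer):
            out[:, :, c] = band / float(np.iinfo(band.dtype).max)
        else:
            out[:, :, c] = band
    return Raster(out, channel_names, geotransform=geotransform)


def write_raster(raster: Raster, path) -> None:
    """Write a raster as multi-band float TIFF (with geotags) or 8-bit PNG."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        data = raster.pixels.astype(np.float32)
        extratags = []
        gt = raster.geotransform
        if gt is not None:
            x0, dx, rx, y0, ry, dy = gt
            if rx == 0 and ry == 0:
                extratags = [
                    (33550, "d", 3, (dx, -dy, 0.0)),
                    (33922, "d", 6, (0.0, 0.0, 0.0, x0, y0, 0.0)),
                ]
        bands = np.moveaxis(data, -1, 0)
        kwargs = {"photometric": "minisblack"}
        if bands.shape[0] > 1:
            kwargs["planarconfig"] = "separate"
        else:
            bands = bands[0]
        tifffile.imwrite(path, bands, extratags=extratags, **kwargs)
    else:
        data = np.clip(raster.pixels, 0.0, 1.0)
        arr = np.round(data * 255).astype(np.uint8)
        if arr.shape[2] == 1:
            arr = arr[:, :, 0]
        Image.fromarray(arr).save(path)


def write_mask(mask: LabelMask, path, palette: dict = DEFAULT_PALETTE) -> None:
    """Write an indexed-color PNG; read-back round-trips the labels."""
    missing = [c for c in range(len(CLASS_NAMES)) if c not in palette]
    if missing:
        raise ValueError(f"palette missing classes {missing}")
    im = Image.fromarray(mask.labels.astype(np.uint8), mode="P")
    flat = []
    for c in range(256):
        flat.extend(palette.get(c, (0, 0, 0)))
    im.putpalette(flat)
    im.save(path)


def load_mask(path) -> LabelMask:
    with Image.open(path) as im:
        if im.mode != "P":
            raise ValueError(f"{path}: mask must be an indexed (palette) PNG")
        labels = np.asarray(im, dtype=np.int64)
    return LabelMask(labels)


def tile_pairs(
    raster: Raster,
    mask: LabelMask,
    tile: int = DEFAULT_TILE,
    policy: str = "drop_partial",
) -> list[TilePair]:
    """Cut a scene into non-overlapping row-major tile/mask pairs.

    ``drop_partial`` keeps only fully covered tiles; ``pad_reflect``
    reflect-pads the right/bottom edges so every pixel is covered.
    """
    if raster.shape != mask.shape:
        raise ValueError("raster and mask dimensions differ")
    if policy not in ("drop_partial", "pad_reflect"):
        raise ValueError(f"unknown edge policy {policy!r}")
    h, w = raster.shape
    pixels, labels = raster.pixels, mask.labels
    if policy == "pad_reflect":
        ph = (-h) % tile
        pw = (-w) % tile
        if ph or pw:
            pixels = np.pad(pixels, ((0, ph), (0, pw), (0, 0)), mode="reflect")
            labels = np.pad(labels, ((0, ph), (0, pw)), mode="reflect")
            h, w = pixels.shape[:2]
    out = []
    for i in range(h // tile):
        for j in range(w // tile):
            win = (slice(i * tile, (i + 1) * tile), slice(j * tile, (j + 1) * tile))
            out.append(
                TilePair(
                    Raster(pixels[win].copy(), raster.channel_names, nodata=raster.nodata),
                    LabelMask(labels[win].copy()),
                )
            )
    return out
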