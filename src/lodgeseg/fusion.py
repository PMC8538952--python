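"""Channel fusion: the excess-green index, DSM normalization, RGB+X stacks.

The excess-green index here follows the source method's printed form

    ExG = (2R − G − B) / (R + G + B),

a ratio of linear forms in the (unit-scaled) color channels, so it is
invariant to uniform illumination scaling. The classical excess-green
numerator 2G − R − B is available as ``variant="classic"``; on lodged
versus standing wheat both variants order the classes the same way once
the lodged canopy is brighter in both red and green.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .raster_io import Raster

__all__ = ["FusedTile", "exg", "normalize_dsm", "fuse", "EXG_RANGE"]

#: Range of the printed-form index: extremes at pure red / pure cyan pixels.
EXG_RANGE = (-1.0, 2.0)

FUSION_KINDS = ("rgb", "rgb_exg", "rgb_dsm")


@dataclass
class FusedTile:
    """Four-channel stack: RGB plus one bounded auxiliary channel."""

    image: Raster
    fusion_kind: str

    def __post_init__(self):
        if self.fusion_kind not in FUSION_KINDS:
            raise ValueError(f"fusion_kind must be one of {FUSION_KINDS}")


def exg(rgb: Raster, variant: str = "printed") -> np.ndarray:
    """Per-pixel excess-green map; zero-sum (black) pixels map to 0."""
    r, g, b = rgb.channel("R"), rgb.channel("G"), rgb.channel("B")
    if variant == "printed":
        num = 2.0 * r - g - b
    elif variant == "classic":
        num = 2.0 * g - r - b
    else:
        raise ValueError(f"unknown ExG variant {variant!r}")
    den = r + g + b
    out = np.zeros_like(den)
    np.divide(num, den, out=out, where=den != 0)
    return out


def normalize_dsm(dsm: np.ndarray, nodata: float | None = None, mode: str = "minmax") -> np.ndarray:
    """Scale a DSM (meters) to [0,1].

    Min-max over the scene; nodata pixels are filled with the scene minimum
    before scaling; a constant scene maps to all zeros.
    """
    if mode != "minmax":
        raise ValueError(f"unknown DSM scaling mode {mode!r}")
    dsm = np.asarray(dsm, dtype=np.float64)
    valid = np.isfinite(dsm)
    if nodata is not None:
        valid &= dsm != nodata
    if not valid.any():
        raise ValueError("DSM has no valid pixels")
    lo = dsm[valid].min()
    hi = dsm[valid].max()
    filled = np.where(valid, dsm, lo)
    if hi == lo:
        return np.zeros_like(filled)
    return (filled - lo) / (hi - lo)


def fuse(rgb: Raster, extra: np.ndarray, kind: str, rescale_exg: bool = True) -> FusedTile:
    """Stack a fourth channel onto RGB.

    ``kind="rgb_exg"``: the raw index lies in [−1, 2]; with ``rescale_exg``
    (default) it is mapped affinely to [0,1] so all four network input
    channels share a dynamic range. ``kind="rgb_dsm"``: the extra channel
    must already be normalized to [0,1]. The RGB channels are passed
    through bit-for-bit.
    """
    extra = np.asarray(extra, dtype=np.float64)
    if extra.shape != rgb.shape:
        raise ValueError(f"extra channel shape {extra.shape} != rgb shape {rgb.shape}")
    if kind == "rgb_exg":
        name = "ExG"
        if rescale_exg:
            lo, hi = EXG_RANGE
            extra = (extra - lo) / (hi - lo)
    elif kind == "rgb_dsm":
        name = "DSMnorm"
    else:
        raise ValueError(f"fuse kind must be rgb_exg or rgb_dsm, got {kind!r}")
    base = rgb.select(("R", "G", "B"))
    pixels = np.concatenate([base.pixels, extra[:, :, None]], axis=2)
    image = Raster(pixels, ("R", "G", "B", name), rgb.geotransform, rgb.nodata)
    return FusedTile(image, kind)
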