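"""Lossless joint image/mask augmentation.

All ops are pixel permutations (elements of the dihedral group D4 acting
on a square tile), applied identically to the image and its mask, so
per-channel value multisets and class frequencies are preserved exactly.
"""
from __future__ import annotations

import numpy as np

from .raster_io import LabelMask, Raster, TilePair

__all__ = ["OPS", "RANDOM_OPS", "apply", "build_augmented_dataset"]

#: identity plus the four lossless transforms the training pipeline draws from
OPS = ("identity", "hflip", "vflip", "rot90", "transpose")
#: ops drawn uniformly when materializing an augmented dataset
RANDOM_OPS = ("hflip", "vflip", "rot90", "transpose")


def _transform(a: np.ndarray, op: str) -> np.ndarray:
    # spatial axes are 0 (rows) and 1 (cols); channel axis, if any, rides along
    if op == "identity":
        return a.copy()
    if op == "hflip":
        return a[:, ::-1].copy()
    if op == "vflip":
        return a[::-1].copy()
    if op == "rot90":
        return np.rot90(a, k=1, axes=(0, 1)).copy()
    if op == "transpose":
        return a.swapaxes(0, 1).copy()
    raise ValueError(f"unknown augmentation op {op!r}; expected one of {OPS}")


def apply(op: str, pair: TilePair) -> TilePair:
    """Apply one lossless op jointly to image and mask."""
    h, w = pair.image.shape
    if op in ("rot90", "transpose") and h != w:
        raise ValueError(f"{op} requires square tiles, got {h}×{w}")
    img = pair.image
    return TilePair(
        Raster(_transform(img.pixels, op), img.channel_names, img.geotransform, img.nodata),
        LabelMask(_transform(pair.mask.labels, op), pair.mask.class_names),
    )


def build_augmented_dataset(pairs, target_count: int, seed: int) -> list[TilePair]:
    """Materialize a fixed-size dataset: originals plus seeded random augments.

    Each generated pair applies one op (uniform over hflip/vflip/rot90/
    transpose) to a uniformly drawn source pair. Reproducible from ``seed``.
    """
    pairs = list(pairs)
    if not pairs:
        raise ValueError("no source pairs to augment")
    if target_count < len(pairs):
        raise ValueError("target_count must be >= number of source pairs")
    rng = np.random.default_rng(seed)
    out = list(pairs)
    for _ in range(target_count - len(pairs)):
        src = pairs[int(rng.integers(len(pairs)))]
        op = RANDOM_OPS[int(rng.integers(len(RANDOM_OPS)))]
        out.append(apply(op, src))
    return out
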