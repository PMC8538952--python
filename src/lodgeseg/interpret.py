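"""Grad-CAM class-activation maps for the segmentation network.

For a dense prediction head the "class score" is taken as the spatial sum
of the target class's pre-SoftMax map. Channel weights are the spatial
means of the score's gradient at the chosen convolutional layer; the map
is the ReLU of the weighted activation sum, bilinearly upsampled to tile
size and max-normalized (an all-zero map stays all-zero).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .network import SegmentationUNet
from .raster_io import CLASS_NAMES, Raster

__all__ = ["CAMHeatmap", "gradcam", "LAYER_ALIASES"]

#: friendly names for the layers most often visualized
LAYER_ALIASES = {"bottleneck": "enc5"}


@dataclass
class CAMHeatmap:
    values: np.ndarray  # H×W in [0,1]
    target_class: int
    layer: str

    def __post_init__(self):
        v = self.values
        if v.ndim != 2 or v.min() < 0 or v.max() > 1:
            raise ValueError("heatmap must be H×W with values in [0,1]")


def gradcam(
    model: SegmentationUNet,
    tile,
    target_class: int | str,
    layer: str = "bottleneck",
) -> CAMHeatmap:
    """Compute a Grad-CAM heatmap for one tile.

    ``tile`` may be a Raster, a FusedTile, or an (H,W,C) array whose
    channel count matches the model. ``layer`` is an activation name
    ("enc1".."enc5", "dec1".."dec4") or the alias "bottleneck".
    """
    if isinstance(target_class, str):
        if target_class not in CLASS_NAMES:
            raise ValueError(f"unknown class {target_class!r}")
        target_class = CLASS_NAMES.index(target_class)
    if not 0 <= target_class < len(CLASS_NAMES):
        raise ValueError(f"class index {target_class} out of range")
    layer_name = LAYER_ALIASES.get(layer, layer)

    if hasattr(tile, "fusion_kind"):
        pixels = tile.image.pixels
    elif isinstance(tile, Raster):
        pixels = tile.pixels
    else:
        pixels = np.asarray(tile)
    x = np.moveaxis(pixels, -1, 0)[None].astype(np.float32)
    h, w = x.shape[2], x.shape[3]

    # inference-mode statistics, but with caches so gradients flow
    model.set_bn_frozen(True)
    try:
        logits = model.forward(x, train=True)
        if layer_name not in model.activations:
            raise KeyError(
                f"unknown layer {layer_name!r}; available: {sorted(model.activations)}"
            )
        dlogits = np.zeros_like(logits)
        dlogits[:, target_class] = 1.0  # d(spatial sum of class map)/dlogits
        model.backward(dlogits)
    finally:
        model.set_bn_frozen(False)
        for p in model.parameters():
            p.grad[...] = 0.0

    acts = model.activations[layer_name][0]  # (C,h,w)
    grads = model.activation_grads[layer_name][0]
    weights = grads.mean(axis=(1, 2))
    cam = np.maximum((weights[:, None, None] * acts).sum(axis=0), 0.0)
    if cam.shape != (h, w):
        cam = ndimage.zoom(cam, (h / cam.shape[0], w / cam.shape[1]), order=1)
        cam = np.maximum(cam[:h, :w], 0.0)
    peak = cam.max()
    if peak > 0:
        cam = cam / peak
    return CAMHeatmap(cam.astype(np.float64), target_class, layer_name)
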