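"""Desk-scale experiment protocols over the synthetic generator.

These are the scaled-down study conditions the package uses to exercise
the full pipeline on a single CPU: 64×64 tiles, Mobile U-Net widths
divided by 4, short Adam schedules (lr 1e-3 — the stock small-model Adam
default, since the published 200-epoch/1e-4 recipe is tied to full-width
training). Scene sizes and counts are chosen so each protocol finishes in
minutes while leaving the measured effects far from their decision
thresholds.
"""
from __future__ import annotations

from dataclasses import replace

import numpy as np

from .interpret import gradcam
from .network import NetworkSpec, build_model
from .synthetic import SceneConfig, generate_dataset, generate_scene
from .training import TrainConfig, evaluate_model, split_dataset, train

__all__ = ["fusion_benefit", "overfit_sanity", "gradcam_localization", "train_demo_model"]


def fusion_benefit(
    seeds=(0, 1, 2),
    color_overlap: float = 0.95,
    n_scenes: int = 10,
    scene_size: int = 128,
    tile: int = 64,
    width_divisor: int = 4,
    epochs: int = 30,
    learning_rate: float = 1e-3,
    augment_factor: int = 2,
    variants=("rgb", "rgb_dsm"),
):
    """Benefit of DSM fusion when color barely separates lodging from wheat.

    For each seed, generates a field dataset with nearly overlapping
    wheat/lodging color models, splits it, materializes a lossless-augmented
    training partition, trains one Mobile U-Net per channel variant, and
    evaluates test mIoU from the best-validation checkpoint. Returns
    (median mIoU per variant, all per-seed values).
    """
    from .augment import build_augmented_dataset

    results = {v: [] for v in variants}
    for seed in seeds:
        cfg = SceneConfig(
            height=scene_size, width=scene_size, color_overlap=color_overlap, seed=seed
        )
        ds = generate_dataset(cfg, n_scenes, tile)
        for v in variants:
            pairs = getattr(ds, v)
            tr, va, te = split_dataset(pairs, seed=seed)
            if augment_factor > 1:
                tr = build_augmented_dataset(tr, augment_factor * len(tr), seed=seed)
            in_ch = pairs[0].image.pixels.shape[2]
            spec = NetworkSpec.variant(
                "table1", in_channels=in_ch, width_divisor=width_divisor, tile=tile
            )
            model = build_model("mobile_unet", spec, seed=seed)
            config = TrainConfig(
                learning_rate=learning_rate, batch_size=4, epochs=epochs, seed=seed
            )
            model, _ = train(model, tr, va, config)
            report, _ = evaluate_model(model, te)
            results[v].append(report.miou)
    medians = {v: float(np.median(r)) for v, r in results.items()}
    return medians, results


def overfit_sanity(
    seed: int = 0,
    epochs: int = 150,
    tile: int = 64,
    width_divisor: int = 4,
    learning_rate: float = 1e-3,
):
    """Capacity check: memorize 8 easy tiles; returns (model, history).

    Train and validation sets are the same 8 tiles (color_overlap 0, so the
    classes are color-separable); training pixel accuracy should approach 1.
    """
    cfg = SceneConfig(height=2 * tile, width=2 * tile, color_overlap=0.0, seed=seed)
    ds = generate_dataset(cfg, n_scenes=2, tile=tile)
    pairs = ds.rgb_dsm  # 8 tiles
    spec = NetworkSpec.variant("table1", in_channels=4, width_divisor=width_divisor, tile=tile)
    model = build_model("mobile_unet", spec, seed=seed)
    config = TrainConfig(learning_rate=learning_rate, batch_size=4, epochs=epochs, seed=seed)
    model, history = train(model, pairs, pairs, config)
    return model, history


def train_demo_model(
    seed: int = 0,
    epochs: int = 25,
    tile: int = 64,
    width_divisor: int = 4,
    color_overlap: float = 0.0,
    learning_rate: float = 1e-3,
):
    """Train a small RGB+DSM Mobile U-Net on easy scenes; returns (model, cfg)."""
    cfg = SceneConfig(height=2 * tile, width=2 * tile, color_overlap=color_overlap, seed=seed)
    ds = generate_dataset(cfg, n_scenes=5, tile=tile)
    tr, va, _ = split_dataset(ds.rgb_dsm, seed=seed)
    spec = NetworkSpec.variant("table1", in_channels=4, width_divisor=width_divisor, tile=tile)
    model = build_model("mobile_unet", spec, seed=seed)
    config = TrainConfig(learning_rate=learning_rate, batch_size=4, epochs=epochs, seed=seed)
    model, _ = train(model, tr, va, config)
    return model, cfg


def gradcam_localization(model, base_config: SceneConfig, seeds, layer: str = "dec3"):
    """Does the lodging-class heatmap concentrate on true lodging regions?

    For each seed, generates one fresh tile-sized scene, computes the
    Grad-CAM map for the lodging class, and compares its mean inside the
    true lodging region with its mean outside. Returns a list of
    (inside_mean, outside_mean) per scene.

    The default layer is a mid-decoder stage rather than the bottleneck:
    at the desk-scale tile size (64 px) the bottleneck feature map has only
    4×4 spatial cells — coarser than the lodging blobs themselves — while
    decoder maps retain enough resolution to localize them.
    """
    from .fusion import fuse, normalize_dsm

    tile = model.spec.tile
    out = []
    for s in seeds:
        cfg = replace(base_config, height=tile, width=tile, seed=int(s))
        scene = generate_scene(cfg)
        fused = fuse(scene.rgb, normalize_dsm(scene.dsm), "rgb_dsm")
        heat = gradcam(model, fused, "lodging", layer).values
        lodge = scene.mask.labels == 2
        if not lodge.any() or lodge.all():
            continue
        out.append((float(heat[lodge].mean()), float(heat[~lodge].mean())))
    return out
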