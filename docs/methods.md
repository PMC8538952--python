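# Methods

## Problem and pipeline

Lodging — permanent displacement of wheat stems from vertical — changes
two observable properties of the canopy in UAV imagery: its height (the
surface model drops by at least ~0.2 m relative to standing wheat) and
its appearance (flattened stems expose a brighter, more reflective
canopy, raising the excess-green index). `lodgeseg` segments orthomosaic
tiles into {background, wheat, lodging} by fusing one of these auxiliary
signals onto RGB as a fourth input band and training an encoder–decoder
network on 256×256 tiles (a configurable constant; the scaled-down
protocols below use 64).

Tiles are cut row-major, origin top-left, half-open windows; partial edge
tiles are dropped by default (`pad_reflect` is available for inference on
arbitrary scenes). Eight-bit color is mapped to [0,1] (DN/255); DSM
values stay in meters until normalized.

## Excess-green index

The index is implemented as printed in the method source,
ExG = (2R − G − B)/(R + G + B), with the classical form
(2G − R − B)/(R + G + B) behind `variant="classic"`. The printed
numerator is unusual (it rewards red, not green) and may be a transcription
slip, but the class ordering the method relies on — lodging above wheat —
holds under both forms whenever the lodged canopy is brighter in both red
and green, which is how the synthetic color models are chosen; users of
either variant therefore see the same sign structure. Zero-denominator
(black) pixels map to 0 so borders cannot produce NaNs. When fused, the
index is affinely rescaled from its [−1, 2] range to [0,1] by default so
all four network inputs share a dynamic range.

DSM normalization is per-scene min-max (the method source fuses DSM
without stating a scaling); per-scene scaling preserves the absolute
height gap between lodged and standing wheat within a scene. Nodata
pixels are filled with the scene minimum before scaling; a constant scene
maps to zero.

## Network

The Mobile U-Net encoder has five stages of widths (64, 128, 256, 512,
1024) with 2×2 stride-2 max-pooling after the first four; the decoder
mirrors it with 3×3 stride-2 transposed convolutions (each followed by BN
and ReLU), skip concatenation with the same-resolution encoder output,
and further feature blocks; the head is a 1×1 convolution (with bias) to
3 class maps plus SoftMax. Every feature block is a depthwise-separable
module — 3×3 depthwise (stride 1, same padding, bias-free) → BN → ReLU →
1×1 pointwise (bias-free) → BN → ReLU, the MobileNetV1 convention — with
parameter count 9·c_in + c_in·c_out + 2·c_in + 2·c_out.

The published architecture table and prose disagree on how many modules
each stage contains, and its stride column contradicts its own shape
column. Shapes are taken as authoritative (depthwise convs stride 1,
pools do the downsampling), and the module count is a spec parameter with
three named variants:

| variant  | modules per stage                      | params (4-ch input) |
|----------|----------------------------------------|---------------------|
| `table1` | one everywhere (table read literally)  | 7,699,503 (7.70 M)  |
| `text`   | two in encoder stage 1 and decoder stages 2–4 (prose) | 7,796,271 (7.80 M) |
| `double` | two everywhere (U-Net double-conv pattern, each 3×3 conv replaced by a DS module) | 9,482,671 (9.48 M) |

Only `double` reproduces the published ~9.49 M total (the residual
~0.007 M is attributable to bias-placement conventions the source does
not state), so it is the variant the reproduction script reports;
`table1` is the default for training since it is the cheapest faithful
reading. The baseline is the classic double-conv U-Net (biased 3×3 convs,
no BN, 2×2 up-convolutions, same skip topology): 31,032,451 parameters,
more than 3× any Mobile U-Net variant. Every builder's introspected count
is asserted equal to an independent closed-form per-layer sum.

Weights are He-uniform, drawn from a seeded generator; identical seeds
give bitwise-identical models. Checkpoints are single `.npz` files with
an embedded JSON spec manifest.

### The numpy layer library

No GPU framework is used: `lodgeseg.nn` implements conv / depthwise /
transposed-conv (as the exact adjoint of the matching strided
convolution), batch norm, 2×2 max-pool (gradient to the first maximum on
ties), ReLU, softmax cross-entropy and Adam, all on float32 NCHW arrays
via im2col matrix products. Every layer's backward pass is checked
against central finite differences in float64 in the test suite, and the
transposed convolution against the adjoint identity
⟨conv(y), x⟩ = ⟨y, convᵀ(x)⟩.

## Training recipe

Adam (β = 0.9/0.999, no weight decay, no schedule), learning rate 1e-4,
batch size 4, 200 epochs, unweighted per-pixel cross-entropy — the SoftMax
companion loss, as the source names none. After each epoch training and
validation loss/pixel-accuracy are recorded; the weights with the best
validation accuracy so far are retained, and all reported test metrics
come from that checkpoint. Splitting is a seeded shuffle with floor
allocation at ratios 0.8/0.1/0.1 (remainder to train), so 1500 tiles give
exactly 1200/150/150. Prediction is per-pixel argmax with ties broken
toward the lowest class index. Batch-norm inference uses running
statistics (momentum 0.1).

## Metrics

A single 3×3 confusion matrix (rows = truth) is accumulated over all
evaluated pixels (micro aggregation — the common segmentation convention;
the source does not specify). Precision, recall, F1 and IoU follow the
standard TP/FP/FN definitions (the source's prose garbles FP/FN;
its formulas only make sense with the standard ones). Degenerate 0/0
cases score 0; `miou(..., ignore_empty=True)` averages over non-empty
classes instead. Reports expose both the lodging-class F1 and the macro
average, since published tables are ambiguous about which is meant.

## Augmentation

Only lossless geometric ops: horizontal/vertical flips, 90° rotation,
x–y transposition — pixel permutations from the dihedral group D4,
applied jointly to image and mask, so class frequencies are exactly
invariant. Dataset materialization is offline: originals first, then
`target − n` pairs, each a uniform random op on a uniform random source,
fully determined by the seed.

## Grad-CAM

For a dense head the class score is defined as the spatial sum of the
target class's pre-SoftMax map. Channel weights are spatial means of the
score's gradient at the chosen layer; the map is ReLU of the weighted
activation sum, bilinearly upsampled to tile size and max-normalized
(all-zero maps stay zero). Batch-norm statistics are frozen during the
forward pass so the map reflects the inference-mode network. The default
layer is the encoder bottleneck; the *localization protocol* below
instead measures at a mid-decoder stage (`dec3`), because at the
desk-scale tile size the bottleneck map has only 4×4 spatial cells —
coarser than the lodging blobs it is asked to localize — while decoder
maps retain resolution.

## Synthetic scenes

Layout: background (bare soil) and lodging patches are
quantile-thresholded Gaussian-smoothed noise fields (correlation length
`blob_smoothness`, default 12 px), giving contiguous irregular blobs and
realized fractions that hit their targets up to discretization. DSM =
100 m + smooth terrain undulation (`terrain_amplitude_m`, default 0.1 m)
+ 0.8 m canopy on wheat, 0.6 m on lodging (`lodging_drop_m` = 0.2 m)
+ N(0, 0.03 m) surface noise. RGB is per-class Gaussian color clipped to
[0,1]: soil (0.45, 0.38, 0.30), wheat (0.20, 0.35, 0.25), lodging
(0.35, 0.50, 0.20) — lodging brighter in R and G so its ExG exceeds
wheat's under both index forms. `color_overlap` pulls the lodging color
model toward the wheat one; at 1.0 the classes are color-identical and
only the DSM separates them — the constructed premise of the
fusion-benefit experiment. The terrain default of 0.1 m (a leveled
agricultural plot) keeps that premise true per-pixel: larger undulation
than the 0.2 m lodging drop would bury the height signal after per-scene
min-max scaling.

What the generator does *not* emulate: row structure, growth-stage
phenology, shadows and view-angle effects, photogrammetric DSM artifacts,
spatially correlated color texture. Passing the suites below therefore
demonstrates that the pipeline recovers the statistical structure the
method postulates, not field-scale accuracy on real imagery.

## Desk-scale experiment protocols

All protocols run on one CPU in minutes; sizes are the package's own
scaled-down study conditions.

* **Fusion benefit** (`experiments.fusion_benefit`): per seed (0, 1, 2),
  10 scenes of 128² at `color_overlap` 0.95 → 40 tiles of 64², split
  0.8/0.1/0.1, training partition augmented 2×; Mobile U-Net (`table1`,
  widths/4), Adam lr 1e-3, 30 epochs. Median test mIoU of the RGB+DSM
  model must exceed the RGB-only model's by ≥ 10 points. The scaled lr
  (1e-3, the stock small-model Adam default) replaces the full-scale
  1e-4/200-epoch recipe, which does not converge in 30 epochs at this
  width.
* **Overfit sanity** (`experiments.overfit_sanity`): 8 color-separable
  tiles, 150 epochs; training pixel accuracy must reach 0.95 (it passes
  0.95 around epoch 33 and ends near 1.0).
* **Grad-CAM localization** (`experiments.gradcam_localization`): a model
  trained for 25 epochs on easy RGB+DSM scenes; on 5 fresh scenes the
  lodging-class map's mean inside true lodging regions must exceed the
  mean outside in at least 4.

## Numerical notes and limitations

* All per-pixel 0/0 conventions, tie-breaks and degenerate-input
  behaviors are stated above and tested.
* Training is bitwise-reproducible for a fixed seed on a fixed BLAS
  configuration; across BLAS builds/thread counts results may differ in
  the last float, which can shift a best-epoch choice.
* The exact bias/BN convention behind the published 9.49 M count is not
  recoverable; the `double` variant's 9.48 M is the closest faithful
  reconstruction and both other readings are reported alongside it.
* GeoTIFF support covers axis-aligned geotransforms (pixel-scale +
  tiepoint tags) only; CRS handling and orthomosaic stitching are out of
  scope.
* The published FCN comparison is not implemented: its architecture is
  unspecified in the source material.
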