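# Methods

## The detection model

The detector is a fully convolutional grid classifier. A backbone CNN maps
an RGB image (H × W, any size divisible by the stride) to a feature map at
1/stride resolution; a head of two 1×1 convolutions (feature → hidden →
3), with ReLU, dropout (p = 0.5) and a per-cell softmax, converts each
feature vector into probabilities for *background*, *female* and
*male*. No bounding boxes are predicted: each fly is represented by the
grid cell its box centroid falls into, and detections are points at cell
centres. Bycatch (non-target insects) is deliberately **not** an output
class; it is background the model must learn to ignore.

Two backbones share this head:

| variant   | architecture                                             | stride | features | patch |
|-----------|----------------------------------------------------------|--------|----------|-------|
| `paper18` | 18-layer residual network truncated after its last residual block | 32 | 512 | 512 px |
| `tiny`    | 3 strided 3×3 convs (16/32/64 ch) + one stride-1 3×3 conv | 8  | 64  | 128 px |

The trailing stride-1 convolution in `tiny` widens the receptive field to
31 px, enough to cover one whole fly silhouette at the tiny-profile scale;
without it each cell sees only a fly fragment and the sex cue (wing spots
near the wing tips) is frequently outside the cell's view. Weights are
He-normal initialised; no pretraining is required or used by any test,
though a checkpoint with pretrained backbone weights can be loaded.

All layers (convolution, batch normalisation, max-pooling, dropout,
residual blocks) and their gradients, plus Adam, are implemented in numpy
(`trapgrid/_nn.py`), NCHW float32. Convolution is evaluated as a sum over
kernel offsets of strided slices, which is exact and memory-flat.
Inference disables dropout and uses batch-norm running statistics, so
predictions are bit-reproducible.

## Training

Each epoch crops `patches_per_image` square patches at uniformly random
positions from every training image (an image smaller than the patch is
used whole). The target grid labels a cell DSF/DSM iff a fly-box centroid
lies in its footprint; a clipped box counts iff its centroid is inside the
patch; bycatch centroids are background; when two centroids of different
classes share a cell, the one nearest the cell centre wins. Patches and
target grids are augmented jointly with a uniformly drawn element of the
8-element dihedral group (flips and 90° rotations).

The loss is per-cell cross entropy with class weights. Flies occupy a
vanishing fraction of cells (one cell in ~2000 at full scale), so the
unweighted loss collapses to "everything is background"; `"auto"` weights
use inverse cell-class frequencies over the training set, clamped to
[1, 100]. Optimisation is Adam with a two-phase schedule — defaults
lr 1e-5 for 50 epochs then 1e-6 for 250 at full scale; the tiny profile
uses 2e-3/24 then 2e-4/8, appropriate for training from scratch.
Every `validate_every` epochs the model is validated at full-image scale
with the point-matching metric, and the checkpoint with the best
validation AUC (fly classes combined) is kept; epochs without an AUC pass
fall back to validation loss. Training aborts if the loss becomes
non-finite. The loss function, class weighting and target-assignment rule
are this package's own choices; the centroid rule mirrors the
centroid-based evaluation.

## Inference

Full images are right/bottom reflection-padded to a multiple of the patch
size, tiled, and the per-tile probability grids stitched; cells whose
centres fall in the padding are discarded, so no detection can leave the
original image. Reflection (rather than zero) padding avoids artificial
dark borders — trap edges are already a known false-positive site.
Non-maximum suppression runs once on the stitched grid, so duplicates
straddling tile borders are suppressed. NMS is class-agnostic: a cell's
confidence is max(p_female, p_male); a cell survives iff it beats all 8
neighbours, with equal-confidence ties resolved in favour of the cell
earlier in row-major order (a deterministic rule; on a constant plateau
this keeps non-adjacent representatives). Survivors below a confidence
floor (default 0.05) are dropped to bound output size; evaluation sweeps
thresholds above the floor. The predicted class is the argmax of the two
fly classes.

## Evaluation

Matching is greedy in descending confidence (ties keep insertion order).
Each detection considers only its *nearest* fly-class ground-truth
centroid (Euclidean): farther than the distance threshold (50 px at full
scale) → Fp; already claimed → Fp; wrong class (in per-class mode) → Fp,
even if a correct-class ground truth lies slightly farther but within
threshold — the nearest-neighbour rule is taken literally; otherwise Tp.
Unclaimed ground truths are Fn. Bycatch boxes are excluded from matching
entirely (neither targets nor misses), but false positives within the
threshold of a bycatch centroid are tallied in a diagnostic
`fp_on_bycatch` column, since bycatch is the dominant false-positive
source on real traps.

PR curves sweep thresholds over the sorted unique detection confidences
plus 0; precision is defined as 1 when no detections survive. The AUC is
the trapezoidal area over the achieved (recall, precision) points in
threshold order, anchored at (0, first precision) — no 11-point or step
interpolation. Dataset evaluation pools detections across images
(micro-averaging) but matches strictly within images; the per-sex curves
match same-class detections to same-class ground truths, and "Both" pools
the fly classes under class-agnostic matching. A class with zero ground
truths raises an error rather than reporting an undefined recall.

## The synthetic scene generator

The generator emulates the acquisition the detector is meant for: a red
sticky card with a printed grid occupying most of a cluttered outdoor
frame; dark fly silhouettes (elliptical body, translucent splayed wings,
head) whose **only** sex difference is two dark discs near the male's wing
tips; and bycatch drawn from two families — spotless drosophilid
lookalikes (slightly lighter and smaller than SWD, the realistic confuser
for females) and insects of a different size/shape family. Box areas are
log-normal with mean `fly_area_mean` (default 5700 px², the reference
photography's average; σ_log = 0.42, putting ~95% of areas within a
factor ~2.3 of the mean) and box aspect is jittered ±15% around 1:1.3.
Insects are axis-aligned (portrait or landscape at random); arbitrary
rotation is left to the dihedral training augmentation. Illumination can
be uniform, a lateral gradient, or a soft elliptical shadow; placement
keeps size-aware separation between insects unless `cluster_prob`
deliberately places one insect adjacent to/overlapping another to create
the occluded regime that defeats grid detectors. `degrade_uav` emulates
aerial acquisition: Gaussian defocus, framing offset (with boxes shifted,
clipped, and dropped when fully outside), and blur-proportional noise.

What the generator does **not** emulate: photorealistic texture, specular
glue reflections, insect damage/aging, true drosophilid anatomy, and
pixel-intensity statistics of real traps (no such statistics are
published; the palette and the 10-grey-level box-vs-card contrast margin
are generator parameters, not claims about real data). Passing the
synthetic-recovery tests therefore shows the pipeline is correct and
trainable, not that the reported real-image accuracies transfer.

## Profiles and problem sizes

The `paper` profile keeps the full-scale settings (5472×3648 frames,
512-px patches, stride 32, 5700 px² flies, 50 px matching radius, 300
epochs). The `tiny` profile scales geometry by 1/4 linearly — 256×256
scenes, ~356 px² flies, stride 8, 12.5 px radius, 128-px patches — and
trains for 32 epochs, so a full train/evaluate cycle takes about a minute
on one CPU. The end-to-end checks train on 40 generated scenes (32 train /
8 validation) and evaluate on 10 held-out scenes with well-separated flies
(`cluster_prob = 0`); under these conditions the combined AUC is ≈0.9–0.95
and male AUC exceeds female AUC, the asymmetry expected when wing spots
are the only sex cue and spotless lookalikes are present.

## Numerical and interface choices

- Boxes are 0-based half-open internally; Pascal VOC XML stores 1-based
  inclusive coordinates, converted only at the I/O boundary. Which
  convention the original labelling tool intended is not documented; this
  choice is applied consistently on read and write, so round-trips are
  exact.
- Dataset splits use largest-remainder rounding of n·fractions (exact
  partition, deterministic per seed). 249 images at 70/20/10 give
  (174, 50, 25).
- Cell-centre readout: a detection sits at origin + ((col+0.5)·stride,
  (row+0.5)·stride).
- Model checkpoints are `.npz` arrays plus a JSON sidecar with the
  detector configuration.
- Degenerate inputs fail loudly: unknown class names, out-of-image boxes,
  non-divisible input sizes, zero ground truths, non-finite losses and
  unplaceable insect counts all raise typed errors.

## Known limitations

- The numpy engine is single-threaded and CPU-bound; the `paper18`
  variant is provided for architectural fidelity and inference-shape
  checks, but training it at full scale is impractical here.
- NMS cannot separate two flies whose centroids fall within one grid cell
  (stride 32: 32 px); clustering and occlusion degrade recall by design.
- The wrong-class-nearest-neighbour matching rule can under-credit a
  detector when two different-sex flies are close together; the literal
  rule is implemented and documented rather than second-guessed.
- AUC values depend mildly on the integration convention; trapezoidal
  integration over achieved operating points is used throughout, so
  comparisons should use the same convention.
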