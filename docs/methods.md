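# Methods

This note records the models, the parameter choices, and the reasoning
behind the design decisions that were genuinely open.

## Synthetic scenes as the study system

The generator (`cdpd.synthetic_scenes`) emulates the *structure* of pest
photographs — multi-object scenes of K ≥ 2 classes on textured
backgrounds, with boxes and pixel masks that are mutually consistent —
not their appearance.  Objects are filled ellipses (even classes) or
jittered star polygons (odd classes) with hue-coded colours; polygon
vertices sit on evenly spaced angles with bounded jitter so every object
rasterizes to one connected component.  Objects are placed with a 2-px
guard band and whole-scene restarts, so the object count always equals
the connected-component count of the mask.  Images are quantized to the
8-bit grid at generation, which makes the PNG round-trip bit-exact.
Boxes are 0-based half-open pixel intervals internally; the YOLO
normalized centre format (6 decimals) exists only at the file boundary,
with the COCO-style JSON carrying full-precision coordinates.

Seven photometric corruptions stand in for deployment-time weather
shifts.  Severity `s ∈ [0,1]` maps to physical parameters through fixed
constants (gain `1+0.8s` for brightness, `1−0.7s` for darkness, noise
σ = 32s on the 0–255 scale, peak fog alpha `0.8s`, `round(40s)` rain
streaks, `round(60s)` snow blobs, flip probability `0.2s` for
salt-and-pepper); `s = 0` is the identity for every kind.  All
corruptions are photometric, so labels are invariant by construction.
Real weather imagery is deliberately not used; the corruptions are
procedural so the package has no data dependencies.

What passing tests on these scenes show: that the *mechanisms* — the
losses, the gates, the adaptation loop — behave as specified.  What
they do not show: performance on real pest imagery, which has texture,
occlusion, scale variation and label noise the generator does not
emulate.

## Strong and weak augmenters

The strong augmenter is a small residual encoder–decoder (stride-2
down, residual mix, nearest-neighbour up) whose final convolution is
initialized at scale 1e-3, so the untrained generator is near-identity
and early augmentations are label-preserving.  Its classifier is a
small trainable K-class sigmoid network with the same input/output
contract as a fine-tuned large classifier; no pretrained weights are
shipped.  Default loss weights α = 0.01, λ_bce = 0.4, λ_d = 0.6,
λ_dif = λ_bdf = 0.5; the batch-diversity loss is computed as pairwise
differences between augmented images, the reading that makes its double
sum non-vacuous.  The augmenter trains for 10 rounds by default and the
final 3 rounds of outputs are retained (3× the originals).  Degenerate
batches (n < 2) give `L_bdf = 0`; probabilities are clamped to
[1e-7, 1−1e-7] before logs.  The classifier trains on both augmented and
original images.  Weak rounds pair one noise level and one brightness
draw per image, brightness applied first — the composition order is a
fixed convention.

## Gates and the dual-branch model

The gate's "fully connected layer" acts on the global-average-pooled
channel descriptor, giving a per-channel gate `x ∈ (0,1)^C` broadcast
over space; the transform is a 1×1 channel-mixing affine followed by
exact (erf-based) GeLU, so the message matches the source map's shape
and the parameter count is independent of resolution.  Cross-branch
channel mismatches are resolved by a learnable 1×1 projection on the
source side (identity when counts match).  Both fusion directions are
computed from pre-fusion features — a simultaneous update, so fusion is
order-independent.  Transforms are initialized at scale 0.05; zeroing
them makes the dual-branch forward bitwise-equal to two independent
single-branch forwards, which is both a test and a safety property.

The toy backbone is a stack of 3×3 stride-2 convolutions with leaky
ReLU (default 3 stages, channels 8/16/16, 48×48 inputs → 6×6 grid).
The detection head is anchor-free: per grid cell a sigmoid-bounded
centre offset, softplus sizes in stride units (softplus rather than a
bounded squash so oversized boxes keep a usable gradient and cannot
saturate), an objectness logit (bias-initialized to −2, the
most-cells-are-empty prior) and per-class sigmoid probabilities.  The
segmentation head is a small top-down pyramid decoder over the
post-fusion auxiliary features with a full-resolution 3×3 sharpening
convolution and a −2 foreground-prior bias; the pyramid is what lets the
Dice loss reach small values at pixel resolution.

## Training

`L_total = L_main + λ·L_aux` with λ = 1 by default.  `L_main` is class
BCE over matched positives (summed over classes, averaged over
positives) + (1 − mean IoU of matched pairs, worst-case 1 when nothing
matches) + objectness BCE averaged over all cells; `L_aux` is the Dice
loss, 0 when prediction and target are both empty.  One optimizer holds
the main, auxiliary and gate parameters; the gate group has its own
rate (0.02).  The optimizer is SGD with momentum 0.9 and global
gradient-norm clipping at 5 — without momentum the uniformly normalized
objectness term crawls, and without clipping the Dice term occasionally
destabilizes the auxiliary branch at the schedule's peak.  The learning
rate ramps up linearly over the first 5% of epochs, then follows either
the linear schedule between the configured endpoints (the printed
configuration gives an increasing 0.05 → 0.1 ramp, kept as the default
reading) or a cosine decay (the conventional alternative, used by the
toy experiments with 0.04 → 0.004).

Matching: evaluation and adaptation match predictions to boxes greedily
by IoU at threshold 0.5 with lower-index tie-breaks.  Training instead
assigns each target to the grid cell containing its centre (the
standard one-stage assignment).  The greedy matcher cannot bootstrap an
untrained model — nothing clears the threshold, the IoU term pins at
its worst case, and no box gradient flows — so a deterministic
assignment is the only way the training criterion can be met; after
convergence the two matchings agree.

Toy problem sizes (chosen for single-CPU runtimes): the overfit sanity
check uses 8 single-object 48×48 scenes and 500 steps; the generaliz-
ation experiments use 40 training scenes and 120 epochs, which reach
mAP50 ≈ 0.8 on held-out clean scenes.

## Test-time adaptation

Each test image spawns `num_variants = 16` images: 5 noise-only, 5
brightness-only, 6 combined, with parameters on deterministic uniform
grids (noise std up to 12/255, brightness factor in [0.7, 1.3], offset
in [−0.3, 0.3]) and seeded noise draws.  All variants are
intensity-only, so pseudo-label boxes need no coordinate remapping.  A
result's confidence is the mean post-NMS box confidence (0 with no
boxes); the argmax across variants supplies the box pseudo-labels (from
the detection branch) and that same variant's auxiliary output, binar-
ized at 0.5, supplies the mask pseudo-label.  Ties resolve to the
lowest variant index.  Selection is per-image.

The adaptation loss is computed on the original image's predictions,
not averaged over variants.  `L_cls` is cross-entropy against pseudo-
class one-hots over matched pairs; `L_loc` is the summed squared
difference of the four box parameters normalized by image size;
`L_conf` is objectness BCE with targets from pseudo-confidence
binarized at 0.5; `L_aux` is the per-pixel squared mask error
normalized by H·W so λ's balance is resolution-independent.  Updates
touch the main and auxiliary parameters with plain SGD at η (default
1e-4 in the config; the stream experiments use 1e-3, about 1/40 of the
training rate); gates stay frozen during adaptation by default
(`adapt_dag` enables them) while fusion itself remains active in every
forward pass.

Two stabilizers guard against self-training error accumulation, the
known failure mode of pseudo-label methods on long streams:

* **Confidence gate** — the update is skipped when the selected
  pseudo-label is empty or its mean confidence is below
  `min_confidence` (default 0.25): an image the model cannot label
  carries no usable self-supervision, and training all objectness
  toward zero on such images collapses the detector.
* **Objectness ignore region** — unmatched predictions whose own
  confidence is ≥ 0.25 are excluded from `L_conf` instead of being
  pushed toward zero.  Pseudo-labels systematically miss second objects
  under strong shifts; penalizing those genuine detections as negatives
  erodes recall over the stream.  Only matched predictions and weak
  unmatched ones enter the sum.

Both were adopted after stream-level experiments showed confidence
erosion on multi-object scenes; with them, adaptation on a darkness-
shifted stream improves last-quartile mAP50 substantially when the
frozen model is degraded and leaves it essentially unchanged when the
frozen model is already robust.

## Metrics

mAP uses COCO-style 101-point interpolated precision–recall integration
(the de-facto standard of YOLO tooling), averaged over classes present
in the truths, then over IoU thresholds (0.5; or 0.50:0.05:0.95).
Precision/Recall are reported at confidence 0.25 — an operating point
that must be fixed by convention.  Inference applies class-wise NMS at
IoU 0.5, score 0.25.  The confusion matrix matches class-agnostically
(so cross-class confusions are visible) with background row/column for
unmatched predictions/truths.  Segmentation quality is tracked through
the Dice loss of the auxiliary branch on the binary foreground mask.

## Numerical conventions

Float64 throughout.  Probabilities clamped to [1e-7, 1−1e-7] before
logs; IoU denominators carry a 1e-12 epsilon (degenerate boxes give
IoU 0); `σ(z)` and box decodes are computed in stable forms; clip
passes gradients only inside the range.  Determinism: every source of
randomness is a `numpy` Generator seeded from an explicit seed via
`SeedSequence`; per-image variant seeds in a stream depend on (domain,
image index), not stream position, so reordering domains isolates the
effect of carried-over adaptation state.

## Known limitations

* The scenes are far easier than real pest imagery; absolute metric
  values do not transfer.
* The toy backbone's 6×6 grid resolves at most one object per cell;
  crowded scenes need a finer grid or a real backbone behind the same
  stage contract.
* The increasing linear learning-rate schedule is kept as the default
  reading of the configuration it mirrors, but the cosine option is
  what the toy experiments use; at toy scale the increasing ramp is
  usable but slower to converge.
* Adaptation gains depend on the shift actually degrading the frozen
  model; on mild shifts the stabilizers make TTA a near no-op rather
  than a win.
* The numpy engine is single-threaded and eager; it is sized for these
  experiments, not for production training.
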