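# Methods

This note records the models, conventions and design decisions behind
`pestdet`, in the order data flows through the package.

## Numerical substrate

No GPU deep-learning framework is used.  `pestdet.autograd` is a small
tape-based reverse-mode autodiff over float32 NumPy arrays whose
primitives are exactly the operations a one-stage convolutional detector
needs.  Convolutions use the shift-and-GEMM scheme (one BLAS contraction
per kernel offset), so forward and both backward passes are exact, and
every primitive is verified against central finite differences in the
test suite.  All randomness flows through seeded
`numpy.random.Generator` objects; training runs, synthetic datasets and
anchor fits are bit-reproducible under their seeds.

## Architecture

The default ("proposed") detector:

| stage | block | output (512 input) |
|---|---|---|
| stem | Focus: 2×2 space-to-depth + conv | 14×256×256 |
| stage 1 | conv s2 + C3(n=3, SK) | 28×128×128 (P2 tap) |
| stage 2 | conv s2 + C3(n=3, SK) | 56×64×64 (P3 tap) |
| stage 3 | conv s2 + C3(n=3, SK) | 112×32×32 (P4 tap) |
| stage 4 | conv s2 + SPP(5/9/13) + C3(n=3, SK) | 224×16×16 (P5) |
| neck | PANet top-down to stride 4 and bottom-up | P2–P5 |
| heads | 1×1 conv, 3 anchors × (5+K) channels | 128/64/32/16 grids |

The unmodified small baseline used for the layer comparison keeps the
same widths but repeats (1,3,3,1), no SK attention, and a three-scale
(P3–P5) neck.  Every conv unit is conv → batch norm → SiLU.

**Layer counting convention** (the "module-summary" count used by the
complexity report): each conv/BN-act unit, bottleneck (counted once as a
whole, regardless of the SK layer inside), pooling layer, upsample,
concatenation, space-to-depth and per-scale head counts once; C3 counts
its three 1×1/fusion convs plus its n bottlenecks; SPP counts 2 convs +
3 pools + 1 concat.  Under this convention the proposed model has 79
layers, the baseline 61: +4 from thickening the shallow CSP stages to
the uniform depth of the deeper ones, +14 from the extra P2 neck branch
(conv, upsample, concat, C3 top-down; conv, concat, C3 bottom-up; one
extra head) — a delta of exactly 18.

**Width calibration.**  The reference publication reports the proposed
model at 4.8 GFLOPs while the small model it extends sits at 16,
implying an undisclosed width scaling.  The stage widths of the default
spec, (14, 28, 56, 112, 224) — a clean ×2 progression — were calibrated
once so the analytic count (MAC×2, full forward at 512×512, convolution
and FC layers) lands at 4.78 GFLOPs, i.e. 4.8 at the printed precision.
Elementwise BN/activation/pooling traffic is excluded from the headline
number and available behind a flag (it adds ≈3%).

**Selective-kernel attention.**  Split: bias-free 3×3 and 5×5 branches
U₁, U₂ at constant channel count.  Fuse: global average pooling of
U = U₁+U₂, then FC(C→d) → BN → ReLU → FC(d→C) → sigmoid with
d = max(C/r, 8), r = 16.  Scale: one shared weight vector multiplies
both branches, V = (U₁+U₂)⊙a — the printed form of the modified block,
unlike classic SK-Net's per-branch softmax, which remains available
behind `classic_softmax`.  Sigmoid outputs are clamped to
[10⁻⁶, 1−10⁻⁶] so the open-interval contract survives float32
saturation.  The block sits after the 3×3 conv inside every backbone
bottleneck.

**Decode.**  Per anchor and cell: center = (2σ(t_xy) − 0.5 + cell)·stride,
size = (2σ(t_wh))²·anchor, score = σ(obj)·σ(cls) — the v5-family
parameterisation, adopted because the head symbols t_x, t_y, t_w, t_h are
named without a transform.  Candidates whose size underflows to zero
width/height in float are dropped.  NMS is class-wise greedy by
descending score (ties broken by input order), suppressing IoU > 0.45;
default confidence threshold 0.25.

**Anchors.**  k-means on pixel (w, h) under the 1 − IoU(wh) distance:
k-means++ seeding with that same distance, Lloyd updates by cluster
mean, 8 restarts, empty clusters re-seeded at the worst-covered box.
Hand-rolled because library k-means implementations do not accept this
metric.  Anchors are sorted by area into ascending triples, one per
scale; with fewer boxes than anchors the default table is used with a
warning.  `train()` refits anchors to the training labels by default.

## Loss and target assignment

A label is assigned to an anchor at a scale when
max(w/a_w, a_w/w, h/a_h, a_h/h) < 4, at its containing cell plus the
nearer horizontal and vertical neighbour cells.  Per layer:
box = mean(1 − CIoU) over assigned slots; class = logistic cross-entropy
on the K class logits at assigned slots (one-hot targets); objectness =
logistic cross-entropy over every slot with positive targets set to the
detached, zero-clamped CIoU and layer balance weights 4.0/1.0/0.4/0.1
(P2→P5).  Term gains default to box 0.05, objectness 1.0, class 0.5.
The reported total is exactly the sum of the three weighted components.
In the CIoU gradient the α coefficient is held constant (the usual
stabilisation).  The CIoU value itself lies in (−2, 1]; the loss term
1 − CIoU is therefore bounded in [0, 3) per slot and zero only for a
perfect box.

## Normalisation statistics at very small batches

CPU-scale training uses batches of 1–2 images.  There, BatchNorm's batch
statistics are image-specific: the network trains well against them but
its running-average statistics describe no image in particular, and
inference quality collapses (observed directly: ~90% training-loss
reduction with near-zero eval mAP).  Two remedies are implemented:

* `ModelSpec.norm_stats="instance"` — every 4-D normalisation uses the
  sample's own spatial statistics in training *and* inference.  The
  network is then deterministic per input, batch-size independent, and
  has no train/eval statistics gap.  This is the configuration of the
  convergence check below.  (The 1-D normalisation inside the SK fuse
  path keeps running statistics; a single channel descriptor has no
  spatial extent to normalise over.)
* `TrainConfig.bn_freeze_fraction` — classic batch norm, with running
  statistics frozen partway through training so the late optimisation
  phase targets the inference-time network.

The default spec keeps classic batch-norm semantics ("running").

## Training

SGD with momentum 0.937, weight decay 5·10⁻⁴ applied to conv/FC weights
only, global gradient-norm clipping at 10, linear warmup followed by a
cosine decay to a final-lr fraction, horizontal flips and centre scale
jitter (0.8–1.25) as default augmentation, and per-epoch validation
with best-mAP@0.5 checkpoint retention.  Defaults follow the published
protocol where stated (200 epochs, batch 10, SGD); the learning-rate
schedule, gains and clipping are package choices, configurable in
`TrainConfig`.  A non-finite loss aborts with diagnostics rather than
continuing.  Head biases are initialised to a low objectness prior
(≈8 objects per image per scale) and near-uniform class priors.

## Synthetic scenes

The generator emulates the statistical structure of the five-class field
collection — per-class image counts (392/315/148/392/318), one primary
object per image, few small objects against backgrounds of matching hue
and texture, optional unlabeled distractor blobs — with class-separable
parametric glyphs (segmented body + legs for ants; elongated body and
hind legs for grasshoppers; snouted oval for palm weevils; pentagonal
shield; striped body with wings for wasps).  Object long sides are drawn
from Beta(1.2, 3.5) over the configured fraction range (default
0.04–0.25 of the image side), so the default size distribution is
dominated by the small-object band (w·h < 0.04) the P2 head targets.
Every label is the tight bounding box of the glyph's rendered support,
making label/mask agreement exact by construction.  What the generator
does **not** emulate: photographic texture, occlusion, lighting,
pose/viewpoint variation, class-imbalanced scenes with many instances.
Passing tests on these scenes therefore validate the machinery
(rendering → labels → assignment → loss → optimisation → evaluation),
not field-accuracy claims on real imagery.

## Problem sizes used in the checks

The convergence check trains on 20 scenes at 64×64 (one object each,
long-side fraction 0.45–0.7, no clutter), batch 1 — 1000 SGD steps in 50
epochs, about two minutes on one CPU — with instance normalisation,
lr 0.12, momentum 0.9, no augmentation, cosine to 0.05·lr.  Observed:
88% total-loss reduction and train mAP@0.5 = 1.0 of the retained best
model.  Architecture quantities (layer delta 18, 4.78 GFLOPs) are
computed at the full 512 working size.  Brute-force oracles run at
500 boxes (NMS), 1000 random pairs (CIoU), 100 random maps (SK
identities).

## Known limitations

* NumPy execution: full-resolution (512) training is possible but slow;
  the package is meant for method study and desk-scale experiments, not
  production training runs.
* Instance-statistics mode deviates from classic BatchNorm inference;
  models trained in one mode should not be evaluated in the other.
* The mAP IoU threshold is fixed at 0.5 (the model family's customary
  headline metric); COCO-style mAP@[.5:.95] is out of scope.
* The synthetic scenes cannot support claims about real-field accuracy;
  absolute detection metrics on the unreleased collection are not
  reproducible here and are not asserted anywhere in the package.
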