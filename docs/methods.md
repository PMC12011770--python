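# Methods

## Scope and model

`pdyolo` implements a single-stage weed detector for RGB field imagery.
The architecture augments a nano-scale CSP backbone with a
parallel-focusing feature pyramid (PF-FPN) and a dynamic detection head:

* **Backbone.** Conv(3x3, stride 2)+BN+SiLU stems, C2f
  split-bottleneck-concat blocks (depths [1,2,2,1] after the 0.33 depth
  multiplier), and a terminal SPPF with kernel 5.  Width multiplier 0.25
  over the base plan (64, 128, 256, 512, 1024) gives taps C1/C2/C3 with
  64/128/256 channels at strides 8/16/32, plus an internal stride-4 tap
  used by the neck.  Batch-norm uses momentum 0.03 and eps 1e-3.

* **ELA (efficient local attention).** Per-axis strip means, a depthwise
  1-D convolution (kernel 7, bias-free) along the pooled axis, group
  normalisation with 16 groups (falling back to one group per channel
  below 16 channels), and a sigmoid.  The attention map is the outer
  product of the two axis gates, hence rank <= 1 per channel and bounded
  in (0, 1).  The printed normalisers of the strip-pool definitions mix
  up the two axes; the implementation uses true means over the summed
  axis.  The 1-D convolutions use edge-replicate padding so a constant
  feature map yields an exactly flat gate (0.5 after normalisation); the
  kernel size 7 follows the original ELA design.

* **FFAM.** The three taps are co-registered on the stride-16 grid: the
  stride-8 branch through a 3x3/stride-2 conv, the stride-16 branch
  through a 3x3 conv, the stride-32 branch through nearest x2 upsampling
  plus a 1x1 conv.  (As printed, the alignment equation assigns the
  stride-2 conv to the mid branch, which cannot co-register the three
  grids; the roles of the low/mid transforms are swapped.)  Fusion is
  `MS = ELA(high)*low + high + ELA(mid)*mid`, followed by a parallel
  depthwise bank with kernels k_m = (m+1)*2+1 = [5,7,9,11], an identity
  path and a plain 1x1 pointwise fusion (`MC`), and the residual output
  `F' = MS + MC`.  `MC` keeps its internal `+MS` residual *and* the
  output adds `MS` again, following the printed composition literally.

* **HARFM.** The shallower lateral input is projected by a 3x3 Conv+BN+
  SiLU (stride 2 when its grid is twice as fine) to the deeper level's
  channel count and concatenated (2*C2 channels).  The gate is a
  bottleneck — 1x1 down to 2*C2/r, two depthwise 3x3 convolutions
  (edge-replicate padding), 1x1 back up, ReLU after every convolution —
  then GroupNorm(16) and a sigmoid; output `Fout = gate*FC + FC`.  The
  printed text types the bottleneck once as C2/r and once as 2C2/r;
  2*C2/r is adopted because the restoring 1x1 returns to 2*C2.

* **PF-FPN wiring.** One radial FFAM aggregates {C1, C2, C3} and its
  output is redistributed to each level (nearest x2 up / identity /
  3x3-stride-2 down, each with a 1x1 channel-matching conv).  Because a
  1x1 conv (+BN+SiLU, all per-pixel per-channel maps) commutes exactly
  with nearest upsampling, the stride-8 match conv is applied before the
  resize, which is functionally identical and cheaper.  One HARFM per
  lateral path recalibrates each backbone level against its adjacent
  shallower tap (the stride-8 path uses the internal stride-4 feature).
  Per level, the redistributed radial stream and the lateral stream are
  concatenated and fused by a C2f block.  The source figures are
  ambiguous about the HARFM<->FFAM dataflow direction; this wiring keeps
  both data paths (lateral recalibration and radial aggregation) and is
  a documented design choice.  With FFAM and HARFM disabled the neck
  reduces to the classic top-down/bottom-up lateral C2f pyramid
  (PA-FPN), which is the baseline ablation.

* **Dynamic head.** Levels are projected to a common width, resampled to
  a shared grid and processed by sequential blocks of scale-aware,
  spatial-aware and task-aware attention (in that order).  Scale: a
  hard-sigmoid of a linear map of each level's global mean.  Spatial:
  modulated deformable 3x3 sampling (K = 9, bilinear interpolation,
  out-of-bounds reads as zero) with offsets and masks predicted from the
  median level; each output level averages deformable convolutions of
  itself and its adjacent levels with separate weight banks, then
  GroupNorm + ReLU.  Task: `max(a1*x+b1, a2*x+b2)` per channel with
  coefficients from a pooled two-layer bottleneck, squashed to (-1, 1);
  a1 is offset by +1 so the initial activation is a standard rectifier.
  The common grid is the deepest (stride-32) level: with a stride-16
  grid the spatial attention costs ~12.6k FLOPs per added parameter and
  no hyperparameter assignment reproduces the published budget, whereas
  the stride-32 grid matches the published head cost (~3.1k FLOPs per
  parameter) while preserving the level-space-channel decomposition.

* **Detect head.** Decoupled per-level branches: two 3x3 Conv+BN+SiLU
  then a 1x1 output for the class logits and for the 4 x 16-bin
  distribution-focal box logits.  Hidden widths follow the YOLO-family
  rule (c2 = max(16, c/4, 64), c3 = max(c, min(nc, 100))).  Class biases
  initialise to -4.6 (~1% prior), box biases to 1.

## Canonical configuration and budget accounting

Free hyperparameters never stated for the architecture were resolved
jointly against the published parameter/FLOP budget and ship as the
canonical config: FFAM width C' = 112, HARFM reduction r = 16, dynamic
head width 80 with 2 blocks.  The resulting budgets (12 classes,
640x640):

| build                     | params (M) | GFLOPs |
|---------------------------|-----------:|-------:|
| baseline (all blocks off) |      3.01  |   8.1  |
| full PD-YOLO              |      3.97  |  10.6  |
| difference                |      0.96  |   2.5  |

Parameter counts are exact integers summed over modules.  FLOPs are
layer-wise closed forms counting each multiply-accumulate as two FLOPs
for convolutions, linear layers and the deformable projection;
normalisation, activations, pooling and resampling are not counted
(the convention under which the baseline reports its published 8.1 G).

## Compute core

All layers run on the package's own NumPy reverse-mode autodiff core
(`pdyolo.nn`): conv2d via im2col + matmul with hand-written backward,
BatchNorm/GroupNorm with exact backward through batch statistics,
max-pool, nearest resize, and bilinear gathering for deformable
sampling.  Gradients flow to sampled features and modulation masks; the
sampling *offsets* are treated as constants in backward (the derivative
of the bilinear weights w.r.t. the offsets is not propagated).  This
leaves the forward pass exact — the dense-convolution equivalence holds
to 1e-5 — and in training the offset predictor still adapts through its
other output (the masks) and the surrounding layers.  Weight init is
uniform Kaiming-style from a dedicated stream reseeded by
`nn.seed_init`, so two builds from the same seed are bit-identical.

## Training

SGD with momentum 0.937, weight decay 5e-4 (conv/linear weights only),
lr 0.01 with 3-epoch linear warmup and cosine decay to 1%.  Loss:
task-aligned assignment (metric score^0.5 * IoU^6, top-10 anchors whose
centre lies inside the box; ties to the higher-IoU ground truth),
binary cross-entropy weighted by the normalised alignment metric,
complete-IoU box loss, and a two-bin distribution-focal term, weighted
0.5/7.5/1.5 and normalised by the summed target scores.  Mosaic
augmentation (2x2 composite, boxes clipped, sub-2-px boxes dropped) is
active only before the configured cutoff epoch (default 15).
Non-finite loss aborts with a diagnostic.

## Evaluation

mAP uses class-wise greedy matching by descending score (ties broken by
larger box area, then class id), one detection per ground truth, and
101-point interpolated precision-recall integration; mAP@0.5:0.95
averages IoU thresholds 0.5 to 0.95 in steps of 0.05.  Classes without
ground truths are excluded from the mean.  Dataset precision/recall are
reported as plain counts over all detections (IoU 0.5) plus the max-F1
operating point.  TIDE decomposition assigns every non-true-positive
detection to exactly one of {Cls, Loc, Both, Dupl, Bkg} with foreground
IoU 0.5 and background IoU 0.1 (the cited defaults), checked in that
order; unmatched ground truths are Miss, and FP/FN are residual rates
(detection-side errors over detections, Miss/FN over ground truths).

## Synthetic scenes

The generator emulates the stated challenges of the field datasets —
occlusion, large scale differences, small targets, textured soil — not
their photometric realism.  Backgrounds are multi-octave value noise in
soil tones; plants are procedurally drawn rosette/star/ellipse
silhouettes with class-conditioned, well-separated colour palettes
(nearest-centroid colour classification of single-object crops exceeds
90%, so the classes are learnable by construction).  Placement enforces
the requested occlusion probability and small-target fraction
(silhouettes under 1% image area); labels are tight boxes extracted
from the rendered masks, exact by construction.  A scene is fully
determined by (seed, index).  Passing tests on these scenes demonstrates
the training and evaluation machinery end to end; it does not
demonstrate field-data accuracy, which requires the real datasets and
GPU-scale training.

## Desk-scale problem sizes

The end-to-end smoke experiment trains the full model on 64 scenes of
64x64 px with 1-2 large objects of 3 classes, batch 4, up to 100 epochs
without mosaic, evaluating on the training set every 5 epochs and
stopping once training-set mAP@0.5 reaches 0.9.  These sizes were chosen
so the whole experiment runs on a single CPU in minutes; the published
protocol (640x640, 200 epochs, mosaic off after epoch 15, 8:1:1 splits)
remains the default for real datasets.

## Known limitations

* Offsets detached in the deformable backward (above).
* The FLOP counter instruments the compute primitives themselves
  (conv/linear/deformable projection), so any model assembled from
  `pdyolo.nn` layers is covered; uncounted op classes (norm, activation,
  pooling, resize) are a stated convention, not omissions.
* Letterboxing uses bilinear resize via Pillow; sub-pixel differences
  from other resize implementations are possible.
* The TIDE report is count-based; it does not reproduce the
  mAP-impact weighting of the original tool.
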