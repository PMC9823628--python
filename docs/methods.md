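# Methods

## Model

The detector is a one-stage anchor network in the small configuration:
CSP-Darknet backbone (Focus entry, CBS = conv + batch-norm + SiLU units,
CSP blocks, spatial pyramid pooling), a PANet neck producing feature maps
at strides 8/16/32, and a 1×1-conv head emitting, per anchor and grid
cell, 4 box offsets, an objectness logit and one class logit (the pear
task is single-class). Depth multiple 0.33 and width multiple 0.50 set
the block repeats and channel widths; anchors default to the stock COCO
priors, defined in pixels at a 640 input and rescaled proportionally for
other input sizes. CSP blocks split their input into a feature-extraction
path (with residual units in the backbone, without in the neck) and a
cross-stage path, concatenated and mixed by a 1×1 conv; bottlenecks run
at full block width.

Boxes decode as `xy = (2σ(t_xy) − 0.5 + cell) · stride` and
`wh = (2σ(t_wh))² · anchor`.

### Variants

The neck paths are named by resolution: P1 = stride 8 (high resolution),
P2 = stride 16, P3 = stride 32.

* **SC** adds two skip connections carrying pre-fusion feature maps past
  the neck's CSP blocks. The published description fixes only the bypass
  counts — one feature-extraction module bypassed into P2's fusion point
  and two into P3's — not the wiring. We implement both skips as
  parameter-free stride-2 max-pools: the concat feeding P1's CSP is
  pooled and appended to P2's fusion concat (bypassing that CSP), and
  P2's enlarged fusion concat is pooled and appended to P3's fusion
  concat (so a component arriving at P3 through both skips has bypassed
  two CSPs). Choosing pooled identity maps rather than learned
  projections keeps the skips cheap; the resulting cost increment of the
  SC variant over the baseline (+0.33 M parameters, +0.42 GFLOPs at 640)
  closely matches the published ablation table's step, which supports
  the reading. The wiring is stored as an explicit layer graph, so the
  bypass counts are verified by graph traversal in the tests.
* **TE** replaces the CSP in P3 with a transformer encoder. The encoder
  is shape-preserving: a multi-head self-attention sublayer and a
  convolutional feed-forward sublayer (two pointwise convs, expansion 4,
  SiLU), each residual, batch-norm applied before each sublayer and
  dropout after each transform. Since the replaced CSP also reduced
  channels, a 1×1 CBS precedes the encoder. Head count 4, dropout 0.1,
  embedding width equal to the channel count at the insertion point, and
  no positional encoding — these internals are unstated in the source
  description and are declared choices; absence of positional encoding
  makes the attention sublayer spatially permutation-equivariant, which
  the tests exploit.
* **TC** replaces the CSP in P2 with CSP-FF: the two parallel CSP paths
  become a convolutional path (one bottleneck — local features) and a
  transformer-encoder path (global features), fused by AFF, then a 1×1
  channel-balancing CBS.
* **FP** applies all three.

AFF computes `out = M·X + (1−M)·Y` with `M = σ(local(Z) + global(Z))`,
`Z = X + Y`; the local branch is a pointwise bottleneck (reduction 4) at
full resolution and the global branch the same bottleneck after global
average pooling. The output is therefore an elementwise convex
combination of its inputs — an invariant asserted in the tests. The
reduction ratio 4 is our choice.

### Parameter/FLOP accounting

FLOPs are counted as 2 × multiply-accumulates over convolution and matrix
product layers (attention included; batch-norm and activations excluded),
measured by instrumenting an actual forward pass at the requested input
size. Under this convention the baseline at 640 counts 16.28 GFLOPs and
7.064 M parameters. We do not attempt to reproduce the published memory/
FLOP figures of the modified variants, which depend on unpublished block
hyperparameters.

## Loss and assignment

The composite loss is
`w_box · mean EIoU + w_obj · BCE(objectness) + w_cls · BCE(class)`, with
stock weights (0.05, 1.0, 0.5), objectness balanced per scale
(4.0/1.0/0.4) and scaled by batch size. EIoU adds center-distance and
width/height penalties, each normalised by the enclosing box, to
`1 − IoU`; it is zero iff the boxes coincide and invariant to joint
translation/scaling. All denominators carry a 1e-7 guard. Targets follow
the stock multi-anchor rule: a target matches each anchor whose w/h ratio
is within 4.0, in its own cell and the two nearest neighbouring cells;
objectness targets at assigned positions are the detached decoded IoU.
With a single class the class logit is still trained (toward 1 at
assigned positions) so that confidence = σ(obj)·σ(cls) stays calibrated;
per-scale component means are averaged across scales.

Two printed details of the source formulas required interpretation: the
IoU formula as printed is inverted (union over intersection), and the
height penalty prints an ambiguous exponent; both are implemented in the
only form consistent with the rest of the protocol (standard IoU in
[0, 1]; squared distance by symmetry with the width term).

## Optimisation

SGD with momentum 0.937 and weight decay 4.8e-4 applied to conv/linear
weights only; lr 0.01 decayed by cosine to a final factor 0.1; linear
warmup of lr and momentum (from 0.8) over the first three epochs of
iterations. The published recipe's "momentum decayed to 1e-4" is not a
meaningful SGD setting and is read as the stock warmup schedule.
Validation loss is computed in evaluation mode each epoch and the
best-validation weights are restored at the end. Checkpoints are `.npz`
archives of named arrays plus the model configuration; the pretrained-
weight hook loads every shape-compatible entry by name and reports the
rest as skipped (cross-variant transfer loads the backbone and skips the
new neck blocks).

## Autograd engine

No deep-learning framework is part of the package's dependency set; the
network runs on a purpose-built reverse-mode autograd over numpy float32
arrays (`pearnet.nn`). Convolution is im2col + BLAS matmul with an
explicit col2im backward; max-pooling recomputes its argmax mask in the
backward pass (ties receive gradient from every attaining position);
batch-norm differentiates through the batch statistics exactly. Gather
operations accumulate duplicate indices (`np.add.at`), which the target
assignment relies on. Gradients of every kernel are verified against
central finite differences in the test suite.

## Synthetic scenes

The generator emulates the structure of an in-field pear dataset, not its
photographic appearance: shaded yellow-green ellipses (aspect 0.8–1.1,
radial gradient, specular highlight under strong/artificial light) over a
leaf-and-branch textured background, occluded by foliage blobs and branch
strips up to a per-pear coverage bound. Ground truth is amodal (the full
fruit extent) clipped to the image; pears whose clipped radius falls
below 5 px are omitted, so every emitted box is evaluable under the size
stratification. The default radius mixture (25% small, 58% medium, 17%
large) and the illumination/viewpoint frequencies used by fixture sets
follow the stratum proportions reported for the field dataset. The four
illumination regimes are brightness/gamma/colour-temperature transforms
ordered weak < normal < strong in mean brightness, with a warm vignetted
cast for artificial light; the bird's-eye viewpoint densifies the canopy
texture and shrinks the fruit-size distribution by 20%. Scenes are
deterministic functions of their spec, including its seed.

What passing tests on these scenes shows is that the implementation —
rendering, assignment, loss, optimisation, decoding, metrics — is
self-consistent and can fit controllable data; it does not show
field-level accuracy. Real orchard images differ in texture statistics,
lighting physics, label noise and fruit appearance, and no claim is made
that synthetic AP transfers.

Augmentations (left-right and up-down flips, HSV jitter with gains
±0.015/±0.7/±0.7, Gaussian blur σ ∈ [0.5, 1.5], 4-image half-scale
mosaic) remap boxes consistently; flips preserve box areas exactly and
are involutions, properties the tests assert.

## Numerical conventions and edge cases

* float32 throughout the network; box geometry in float64 scalars.
* Head bias initialisation: objectness −4, class −1 (rare-object prior).
* Batch-norm eps 1e-3, running-stat momentum 0.03.
* NMS is class-agnostic (single class), greedy by descending confidence,
  suppressing IoU > threshold against kept boxes; exact threshold
  equality survives.
* AP uses all-point interpolation (area under the precision envelope);
  11-point interpolation is available behind a flag. AP is undefined
  (raises) with zero ground truths; empty strata are reported as absent.
* Size-class boundaries land in the lower class (radius exactly 10 px →
  small, exactly 25 px → medium); radius is half the larger box side,
  treating pears as near-circular. Radius exactly 5 px is kept.
* Degenerate zero-area box pairs have IoU 0; a pair degenerate at a
  single point has EIoU 0.
* Splits are floor-based for val/test with the remainder to train
  (3680 → 2944/368/368 at 80/10/10).
* Near-duplicate filtering is a greedy sequential ORB-descriptor scan
  (500 keypoints, mutual-match ratio threshold 0.6 by default); the
  selection that reduced the original 7541 captures to 3680 images is
  re-parameterised, not emulated.

## Desk-scale problem sizes

The package's own test and demonstration runs use scaled-down sizes
chosen to keep a full run in CPU-minutes: structural tests at 64–128 px
input and width multiple 0.25; the convergence check trains the FP
variant (width 0.25, 128 px) on 16 easy scenes — three large unoccluded
pears each — for 400 iterations at batch 4, reaching training-set AP50
≈ 0.7 from random initialisation; profiling runs at the full 640.
The full published recipe (640 px, batch 8, 200 epochs) is expressed by
the defaults of `TrainConfig` and remains available unchanged.

## Known limitations

* Images are plain-resized to the square input (no letterboxing), which
  distorts aspect ratio for non-square sources; the synthetic data is
  square so tests are unaffected.
* Batch-norm statistics with very small batches are noisy; validation
  loss early in training can be large until the running stats settle.
* CPU-only: a full-scale 640-px, 200-epoch training run is impractical
  here — the training surface is exercised at reduced sizes.
* Mosaic augmentation is implemented and tested but not enabled inside
  the default training loop's random selection (flips/HSV/blur are),
  since it resamples the dataset composition mid-epoch.
* The exact skip-connection wiring and the transformer-encoder internals
  are declared design choices where the source description is silent, as
  noted above.
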