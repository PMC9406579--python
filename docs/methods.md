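# Methods

## The model

`rdaunet` implements a U-shaped encoder/decoder network for binary
segmentation of single-channel CT slices, combining three standard
convolutional motifs:

**Residual blocks.** Each block computes `H(x) = F(x) + shortcut(x)`, where
`F` is two 3x3 convolution -> batch-norm -> ReLU stages and the shortcut is
the identity when the channel counts match, otherwise a 1x1 convolution.
Training therefore optimizes the residual `F(x) = H(x) - x` toward zero,
which mitigates vanishing gradients in deep stacks. With the residual
branch zeroed the block is exactly the identity map; the tests assert this
numerically.

**Dense blocks.** Layer *i* consumes the concatenation of the block input
and every earlier layer's output and emits `growth_rate` new channels
(feature reuse); the block output is the final concatenation, with
`in + layers x growth_rate` channels. Dense connectivity gives every layer
a short path to the loss.

**Attention gates.** Each decoder stage gates its encoder skip feature `x`
with coefficients computed from the coarser decoder feature `g` (half of
x's spatial size): `x` is brought to g's grid by a learned stride-2 1x1
convolution, both are projected into an intermediate space (`W_g`, `W_x`),
summed, passed through ReLU, reduced to one channel (`psi`) and squashed by
a sigmoid into `alpha in (0,1)`, which is upsampled (nearest-neighbour)
back to x's grid and multiplied into `x`. Saturating `psi`'s bias to +-20
reproduces the pass-through and suppression limits to < 1e-6, which the
tests assert.

**Topology.** Encoder stage at level `l` (width `base_filters * 2^l`):
residual block then dense block, followed by 2x2 max pooling; a
residual+dense bottleneck sits below the deepest level. Decoder stage:
kernel-2/stride-2 transposed convolution (the classic up-convolution),
attention-gated skip, concatenation, then two 3x3 conv+BN+ReLU. A 1x1
convolution plus sigmoid yields the probability map at input resolution.
The serial residual-then-dense composition within a stage is this package's
reading of the hybrid encoder; `block_mode` exposes `res_only` /
`dense_only` ablations. Published figures leave every channel width
unstated, so widths, dense depth and growth rate are explicit
`ArchitectureConfig` fields; the defaults (depth 4, base 16, dense layers
4, growth = width/2) land the default network in the ~10M-parameter range
of the original design. The exact published parameter total depends on
unreadable figure annotations and is deliberately not a target.

## The numerical engine

No deep-learning framework is part of the dependency set; `rdaunet.nn` is a
small reverse-mode automatic-differentiation engine on numpy arrays, built
for exactly the primitives this network needs. Convolutions lower to
im2col patch matrices and BLAS matmuls; the input gradient of a stride-1
convolution is computed as the full correlation with the flipped kernel
(again an im2col matmul) rather than a scatter-add. The transposed
convolution is restricted to kernel 2 / stride 2, where output blocks do
not overlap and both directions reduce to a single tensordot. Max-pool
ties resolve to the first maximum. All arithmetic is float32 (scalars do
not promote); gradients of every primitive and of the assembled network are
validated against central finite differences in the test-suite. The engine
is single-threaded and bit-deterministic for a fixed seed.

## Preprocessing

* **HU windowing**: clamp to `[hu_min, hu_max]` then rescale linearly to
  [0,1]. The window the original work used is unpublished; the default
  [-100, 400] HU is a standard liver soft-tissue window and is fully
  configurable. Histogram equalization is available but off by default.
* **Resizing**: images bilinear, masks nearest-neighbour (binarity is
  preserved exactly); the fidelity pipeline resizes 512 -> 224.
* **Splitting**: seeded uniform permutation, cut at `round(ratio * n)`;
  the protocol ratio is 8:2 at the image level.
* **DICOM conversion**: slices ordered by `ImagePositionPatient` z,
  rescale slope/intercept applied to produce HU, spacing and origin carried
  into the NIfTI header.
* **Augmentation**: horizontal/vertical flips and quarter-turn rotations,
  applied identically to image and masks.
* Coordinates are 0-based row-major (row, column) throughout.

## Evaluation protocol

From per-pixel confusion counts: `ACC = (TP+TN)/total`,
`DSC = 2TP/(2TP+FP+FN)`, `IoU = TP/(TP+FP+FN)`; the identity
`IoU = DSC/(2-DSC)` holds whenever the union is non-empty, and `ACC >= IoU`
always (accuracy credits the background). The average Hausdorff distance
is `(mean_{g in G} d(g,S) + mean_{s in S} d(s,G))/2` over *boundary* point
sets (mask minus its 4-connected erosion) — the metric is a boundary-error
measure — in pixels by default, physically scaled when a spacing is given;
full-mask point sets are available for comparison. AUC uses the
Mann-Whitney rank formulation with half-credit ties. Aggregation over a
case set is the unweighted per-image mean; when both masks are empty
DSC/IoU are defined as 1.0 with a warning, and a case with an empty mask
contributes no AVGDIST (the excluded count is reported). Every metric has
a brute-force oracle twin in the tests (set arithmetic, all-pairs distance
loops, exhaustive pair comparison).

## Synthetic phantoms

Patient CT cannot be redistributed, so the generator fabricates the minimal
structure the task needs: an air background (-1000..-800 HU), a soft-tissue
body oval (0..60 HU), one connected liver region (40..70 HU) — an ellipse
with semi-axes 0.18-0.28 of the image side, perturbed by a low-frequency
radial harmonic series (k = 2..4, relative amplitude <= 0.12) so the
boundary is not an analytic ellipse — and 0-5 disjoint circular lesions
(80..140 HU) placed strictly inside the liver via its Euclidean distance
transform. One intensity per class per sample is drawn uniformly from its
interval, then Gaussian noise (default sd 5 HU) is added. Generation is a
pure function of (config, seed); datasets are written as NIfTI with a JSON
manifest, gzipped with a zeroed timestamp so re-runs are byte-identical.

What the phantoms do *not* emulate: CT physics (beam hardening, ring and
motion artifacts, anisotropic noise), anatomical variability of organ
shape, multi-organ confusion, contrast phases, and truly ambiguous
liver/soft-tissue boundaries. Passing the desk-scale tests therefore
demonstrates that the architecture, optimization and evaluation machinery
are correct and can learn a nested, intensity-contrasted segmentation task
— not that the network reaches clinical-grade accuracy on real CT.

## Training protocol

The fidelity defaults mirror the published protocol: 100 epochs, batch 8,
Adam (0.9/0.999, eps 1e-8) at learning rate 1e-6, image-level 8:2
train/validation split, separate single-target models for liver and
lesion. The training objective is unpublished; the package defaults to
pixelwise binary cross-entropy, with soft-Dice and BCE+Dice available.
Model selection keeps the lowest-validation-loss epoch. Everything (split,
weight init, batch order) derives from one seed; checkpoints round-trip
bit-exactly.

At 1e-6 a tiny model cannot learn visibly in minutes, so a desk-scale
profile ships alongside the fidelity defaults
(`TrainConfig.desk_scale()` / `run_desk_scale_experiment()`): 80 phantoms
at 64x64 (8:2 split -> 64 training, 16 held-out), depth 3 / base 8
network (~400k parameters), 15 epochs, batch 8, Adam at 1e-3. The lesion
foreground occupies only ~1% of pixels at this scale, and plain BCE
collapses to the empty prediction; the desk-scale lesion run therefore
uses the compound BCE+Dice objective (the liver run keeps BCE). These
problem sizes are the package's demonstration conditions; the fidelity
configuration is unchanged by them.

## Numerical choices and degenerate inputs

* Binarization threshold 0.5; threshold 1.0 yields an empty mask (the
  sigmoid is strictly below 1).
* BCE clips probabilities to [1e-7, 1-1e-7]; soft Dice uses smooth = 1.
* Batch norm: momentum 0.1, eps 1e-5, running statistics for inference.
* Weight init: He-normal, biases zero, seeded per network.
* `input_size` must be divisible by `2^depth` so pooling and up-convolution
  round-trip exactly; violations are configuration errors, as are empty
  id lists, non-binary masks and inverted intervals (the error names the
  offending field).
* Evaluating samples whose ids appear in the recorded training split
  raises a leakage error unless explicitly overridden.

## Known limitations

2-D slices only (no 3-D convolutions or volumetric distance metrics); no
pretrained weights; the numpy engine is CPU-bound and suited to desk-scale
problems, not the full 19,514-image corpus of the original study; the
published headline accuracies require that restricted corpus and GPU-scale
training and are out of scope here.
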