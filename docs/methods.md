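# Methods

## Problem and model

`hipposeg` segments hippocampal subfields — CA1-3, CA4/DG and the
subiculum (SUB) — from co-registered multi-modal 3D MRI (T1w + T2w) with
a dual-branch encoder–decoder network, here called DSNet.

The network is U-shaped:

- **Encoder.** Five ConvBlocks (3×3×3 convolution → batch normalization
  → ReLU) separated by 2×2×2 max-pooling, so stage *l* runs at 1/2^(l−1)
  resolution with C_l = C·2^(l−1) channels (C = 16 by default). Inputs
  must be divisible by 2^(n_stages−1) = 16 along each axis.
- **Transformer bottleneck.** The deepest feature map is flattened to
  one token per voxel, linearly projected to a C′-dimensional token
  space (C′ = 512, following the convention of transformer-bottleneck
  segmentation nets) and summed with a learnable positional table. A
  pre-norm transformer block then computes

      y = MSA(LN(F_token)) + F_token
      F_global = FFN(LN(y)) + y

  where MSA is N = 8-head self-attention, head i using the contiguous
  column block i·d_k…(i+1)·d_k of each C′×C′ projection, with scaled
  dot-product softmax (1/√d_k), and the FFN is a two-layer perceptron
  with GELU and hidden width 4·C′ (the hidden width is not pinned down
  by the recipe we follow; 4× is the transformer default). Tokens are
  projected back to C_l channels and folded to the feature grid. The
  transformer can be attached at stage 5 (default), stage 4, or both;
  at stage 4 it transforms the feature map on the main path, so both
  the skip connection and the deeper stages see the contextualized
  features.
- **CBAM skip attention.** Every skip connection passes through a
  Convolutional Block Attention Module: first a channel gate
  σ(MLP(maxpool) + MLP(avgpool)) with a shared two-layer MLP
  (reduction 16, hidden width at least 1), then a spatial gate
  σ(Conv₇([chan-max, chan-avg])) with a 7×7×7 convolution. Both gates
  lie in (0,1), so CBAM can only attenuate; with all weights zeroed the
  module scales its input by exactly 0.25, which the tests exploit.
- **Dual-branch decoder.** Up-sampling uses transposed convolutions
  (kernel 2, stride 2), each followed by a ConvBlock consuming the
  up-sampled features concatenated with the gated skip. After two
  up-samplings the decoder splits: one branch segments the whole
  hippocampus (2-class head), the other its subfields (4-class head).
  At each post-split stage the hippocampus branch's concatenated
  feature map is added elementwise into the subfield branch's before
  the subfield ConvBlock — the whole-organ context guides the subfield
  decisions. Heads are 1×1×1 convolutions; softmax is applied at loss
  and inference time only.

## Loss

Both branches use the negated soft Dice coefficient, computed per class
and per sample (voxelwise products summed spatially), smoothed by
ε = 1e−5 in numerator and denominator so absent classes contribute a
finite term, averaged and negated; the total is
L = λ₁·L_binary + λ₂·L_subfield with λ₁ = λ₂ = 0.5. A single-branch
model sets λ₁ = 0.

## Training recipe

Adam with L2 weight decay 1e−5; poly schedule
lr(t) = 0.001·(1 − t/T)^0.9 per iteration, reaching 0 at the final
step. (A "decay factor of 0.9 per iteration" read multiplicatively
would underflow to ~1e−50 within a thousand steps, so the poly exponent
reading is the only one compatible with thousands of epochs.) Batch
size 4; random 128³ patches (32³ in the tiny configuration); per-axis
mirroring with probability 0.5; one additive intensity shift per
channel drawn from [−0.1, 0.1] — applied after per-channel z-scoring so
the range is on a unit-variance scale; one isotropic zoom factor from
[0.9, 1.1] (trilinear for images, nearest-neighbour for labels,
recentred to the patch size). All augmentation draws happen
unconditionally so the random stream is independent of which
augmentations fire; a single config seed drives phantom generation,
weight initialization, sampling and augmentation through spawned
substreams, making runs bit-reproducible on one machine. The last 4
per-epoch checkpoints are retained.

## Inference and post-processing

Volumes are zero-padded symmetrically to window multiples, tiled by
non-overlapping 128³ windows, and each window's per-class softmax is
averaged arithmetically over the retained checkpoints ("averaging the
outputs", hence probabilities rather than logits). Hard labels are the
argmax over averaged subfield probabilities, ties resolving to the
lowest class index. Connected components of the predicted foreground
union (26-neighbourhood) smaller than 1000 voxels — 64 mm³ at 0.4 mm
isotropic spacing — are relabelled as background; components at the
threshold survive (strictly-smaller semantics).

## Evaluation

Dice = 2|A∩B|/(|A|+|B|) on voxel sets; two empty masks score 1, one
empty scores 0 (fixed conventions for degenerate cases). HD95 pools the
directed nearest-neighbour distances between the two boundary voxel
sets in both directions, in physical millimetres, sorts them ascending
and takes the lower nearest-rank 95th percentile. Boundary voxels are
foreground voxels with at least one face-adjacent (6-connected)
background neighbour, out-of-grid counting as background. Reports cover
the three subfields plus the whole hippocampus computed on the union of
subfield predictions (the binary branch's own mask is available
separately from the prediction object).

## Preprocessing

The union foreground extent over all training label maps, expanded by a
32-voxel margin and clipped to the grid, defines one bounding box; all
images are cropped to it and brought to a fixed grid (267×182×174 for
the source dataset; both are configurable since phantoms use smaller
grids) by symmetric zero-padding or trimming with the extra voxel on
the high side — never interpolation. Intensities are then histogram-
matched per channel to the first training subject (any fixed in-cohort
reference serves the purpose; a constant source channel maps to the
reference median). Finally the training set is doubled by mirroring
along the left–right axis; subfield identities are not swapped, as the
classes are not lateralized.

## Synthetic phantoms

The phantom generator emulates just the features downstream code needs:
two co-registered channels with distinct per-label contrast orderings
(T1w-like and T2w-like), a compact ellipsoidal organ partitioned into
three contiguous bands along its long axis (preserving the
nested/contiguous subfield topology while staying analytically
checkable), a smooth multiplicative bias field
1 + a·sin(πu)sin(πv)sin(πw) over normalized coordinates, additive
Gaussian noise, and small bright distractor blobs grown voxel-by-voxel
to an exact target size, placed at least 8 voxels clear of the organ so
component filtering is unambiguous. Cohorts jitter organ pose (±2
voxels) and semi-axes (±10%) per subject from spawned seed sequences.
Phantoms deliberately omit MRI physics (partial volume, Rician noise,
anatomy-shaped subfields), so passing tests demonstrate that the
pipeline and optimization work end-to-end, not that real-data accuracy
figures transfer.

## Numerical implementation

The network, its gradients, and Adam are implemented directly on numpy
via a small reverse-mode autodiff engine (`hipposeg.nn`): broadcast-
aware arithmetic, batched matmul, axis reductions, and dedicated 3D
convolution / transposed-convolution / max-pooling ops with
hand-written adjoints (im2col matmuls for small problems, a
memory-light kernel-offset loop for large ones; both paths are tested
to agree bitwise-closely, and every op is verified against central-
difference gradients in float64). Max reductions split gradients
equally among ties; batch norm uses batch statistics in training and
frozen running estimates (momentum 0.1) in eval; softmax subtracts a
detached rowwise max for stability. Training tensors are float32;
formula-oracle tests run the same modules in float64 at 1e−6
tolerances.

## Desk-scale experiment sizes

The bundled end-to-end experiment (`hipposeg.experiments.tiny_overfit`)
trains the `dsnet-tiny` preset (base 4 channels, 32-dim tokens, 2
heads) on two 32³ phantom subjects for 300 epochs at batch 2 and scores
the training subjects with checkpoint-averaged inference plus component
filtering. With seed 1 this reaches hippocampus Dice ≈ 0.86 and mean
subfield Dice ≈ 0.85, demonstrating learnability of the phantom task;
these numbers are what the acceptance script recomputes and are not
comparable to real-data accuracy.

## Known limitations

- Full-scale training (16-channel base, 128³ patches, 8000 epochs) is
  supported by the code paths but impractical on CPU; the recipe's
  defaults are faithful, the bundled experiments are scaled down.
- The token→feature-map inverse (linear C′→C_l projection + reshape) is
  a design choice; the recipe we follow does not specify it.
- "Horizontal flip" doubling assumes non-lateralized labels; datasets
  with left/right-specific classes would need a label swap map.
- HD95 conventions (boundary extraction, pooled percentile,
  nearest-rank) follow common practice but other toolkits differ by
  fractions of a voxel.
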