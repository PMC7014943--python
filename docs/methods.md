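# Methods

## Model

The network is a 3D fully-convolutional encoder–decoder for dense voxel
classification of co-registered multi-modality brain MRI. Modalities enter
as input channels, so the same architecture serves 4-channel tumor data and
6-channel stroke perfusion/diffusion data; only the input and output widths
change.

**Encoder.** Four convolutional blocks of 3×3×3 convolutions, each followed
by batch normalization and ReLU (conv→BN→ReLU ordering; convolution biases
are disabled wherever a BN follows). Block 1 applies two plain convolutions
at full resolution (input→32→32 channels). Blocks 2–4 each open with a
stride-(1,2,2) convolution that halves the in-plane extent, followed by two
residual units (two 3×3×3 convolutions with an identity shortcut; the
residual sum precedes the final ReLU). Widths are {32, 64, 128, 256}. This
gives 2 + 3×(1 + 2×2) = 17 backbone convolutions and in-plane down-sample
factors {1, ½, ¼, ⅛}.

**Slice-axis handling.** By default down-sampling acts only in-plane; the
slice (z) dimension is preserved through every layer, retaining
through-plane detail for thin lesion structures and allowing windows as
shallow as a few slices. A `depth_downsample` flag switches to
stride-(2,2,2), which requires the depth to be a multiple of 8.

**Refinement decoder.** An adaptive 1×1×1 convolution per block projects
its features to a constant refine width (default 128). Three refine units
then propagate context from the deepest block to the shallowest
(4→3→2→1): each passes both branches through a 1×1×1 convolution,
up-samples the coarse branch ×2 in the down-sampled dimensions, sums
element-wise, and refines with a 3×3×3 convolution. The last refined map
therefore has the refine width at exactly the input grid, and a biased
1×1×1 convolution plus per-voxel softmax produces the class probabilities.
Up-sampling is trilinear with half-pixel alignment (nearest-neighbour
selectable); its backward pass is the exact adjoint of the interpolation
matrix.

**Parameter budget.** With the default widths the model holds 11,977,477
trainable parameters (BN affine parameters included), i.e. ≈12.0M. The
count is verified in tests against an independent closed-form summation
over the layer list.

## Numerical core

PyTorch-class frameworks are not a dependency: the layer stack is written
on numpy. Convolutions run as im2col (via `sliding_window_view`) plus BLAS
matmul in float32; the backward pass scatter-adds over kernel offsets.
Inference-mode convolutions chunk the column matrix along z above ~256 MB,
so full-plane 240×240 sub-volumes fit in a few GB. Gradient correctness is
established by finite-difference checks at layer and whole-model level
(discrepancies at ReLU kinks are an artifact of central differences, not of
the adjoints). Weight initialization is He fan-in, seeded through the model
config; evaluation-mode inference is deterministic.

## Loss

Training minimizes the softmax focal loss: with p_t the probability
assigned to a voxel's true class, FL(p_t) = −(1−p_t)^γ log(p_t), averaged
uniformly over voxels (no per-class α-balancing). The loss is the standard
multi-class generalization of the binary focal loss; γ defaults to 2, the
canonical value in the focal-loss literature, since no value is otherwise
pinned; γ=0 recovers cross-entropy bit-for-bit. p_t is clamped to
[1e−7, 1]. The trainer uses a fused softmax+focal gradient; a separate
probability-space gradient supports verification by finite differences.

## Training curriculum

Three stages of increasing data complexity, each continuing the previous
weights:

1. original data, cross-entropy;
2. augmentation applied to 50% of scans per epoch, cross-entropy;
3. augmentation on 75% of scans, focal loss.

Augmentation (drawn per scan per epoch): slice-level intensity
amplification by Uniform(0.8, 1.2) per slice and modality; one in-plane
rotation from {0°, 90°, 180°, 270°} shared by all slices; one in-plane
rescale factor from [0.5, 1.2] (linear for images, nearest for labels,
restored to the original extent by center-crop/zero-pad); horizontal then
vertical flips at probability 0.5 each; and an ROI-constrained random crop
whose window must contain the lesion's in-plane bounding box (degrading to
a lesion-centered crop, with a warning, when the box exceeds the window).

The optimizer is Adam at a constant 1e-4 (the full-scale setting: batch 40,
500 epochs per stage). Moment estimates reset at stage boundaries —
each stage is treated as a fresh task — with a `carry_optimizer` flag for
the alternative. Patches are pooled over scans and reshuffled every epoch;
all randomness flows from the config seed, so runs are bit-reproducible.

## Windowing and inference

Scans are windowed along the slice axis: `floor(D/d)` non-overlapping
depth-`d` windows from offset 0, plus one end-anchored remainder window
when `d` does not divide `D` — the unique simple rule that produces 13
windows for a 155-slice scan at depth 12, 3 for 20/7, and 5 for 155/31.
Training windows get an ROI-constrained in-plane crop; inference
sub-volumes keep the full plane. Stitched predictions average class
probabilities on slices covered twice, renormalize, and take the per-voxel
argmax, ties breaking toward the lower class index. No post-processing.

## Synthetic phantoms

The phantom generator emulates the input structure of lesion-segmentation
benchmarks: co-registered multi-channel volumes with nested lesion
compartments. Tumor mode rasterizes concentric axis-aligned ellipsoids
labelled oedema ⊃ non-enhancing ⊃ enhancing ⊃ necrotic inside a brain
ellipsoid; binary (stroke) mode uses a union of 2–3 overlapping ellipsoids
for an irregular outcome mask. Voxel intensity is a per-(class, modality)
table mean plus additive Gaussian noise (default σ = 0.1 against
inter-class gaps ≥ 1, so classes are separable but not trivially noiseless);
geometry is jittered per phantom from a counter-split seeded stream.

Phantoms deliberately omit MRI physics: no bias fields, partial-volume
mixing, anatomical background texture, inter-scan intensity shifts, or
ragged lesion topology. Passing tests on phantoms therefore demonstrates
that the architecture, losses, augmentation, windowing and training loop
are implemented correctly and can fit separable structure — not that the
model reaches benchmark accuracy on clinical data, which requires the real
datasets and GPU-scale budgets.

## Desk-scale profile

Tests and examples run a named reduced profile: widths (8, 16, 32, 64),
refine width 16, depth-8 windows with 32×32 crops, batch 4, 20 epochs per
stage on four phantoms of shape (16, 40, 40). Its learning rate is 1e-3
rather than 1e-4: an epoch here is only ~2 optimizer steps, so the
full-scale rate would need thousands of epochs even on separable phantoms.
At this scale the three-stage run takes ~2 minutes on one CPU and reaches
whole-lesion training Dice > 0.95.

## Conventions and degenerate cases

* Arrays are (modality, z, y, x) / (z, y, x), 0-based; NIfTI files are
  transposed at the I/O boundary. Voxel spacing is carried as metadata only.
* Intensity normalization (unpinned upstream) is per-modality z-scoring
  over nonzero voxels, keeping skull-stripped background at exactly 0; a
  zero-variance foreground maps to 0 rather than dividing by zero.
* Dice of two empty masks is 1.0, of one empty mask 0.0;
  sensitivity/specificity/precision with empty denominators return `nan`
  and are excluded from means — aggregates stay well-defined on lesion-free
  regions.
* Evaluation merges tumor labels into whole {1,2,3,4}, core {1,3,4} and
  enhancing {4} regions; per-case scores average unweighted across cases.

## Known limitations

* The numpy core is single-threaded apart from BLAS; full-scale (batch-40,
  1500-epoch) training is out of reach and out of scope.
* Batch normalization uses per-batch statistics with running averages;
  very small desk-scale batches make eval-mode outputs sensitive to the
  quality of those running estimates early in training.
* The encoder/decoder layer accounting (which convolutions count toward
  the backbone's 17, and that BN affine parameters are included in the
  12M) is pinned as the arrangement consistent with both printed totals;
  alternatives exist but none reproduces both counts.
* No CRF or other post-processing, no surface-distance metrics, no
  test-time augmentation.
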