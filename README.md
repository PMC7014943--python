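# voxseg

Voxel-wise 3D brain lesion segmentation from multi-modality MRI with a
compact residual refinement network, focal-loss curriculum training, and
BRATS/ISLES-style evaluation — runnable end to end on CPU using built-in
synthetic phantoms.

## The problem

Segmenting brain lesions — glioma tissue compartments (necrotic core,
oedema, non-enhancing and enhancing core) or ischemic stroke outcome
regions — from 3D MRI is a dense classification task: every voxel of a
multi-modality scan (T1/T1c/T2/FLAIR for tumors; ADC and perfusion maps for
stroke) gets a class label. Two difficulties dominate: multiple pooling
stages in deep CNNs destroy the fine spatial detail that lesion boundaries
require, and dense 3D training drowns in "easy" background voxels.

## The model

`voxseg` implements a single-pass 3D fully-convolutional network:

* **Encoder** — four blocks of 3×3×3 convolutions (each conv → batch norm →
  ReLU), widths {32, 64, 128, 256}. Block 1 is two plain convolutions;
  blocks 2–4 each open with a strided convolution (convolutional
  down-sampling, no pooling) followed by two residual units of two
  convolutions, giving 17 backbone convolutions and in-plane down-sample
  factors {1, ½, ¼, ⅛}. By default the slice axis is never down-sampled,
  preserving through-plane detail.
* **3D refinement decoder** — an adaptive 1×1×1 convolution per block maps
  features to a constant 128 channels; three refine units fuse context
  top-down (block 4→3→2→1): 1×1×1 convs on both branches, ×2 up-sampling of
  the coarse branch, element-wise sum, then a 3×3×3 conv. The final refined
  map has 128 channels at the full input resolution.
* **Head** — a 1×1×1 convolution and per-voxel softmax over classes.

The default model holds ≈12.0M trainable parameters. Training minimizes the
focal loss FL(p_t) = −(1−p_t)^γ · log(p_t) (cross-entropy at γ=0) over a
three-stage curriculum of increasing data complexity: plain data +
cross-entropy, then 50% augmented data, then 75% augmented data + focal
loss, with Adam throughout. Scans are windowed into fixed-depth slabs along
the slice axis — `floor(D/d)` non-overlapping windows plus one end-anchored
remainder window (a 155-slice scan yields 13 depth-12 training windows and
5 depth-31 inference sub-volumes) — and window predictions are stitched
back by averaging on overlapped slices before the argmax.

The tensor stack (3D convolution, batch normalization, trilinear
up-sampling, Adam, backpropagation) is implemented in-package on numpy with
im2col + BLAS matmul, so everything runs on one CPU.

## Worked example

Train the reduced desk-scale profile on four synthetic tumor phantoms and
evaluate on the training set:

```python
import voxseg as vs

# four synthetic tumor phantoms (desk-scale study conditions)
phantom_cfg = vs.PhantomConfig(shape=(16, 40, 40), n_modalities=4, seed=7)
dataset = [(vs.normalize(v), l) for v, l in vs.make_dataset(4, phantom_cfg, 7)]

# reduced-width network + three-stage curriculum (20 epochs per stage)
model_cfg, train_cfg = vs.desk_scale_profile(epochs_per_stage=20, seed=7)
model = vs.SegmentationModel(model_cfg)
model, history = vs.run_curriculum(model, dataset, train_cfg)
for name, h in history.items():
    print(f"{name}: loss {h[0]:.3f} -> {h[-1]:.3f}")

# sliding-window inference and evaluation on the training phantoms
scores = []
for volume, labels in dataset:
    chunks, plan = vs.split_inference(volume, train_cfg.window_depth)
    probs = [model.forward(c[None])[0] for c in chunks]
    predicted = vs.predict_labels(vs.stitch(probs, plan))
    scores.append(vs.evaluate_case(predicted, labels.labels, scheme="brats"))
for region, vals in vs.aggregate_scores(scores).items():
    print(f"{region:>10}: dice {vals['dice']:.3f}  sens {vals['sensitivity']:.3f}")
```

Output (~2 minutes on one CPU):

```
stage1-plain: loss 2.499 -> 1.255
stage2-augment: loss 1.262 -> 0.941
stage3-focal: loss 0.393 -> 0.209
     whole: dice 0.971  sens 0.996
      core: dice 0.939  sens 0.980
 enhancing: dice 0.763  sens 0.757
```

The per-stage losses fall within each stage (the jump between stages
reflects the changing task: augmented data, then the focal objective, which
is on a smaller scale than cross-entropy because easy voxels are
down-weighted). The merged-region Dice scores show the overfit network
recovers the whole lesion and tumor core almost perfectly at this scale;
the thin enhancing shell is hardest, as in real tumor data.

A CLI wraps the same functionality: `voxseg phantom` writes synthetic NIfTI
datasets, `voxseg describe` prints the layer table, `voxseg train` runs the
curriculum, `voxseg predict` runs split→forward→stitch→argmax on a scan,
and `voxseg evaluate` emits per-case and mean score tables.

## Layout

| module | contents |
| --- | --- |
| `voxseg.volume_io` | NIfTI read/write, modality stacking, z-score normalization |
| `voxseg.phantoms` | synthetic nested-ellipsoid lesion phantoms |
| `voxseg.network` | model assembly, refine units, layer table, checkpoints |
| `voxseg.nn` | numpy conv/BN/ReLU/upsample layers, backprop, Adam |
| `voxseg.losses` | focal loss, cross-entropy, fused softmax gradient |
| `voxseg.metrics` | Dice/sensitivity/specificity/precision, region merging |
| `voxseg.augment` | slice-level intensity jitter, volume-level geometry |
| `voxseg.patching` | slab windowing, sub-volume stitching, argmax labels |
| `voxseg.trainer` | three-stage curriculum, Adam training loop |

See `docs/methods.md` for modelling assumptions, parameter choices and
limitations.
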