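"""The 3D residual refinement segmentation network.

The model is a compact fully-convolutional encoder-decoder for dense
voxel-wise classification of multi-modality brain MRI:

* **Encoder** — four convolutional blocks of 3x3x3 convolutions, each followed
  by batch normalization and ReLU. Block 1 is two plain convolutions; blocks
  2-4 each open with a strided convolution that halves the in-plane extent
  (convolutional down-sampling, no pooling) followed by two residual units.
  Channel widths grow {32, 64, 128, 256}; in-plane down-sample factors are
  {1, 1/2, 1/4, 1/8}. By default the slice (z) axis is never down-sampled, so
  through-plane detail is preserved; a flag enables halving z as well.
  This yields 17 backbone 3x3x3 convolutions: 2 + 3 x (1 + 2 x 2).
* **Refinement decoder** — an adaptive 1x1x1 convolution per block maps its
  features to a constant width (128 by default); three refine units then fuse
  context top-down (block 4 -> 3 -> 2 -> 1), each passing both branches
  through 1x1x1 convolutions, x2 up-sampling the coarse branch, summing
  element-wise, and refining with a 3x3x3 convolution. The last refined layer
  has the full input resolution.
* **Head** — a 1x1x1 convolution to the class count and a per-voxel softmax.

With the default widths the model holds ~12.0M trainable parameters.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

from .nn import BatchNorm3d, Conv3d, ConvBNReLU, Layer, Parameter, ResBlock, Sequential, Upsample, softmax
from .volume_io import MultiModalVolume

__all__ = [
    "ModelConfig",
    "LayerRecord",
    "NetworkDescription",
    "RefineUnit",
    "SegmentationModel",
    "build_model",
    "feature_shapes",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass
class ModelConfig:
    """Architectural description of the segmentation network."""

    n_modalities: int = 4
    n_classes: int = 5
    block_channels: tuple[int, int, int, int] = (32, 64, 128, 256)
    refine_channels: int = 128
    resblocks_per_block: tuple[int, int, int, int] = (0, 2, 2, 2)
    depth_downsample: bool = False
    upsample_mode: str = "trilinear"
    seed: int = 0

    def __post_init__(self) -> None:
        self.block_channels = tuple(int(c) for c in self.block_channels)
        self.resblocks_per_block = tuple(int(r) for r in self.resblocks_per_block)
        if len(self.block_channels) != 4:
            raise ValueError("block_channels must list 4 widths")
        if any(c <= 0 for c in self.block_channels) or self.refine_channels <= 0:
            raise ValueError("channel counts must be positive")
        if self.n_classes < 2:
            raise ValueError("need at least 2 classes (background + lesion)")
        if self.n_modalities < 1:
            raise ValueError("need at least 1 modality")

    @property
    def down_stride(self) -> tuple[int, int, int]:
        return (2, 2, 2) if self.depth_downsample else (1, 2, 2)

    @property
    def divisibility(self) -> tuple[int, int, int]:
        # three x2 down-samplings across blocks 2-4
        return (8, 8, 8) if self.depth_downsample else (1, 8, 8)


@dataclass
class LayerRecord:
    role: str
    kernel: tuple[int, int, int]
    stride: tuple[int, int, int]
    in_channels: int
    out_channels: int
    n_params: int


@dataclass
class NetworkDescription:
    layers: list[LayerRecord]
    total_parameters: int = 0
    backbone_conv_count: int = 0

    def __post_init__(self) -> None:
        self.total_parameters = sum(r.n_params for r in self.layers)
        self.backbone_conv_count = sum(
            1 for r in self.layers if r.role == "encoder-conv" and r.kernel == (3, 3, 3)
        )

    def to_table(self) -> str:
        header = f"{'role':<16}{'kernel':<12}{'stride':<10}{'in':>5}{'out':>5}{'params':>12}"
        lines = [header, "-" * len(header)]
        for r in self.layers:
            lines.append(
                f"{r.role:<16}{'x'.join(map(str, r.kernel)):<12}"
                f"{'x'.join(map(str, r.stride)):<10}{r.in_channels:>5}{r.out_channels:>5}"
                f"{r.n_params:>12}"
            )
        lines.append("-" * len(header))
        lines.append(
            f"backbone 3x3x3 convolutions: {self.backbone_conv_count}    "
            f"total parameters: {self.total_parameters:,}"
        )
        return "\n".join(lines)


class RefineUnit(Layer):
    """Fuse a fine feature map with an x2-coarser one.

    Each branch passes a 1x1x1 convolution; the coarse branch is up-sampled
    by 2 in the down-sampled dimensions; the branches are summed element-wise
    and refined by a 3x3x3 convolution. Output shape equals the fine input.
    """

    def __init__(
        self,
        channels: int,
        upsample_factors: tuple[int, int, int],
        upsample_mode: str = "trilinear",
        rng: np.random.Generator | None = None,
    ) -> None:
        self.channels = channels
        self.fine_conv = ConvBNReLU(channels, channels, 1, rng=rng, role="refine-1x1")
        self.coarse_conv = ConvBNReLU(channels, channels, 1, rng=rng, role="refine-1x1")
        self.upsample = Upsample(upsample_factors, upsample_mode)
        self.out_conv = ConvBNReLU(channels, channels, 3, rng=rng, role="refine-3x3")

    def parameters(self) -> list[Parameter]:
        return (
            self.fine_conv.parameters()
            + self.coarse_conv.parameters()
            + self.out_conv.parameters()
        )

    def forward(  # type: ignore[override]
        self, fine: np.ndarray, coarse: np.ndarray, training: bool = False
    ) -> np.ndarray:
        if fine.shape[1] != self.channels or coarse.shape[1] != self.channels:
            raise ValueError(
                f"refine unit expects {self.channels} channels, got "
                f"{fine.shape[1]} (fine) and {coarse.shape[1]} (coarse)"
            )
        up = self.upsample.forward(
            self.coarse_conv.forward(coarse, training=training), training=training
        )
        if up.shape != fine.shape[:1] + (self.channels,) + fine.shape[2:]:
            raise ValueError(f"coarse branch up-samples to {up.shape}, fine is {fine.shape}")
        fused = self.fine_conv.forward(fine, training=training) + up
        return self.out_conv.forward(fused, training=training)

    def backward(self, grad_out: np.ndarray) -> tuple[np.ndarray, np.ndarray]:  # type: ignore[override]
        dfused = self.out_conv.backward(grad_out)
        dfine = self.fine_conv.backward(dfused)
        dcoarse = self.coarse_conv.backward(self.upsample.backward(dfused))
        return dfine, dcoarse


class SegmentationModel:
    """Realized network: encoder blocks, refinement decoder, softmax head."""

    def __init__(self, config: ModelConfig) -> None:
        self.config = config
        rng = np.random.default_rng(config.seed)
        c1, c2, c3, c4 = config.block_channels
        r = config.refine_channels
        stride = config.down_stride

        self.blocks: list[Sequential] = []
        # Block 1: two plain 3x3x3 convs at full resolution
        self.blocks.append(
            Sequential(
                ConvBNReLU(config.n_modalities, c1, 3, rng=rng, role="encoder"),
                ConvBNReLU(c1, c1, 3, rng=rng, role="encoder"),
            )
        )
        prev = c1
        for width, n_res in zip((c2, c3, c4), config.resblocks_per_block[1:]):
            layers: list[Layer] = [ConvBNReLU(prev, width, 3, stride, rng=rng, role="encoder")]
            layers += [ResBlock(width, rng=rng) for _ in range(n_res)]
            self.blocks.append(Sequential(*layers))
            prev = width

        self.adaptive = [
            ConvBNReLU(c, r, 1, rng=rng, role="adaptive") for c in (c1, c2, c3, c4)
        ]
        up = tuple(2 if s == 2 else 1 for s in stride)
        self.refine_units = [
            RefineUnit(r, up, config.upsample_mode, rng=rng) for _ in range(3)
        ]
        self.head = Conv3d(r, config.n_classes, 1, bias=True, rng=rng, role="head")

    # ------------------------------------------------------------------ plumbing

    def parameters(self) -> list[Parameter]:
        params: list[Parameter] = []
        for block in self.blocks:
            params += block.parameters()
        for a in self.adaptive:
            params += a.parameters()
        for u in self.refine_units:
            params += u.parameters()
        params += self.head.parameters()
        return params

    def _batchnorms(self) -> list[BatchNorm3d]:
        bns: list[BatchNorm3d] = []

        def walk(obj) -> None:
            if isinstance(obj, BatchNorm3d):
                bns.append(obj)
            elif isinstance(obj, Sequential):
                for sub in obj.layers:
                    walk(sub)
            elif isinstance(obj, ResBlock):
                walk(obj.branch1)
                walk(obj.bn2)
            elif isinstance(obj, RefineUnit):
                walk(obj.fine_conv)
                walk(obj.coarse_conv)
                walk(obj.out_conv)

        for block in self.blocks:
            walk(block)
        for a in self.adaptive:
            walk(a)
        for u in self.refine_units:
            walk(u)
        return bns

    def _check_divisible(self, spatial: tuple[int, int, int]) -> None:
        div = self.config.divisibility
        bad = [f"axis {'zyx'[i]}={s} (needs multiple of {d})"
               for i, (s, d) in enumerate(zip(spatial, div)) if d > 1 and s % d]
        if bad:
            raise ValueError("input grid not divisible by the down-sampling factor: " + "; ".join(bad))

    # ------------------------------------------------------------------- forward

    def forward(
        self,
        x: np.ndarray | MultiModalVolume,
        training: bool = False,
        logits: bool = False,
        return_features: bool = False,
    ):
        """Dense per-voxel class probabilities at the input resolution.

        ``x`` is a ``(batch, modality, z, y, x)`` array (a bare
        ``MultiModalVolume`` is promoted to a batch of one). With ``logits``
        the softmax is skipped; ``return_features`` additionally returns the
        per-block encoder features and the last refined map.
        """
        if isinstance(x, MultiModalVolume):
            x = x.data[None]
        x = np.asarray(x, dtype=np.float32)
        if x.ndim != 5:
            raise ValueError(f"expected (batch, modality, z, y, x) input, got {x.ndim}D")
        if x.shape[1] != self.config.n_modalities:
            raise ValueError(
                f"model expects {self.config.n_modalities} modalities, got {x.shape[1]}"
            )
        self._check_divisible(x.shape[2:])

        feats = []
        h = x
        for block in self.blocks:
            h = block.forward(h, training=training)
            feats.append(h)
        adapted = [a.forward(f, training=training) for a, f in zip(self.adaptive, feats)]
        refined = adapted[3]
        for unit, fine in zip(self.refine_units, (adapted[2], adapted[1], adapted[0])):
            refined = unit.forward(fine, refined, training=training)
        out = self.head.forward(refined, training=training)
        if not logits:
            out = softmax(out, axis=1)
        if return_features:
            features = {f"block{i + 1}": f for i, f in enumerate(feats)}
            features["refined"] = refined
            return out, features
        return out

    def backward(self, grad_logits: np.ndarray) -> np.ndarray:
        """Backpropagate a gradient w.r.t. the head's logits; returns dx."""
        dref = self.head.backward(grad_logits)
        dadapted = [None, None, None, None]
        for unit, idx in zip(reversed(self.refine_units), (0, 1, 2)):
            dfine, dref = unit.backward(dref)
            dadapted[idx] = dfine
        dadapted[3] = dref
        dfeats = [a.backward(d) for a, d in zip(self.adaptive, dadapted)]
        grad = None
        for i in (3, 2, 1, 0):
            grad = dfeats[i] if grad is None else grad + dfeats[i]
            grad = self.blocks[i].backward(grad)
        return grad

    def __call__(self, x, **kw):
        return self.forward(x, **kw)

    # ------------------------------------------------------------------ describe

    def describe(self) -> NetworkDescription:
        records: list[LayerRecord] = []

        def add_conv(conv: Conv3d, role: str) -> None:
            n = conv.weight.size + (conv.bias.size if conv.bias is not None else 0)
            records.append(
                LayerRecord(role, conv.kernel_size, conv.stride, conv.in_channels,
                            conv.out_channels, n)
            )

        def add_bn(bn: BatchNorm3d) -> None:
            records.append(
                LayerRecord("batchnorm", (1, 1, 1), (1, 1, 1), bn.channels, bn.channels,
                            bn.gamma.size + bn.beta.size)
            )

        def walk(obj, conv_role: str) -> None:
            if isinstance(obj, Conv3d):
                add_conv(obj, conv_role)
            elif isinstance(obj, BatchNorm3d):
                add_bn(obj)
            elif isinstance(obj, Sequential):
                for sub in obj.layers:
                    walk(sub, conv_role)
            elif isinstance(obj, ResBlock):
                walk(obj.branch1, conv_role)
                add_conv(obj.conv2, conv_role)
                add_bn(obj.bn2)

        for block in self.blocks:
            walk(block, "encoder-conv")
        for a in self.adaptive:
            walk(a, "adaptive-conv")
        for u in self.refine_units:
            walk(u.fine_conv, "refine-conv")
            walk(u.coarse_conv, "refine-conv")
            walk(u.out_conv, "refine-conv")
        add_conv(self.head, "head-conv")
        return NetworkDescription(records)


def build_model(config: ModelConfig) -> tuple[SegmentationModel, NetworkDescription]:
    """Construct the network and its layer-by-layer description."""
    model = SegmentationModel(config)
    return model, model.describe()


def feature_shapes(
    config: ModelConfig, input_shape: tuple[int, int, int]
) -> list[tuple[int, int, int]]:
    """Spatial shape of each block's feature maps for a ``(z, y, x)`` input.

    In-plane extents scale by {1, 1/2, 1/4, 1/8}; depth follows only when
    ``depth_downsample`` is set.
    """
    z, y, x = input_shape
    shapes = []
    for i in range(4):
        f = 2**i
        shapes.append((z // f if config.depth_downsample else z, y // f, x // f))
    return shapes


# ------------------------------------------------------------------ checkpoints


def save_checkpoint(model: SegmentationModel, path: str) -> None:
    """Store config + weights + batch-norm running statistics (.npz)."""
    arrays = {f"param{i}": p.data for i, p in enumerate(model.parameters())}
    for i, bn in enumerate(model._batchnorms()):
        arrays[f"bn{i}_mean"] = bn.running_mean
        arrays[f"bn{i}_var"] = bn.running_var
    cfg = asdict(model.config)
    cfg["class_set_note"] = "background is class 0"
    np.savez(path, config_json=np.bytes_(json.dumps(cfg).encode()), **arrays)


def load_checkpoint(path: str) -> SegmentationModel:
    with np.load(path) as data:
        cfg = json.loads(bytes(data["config_json"]).decode())
        cfg.pop("class_set_note", None)
        cfg["block_channels"] = tuple(cfg["block_channels"])
        cfg["resblocks_per_block"] = tuple(cfg["resblocks_per_block"])
        model = SegmentationModel(ModelConfig(**cfg))
        for i, p in enumerate(model.parameters()):
            arr = data[f"param{i}"]
            if arr.shape != p.data.shape:
                raise ValueError(f"checkpoint mismatch at parameter {i}")
            p.data[...] = arr
        for i, bn in enumerate(model._batchnorms()):
            bn.running_mean[...] = data[f"bn{i}_mean"]
            bn.running_var[...] = data[f"bn{i}_var"]
    return model
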