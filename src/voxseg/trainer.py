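"""Three-stage curriculum training.

Data complexity increases across three stages, each a continuation of the
previous model state:

1. original data, no augmentation, cross-entropy — the "easy task";
2. augmentation applied to 50% of the scans, still cross-entropy;
3. augmentation on 75% of the scans and the focal loss, concentrating the
   gradient on hard voxels.

Each stage runs a fixed epoch budget (500 in the full-scale regime) with
Adam at a constant learning rate of 1e-4. Optimizer moment estimates reset
at stage boundaries by default (each stage is a fresh task); a flag carries
them over instead. A desk-scale profile shrinks widths, patch sizes and
epochs so the full pipeline exercises in minutes on one CPU.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field

import numpy as np

from .augment import AugmentConfig, maybe_augment
from .losses import softmax_focal_with_logits
from .network import ModelConfig, SegmentationModel, save_checkpoint
from .nn import Adam
from .patching import extract_training_patches
from .volume_io import LabelVolume, MultiModalVolume

__all__ = [
    "CurriculumStage",
    "TrainConfig",
    "default_curriculum",
    "desk_scale_profile",
    "train_stage",
    "run_curriculum",
]

logger = logging.getLogger(__name__)

Dataset = list[tuple[MultiModalVolume, LabelVolume]]


@dataclass
class CurriculumStage:
    name: str
    epochs: int
    augment_fraction: float
    loss: str = "cross_entropy"  # or "focal"
    gamma: float = 2.0

    def __post_init__(self) -> None:
        if self.epochs <= 0:
            raise ValueError("epochs must be positive")
        if not 0.0 <= self.augment_fraction <= 1.0:
            raise ValueError("augment_fraction must be in [0, 1]")
        if self.loss not in ("cross_entropy", "focal"):
            raise ValueError(f"unknown loss {self.loss!r}")

    @property
    def effective_gamma(self) -> float:
        return self.gamma if self.loss == "focal" else 0.0


@dataclass
class TrainConfig:
    stages: list[CurriculumStage] = field(default_factory=lambda: default_curriculum())
    learning_rate: float = 1e-4
    batch_size: int = 40
    window_depth: int = 12
    crop_size: tuple[int, int] = (128, 128)
    augment: AugmentConfig = field(default_factory=AugmentConfig)
    seed: int = 0
    checkpoint_dir: str | None = None
    carry_optimizer: bool = False

    def __post_init__(self) -> None:
        if not self.stages:
            raise ValueError("at least one curriculum stage is required")
        if self.learning_rate < 0 or self.batch_size < 1:
            raise ValueError("learning rate must be >= 0 and batch size >= 1")


def default_curriculum(gamma: float = 2.0, epochs: int = 500) -> list[CurriculumStage]:
    """The three-stage schedule: (no-aug, CE) -> (50% aug, CE) -> (75% aug, focal)."""
    if gamma < 0:
        raise ValueError("gamma must be >= 0")
    return [
        CurriculumStage("stage1-plain", epochs, 0.0, "cross_entropy", gamma),
        CurriculumStage("stage2-augment", epochs, 0.5, "cross_entropy", gamma),
        CurriculumStage("stage3-focal", epochs, 0.75, "focal", gamma),
    ]


def desk_scale_profile(
    n_modalities: int = 4,
    n_classes: int = 5,
    epochs_per_stage: int = 20,
    seed: int = 0,
) -> tuple[ModelConfig, TrainConfig]:
    """Reduced widths/patches/epochs for CPU-scale experiments and tests.

    The learning rate is raised to 1e-3: at this scale an epoch is only a
    couple of optimizer steps, so the full-scale rate of 1e-4 would need
    thousands of epochs to converge on even easy data.
    """
    model_cfg = ModelConfig(
        n_modalities=n_modalities,
        n_classes=n_classes,
        block_channels=(8, 16, 32, 64),
        refine_channels=16,
        seed=seed,
    )
    train_cfg = TrainConfig(
        stages=default_curriculum(epochs=epochs_per_stage),
        learning_rate=1e-3,
        batch_size=4,
        window_depth=8,
        crop_size=(32, 32),
        seed=seed,
    )
    return model_cfg, train_cfg


def _epoch_batches(
    dataset: Dataset,
    stage: CurriculumStage,
    config: TrainConfig,
    rng: np.random.Generator,
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Augment scans, window them into patches, pool and shuffle, batch."""
    aug = AugmentConfig(
        intensity_range=config.augment.intensity_range,
        rotation_choices=config.augment.rotation_choices,
        rescale_range=config.augment.rescale_range,
        flip_prob=config.augment.flip_prob,
        crop_size=None,  # cropping happens at patch extraction
        apply_prob=stage.augment_fraction,
    )
    patches: list[tuple[np.ndarray, np.ndarray]] = []
    for volume, labels in dataset:
        volume, labels = maybe_augment((volume, labels), rng, aug)
        patches += extract_training_patches(
            volume, labels, config.window_depth, config.crop_size, rng
        )
    order = rng.permutation(len(patches))
    batches = []
    for start in range(0, len(order), config.batch_size):
        idx = order[start : start + config.batch_size]
        x = np.stack([patches[i][0] for i in idx]).astype(np.float32)
        y = np.stack([patches[i][1] for i in idx]).astype(np.intp)
        batches.append((x, y))
    return batches


def train_stage(
    model: SegmentationModel,
    dataset: Dataset,
    stage: CurriculumStage,
    config: TrainConfig,
    optimizer: Adam | None = None,
    rng: np.random.Generator | None = None,
) -> list[float]:
    """Run one curriculum stage in place; returns per-epoch mean losses."""
    if not dataset:
        raise ValueError("empty training dataset")
    if optimizer is None:
        optimizer = Adam(model.parameters(), lr=config.learning_rate)
    if rng is None:
        rng = np.random.default_rng(config.seed)
    gamma = stage.effective_gamma
    history: list[float] = []
    for epoch in range(stage.epochs):
        losses = []
        for x, y in _epoch_batches(dataset, stage, config, rng):
            optimizer.zero_grad()
            logits = model.forward(x, training=True, logits=True)
            loss, dlogits = softmax_focal_with_logits(logits, y, gamma=gamma)
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite loss in {stage.name} epoch {epoch}: "
                    f"batch mean {x.mean():.3g}, std {x.std():.3g}, "
                    f"logit range [{logits.min():.3g}, {logits.max():.3g}]"
                )
            model.backward(dlogits)
            optimizer.step()
            losses.append(loss)
        mean_loss = float(np.mean(losses))
        history.append(mean_loss)
        logger.info("%s epoch %d/%d mean loss %.5f", stage.name, epoch + 1, stage.epochs, mean_loss)
    return history


def run_curriculum(
    model: SegmentationModel,
    dataset: Dataset,
    config: TrainConfig,
) -> tuple[SegmentationModel, dict[str, list[float]]]:
    """Execute the staged curriculum; each stage continues the last weights.

    A checkpoint is written after every stage when ``checkpoint_dir`` is set.
    Passing a single-stage config realizes the no-curriculum ablation.
    """
    histories: dict[str, list[float]] = {}
    optimizer: Adam | None = None
    for i, stage in enumerate(config.stages):
        if optimizer is None or not config.carry_optimizer:
            optimizer = Adam(model.parameters(), lr=config.learning_rate)
        rng = np.random.default_rng([config.seed, i])
        histories[stage.name] = train_stage(model, dataset, stage, config, optimizer, rng)
        if config.checkpoint_dir:
            os.makedirs(config.checkpoint_dir, exist_ok=True)
            save_checkpoint(model, os.path.join(config.checkpoint_dir, f"{stage.name}.npz"))
    return model, histories
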