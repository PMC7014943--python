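"""Slice-level intensity and volume-level geometric augmentation.

Geometric operations are drawn once per volume and applied identically to
every slice — and to the paired label volume with nearest-neighbour
interpolation — in a fixed order:

  (i) in-plane rotation by one of {0, 90, 180, 270} degrees;
  (ii) in-plane rescale by one factor from [0.5, 1.2], restored to the
       original extent by center-cropping (upscale) or zero-padding
       (downscale);
  (iii) horizontal then vertical flip, each with its own coin;
  (iv) ROI-constrained random crop: the window must contain the lesion's
       in-plane bounding box whenever a lesion is present.

Intensity jitter multiplies each slice (independently per modality) by a
factor drawn uniformly from [0.8, 1.2] and never touches labels. All
randomness flows through an injected numpy Generator so fixed seeds
reproduce augmented batches bit-exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .volume_io import LabelVolume, MultiModalVolume

__all__ = [
    "AugmentConfig",
    "intensity_jitter",
    "geometric_augment",
    "maybe_augment",
    "roi_crop_window",
]

logger = logging.getLogger(__name__)


@dataclass
class AugmentConfig:
    intensity_range: tuple[float, float] = (0.8, 1.2)
    rotation_choices: tuple[int, ...] = (0, 90, 180, 270)
    rescale_range: tuple[float, float] = (0.5, 1.2)
    flip_prob: float = 0.5
    crop_size: tuple[int, int] | None = None
    apply_prob: float = 0.5

    def __post_init__(self) -> None:
        if not 0.0 <= self.apply_prob <= 1.0:
            raise ValueError("apply_prob must be in [0, 1]")
        if min(self.intensity_range) <= 0 or min(self.rescale_range) <= 0:
            raise ValueError("intensity and rescale ranges must be positive")
        if any(r % 90 for r in self.rotation_choices):
            raise ValueError("rotations must be multiples of 90 degrees")


def intensity_jitter(
    volume: MultiModalVolume,
    rng: np.random.Generator,
    intensity_range: tuple[float, float] = (0.8, 1.2),
) -> MultiModalVolume:
    """Amplify each slice of each modality by an independent uniform factor."""
    m, z = volume.data.shape[:2]
    factors = rng.uniform(*intensity_range, size=(m, z)).astype(np.float32)
    data = volume.data * factors[:, :, None, None]
    return MultiModalVolume(data, list(volume.modality_names), volume.spacing)


def _restore_extent(arr: np.ndarray, target_yx: tuple[int, int], pad_value=0) -> np.ndarray:
    """Center-crop or zero-pad the trailing (y, x) axes to ``target_yx``."""
    for axis_offset, target in enumerate(target_yx):
        axis = arr.ndim - 2 + axis_offset
        cur = arr.shape[axis]
        if cur > target:
            lo = (cur - target) // 2
            sl = [slice(None)] * arr.ndim
            sl[axis] = slice(lo, lo + target)
            arr = arr[tuple(sl)]
        elif cur < target:
            pad = [(0, 0)] * arr.ndim
            lo = (target - cur) // 2
            pad[axis] = (lo, target - cur - lo)
            arr = np.pad(arr, pad, constant_values=pad_value)
    return arr


def roi_crop_window(
    labels: np.ndarray,
    crop_size: tuple[int, int],
    rng: np.random.Generator,
) -> tuple[int, int]:
    """Top-left (y, x) of a random crop window containing the lesion bbox.

    With no lesion voxels the window is unconstrained. A lesion bounding box
    larger than the window degrades to a bbox-centered crop with a warning.
    """
    zdim, ydim, xdim = labels.shape
    cy, cx = crop_size
    if cy > ydim or cx > xdim:
        raise ValueError(f"crop {crop_size} exceeds in-plane extent ({ydim}, {xdim})")
    lesion = labels > 0
    starts = []
    if not lesion.any():
        for extent, c in ((ydim, cy), (xdim, cx)):
            starts.append(int(rng.integers(0, extent - c + 1)))
        return tuple(starts)
    proj = lesion.any(axis=0)
    ys, xs = np.where(proj)
    for (lo, hi), extent, c in (((ys.min(), ys.max()), ydim, cy), ((xs.min(), xs.max()), xdim, cx)):
        lo, hi = int(lo), int(hi)
        if hi - lo + 1 > c:
            logger.warning(
                "lesion bounding box (%d) exceeds crop size (%d); centering on lesion", hi - lo + 1, c
            )
            start = min(max((lo + hi + 1 - c) // 2, 0), extent - c)
        else:
            low = max(0, hi + 1 - c)
            high = min(lo, extent - c)
            start = int(rng.integers(low, high + 1))
        starts.append(start)
    return tuple(starts)


def geometric_augment(
    volume: MultiModalVolume,
    labels: LabelVolume,
    rng: np.random.Generator,
    config: AugmentConfig,
) -> tuple[MultiModalVolume, LabelVolume]:
    """Apply one shared rotation/rescale/flip/crop to images and labels."""
    img = volume.data
    lab = labels.labels
    if img.shape[1:] != lab.shape:
        raise ValueError(f"image grid {img.shape[1:]} != label grid {lab.shape}")

    # (i) rotation — same orientation for every slice; axes (y, x)
    quarter_turns = int(rng.choice(len(config.rotation_choices)))
    k = config.rotation_choices[quarter_turns] // 90
    if k:
        img = np.rot90(img, k=k, axes=(2, 3))
        lab = np.rot90(lab, k=k, axes=(1, 2))

    # (ii) in-plane rescale by one shared ratio, restored to original extent
    ratio = float(rng.uniform(*config.rescale_range))
    if not np.isclose(ratio, 1.0):
        yx = img.shape[2:]
        img = ndimage.zoom(img, (1, 1, ratio, ratio), order=1)
        lab = ndimage.zoom(lab, (1, ratio, ratio), order=0)
        img = _restore_extent(img, yx)
        lab = _restore_extent(lab, yx)

    # (iii) horizontal then vertical flips
    if rng.uniform() < config.flip_prob:
        img = np.flip(img, axis=3)
        lab = np.flip(lab, axis=2)
    if rng.uniform() < config.flip_prob:
        img = np.flip(img, axis=2)
        lab = np.flip(lab, axis=1)

    # (iv) ROI-constrained random crop
    if config.crop_size is not None:
        y0, x0 = roi_crop_window(lab, config.crop_size, rng)
        cy, cx = config.crop_size
        img = img[:, :, y0 : y0 + cy, x0 : x0 + cx]
        lab = lab[:, y0 : y0 + cy, x0 : x0 + cx]

    out_vol = MultiModalVolume(
        np.ascontiguousarray(img, dtype=np.float32), list(volume.modality_names), volume.spacing
    )
    out_lab = LabelVolume(np.ascontiguousarray(lab), labels.class_set)
    return out_vol, out_lab


def maybe_augment(
    sample: tuple[MultiModalVolume, LabelVolume],
    rng: np.random.Generator,
    config: AugmentConfig,
) -> tuple[MultiModalVolume, LabelVolume]:
    """With probability ``apply_prob``: intensity jitter then the geometric
    pipeline; otherwise the sample passes through unchanged."""
    if rng.uniform() >= config.apply_prob:
        return sample
    volume, labels = sample
    volume = intensity_jitter(volume, rng, config.intensity_range)
    return geometric_augment(volume, labels, rng, config)
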