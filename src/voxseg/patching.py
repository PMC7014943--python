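"""Slab windowing of scans into training patches and inference sub-volumes.

Scans are windowed along the slice (z) axis: ``floor(D/d)`` non-overlapping
depth-``d`` windows starting at 0, d, 2d, …, plus — when D is not a multiple
of d — one final window anchored at ``D - d`` so every slice is covered.
A 155-slice scan therefore yields 13 depth-12 training windows and 5
depth-31 inference sub-volumes, and a 20-slice scan yields 3 depth-7
windows. At stitch time, slices covered by two windows (only the remainder
window can overlap) average their predicted probabilities before the
per-voxel argmax.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .augment import roi_crop_window
from .volume_io import LabelVolume, MultiModalVolume

__all__ = [
    "WindowPlan",
    "plan_windows",
    "extract_training_patches",
    "split_inference",
    "stitch",
    "predict_labels",
]


@dataclass(frozen=True)
class WindowPlan:
    window_depth: int
    offsets: tuple[int, ...]
    scan_depth: int

    def __post_init__(self) -> None:
        if any(o < 0 or o > self.scan_depth - self.window_depth for o in self.offsets):
            raise ValueError("window offsets fall outside the scan")
        if any(b <= a for a, b in zip(self.offsets, self.offsets[1:])):
            raise ValueError("offsets must be strictly increasing")
        covered = np.zeros(self.scan_depth, dtype=bool)
        for o in self.offsets:
            covered[o : o + self.window_depth] = True
        if not covered.all():
            raise ValueError("windows do not cover every slice")

    @property
    def n_windows(self) -> int:
        return len(self.offsets)


def plan_windows(scan_depth: int, window_depth: int) -> WindowPlan:
    """Equal non-overlapping windows plus one end-anchored remainder window.

    Window count is ``ceil(scan_depth / window_depth)``.
    """
    if window_depth < 1:
        raise ValueError("window_depth must be >= 1")
    if window_depth > scan_depth:
        raise ValueError(
            f"window depth {window_depth} exceeds scan depth {scan_depth}"
        )
    offsets = list(range(0, scan_depth - window_depth + 1, window_depth))
    if scan_depth % window_depth:
        offsets.append(scan_depth - window_depth)
    return WindowPlan(window_depth, tuple(offsets), scan_depth)


def extract_training_patches(
    volume: MultiModalVolume,
    labels: LabelVolume,
    window_depth: int,
    crop_size: tuple[int, int],
    rng: np.random.Generator,
) -> list[tuple[np.ndarray, np.ndarray]]:
    """One (image, label) patch per planned window.

    The in-plane region of each window is picked by the ROI-constrained
    random crop, so a lesion present in the slab is always fully inside the
    patch. Image patches are ``(M, d, crop_y, crop_x)``.
    """
    if volume.grid_shape != labels.grid_shape:
        raise ValueError(f"image grid {volume.grid_shape} != label grid {labels.grid_shape}")
    plan = plan_windows(volume.grid_shape[0], window_depth)
    cy, cx = crop_size
    patches = []
    for o in plan.offsets:
        img_slab = volume.data[:, o : o + window_depth]
        lab_slab = labels.labels[o : o + window_depth]
        y0, x0 = roi_crop_window(lab_slab, crop_size, rng)
        patches.append(
            (
                np.ascontiguousarray(img_slab[:, :, y0 : y0 + cy, x0 : x0 + cx]),
                np.ascontiguousarray(lab_slab[:, y0 : y0 + cy, x0 : x0 + cx]),
            )
        )
    return patches


def split_inference(
    volume: MultiModalVolume, subvolume_depth: int
) -> tuple[list[np.ndarray], WindowPlan]:
    """Full-in-plane sub-volumes for memory-bounded sliding-window inference."""
    plan = plan_windows(volume.grid_shape[0], subvolume_depth)
    chunks = [
        np.ascontiguousarray(volume.data[:, o : o + subvolume_depth]) for o in plan.offsets
    ]
    return chunks, plan


def stitch(probability_chunks: list[np.ndarray], plan: WindowPlan) -> np.ndarray:
    """Assemble per-window class probabilities into a full-depth volume.

    Non-overlapping slices are copied; slices shared with the remainder
    window are averaged, then renormalized per voxel.
    """
    if len(probability_chunks) != plan.n_windows:
        raise ValueError(f"{len(probability_chunks)} chunks for {plan.n_windows} windows")
    first = probability_chunks[0]
    k = first.shape[0]
    out = np.zeros((k, plan.scan_depth) + first.shape[2:], dtype=np.float64)
    count = np.zeros(plan.scan_depth, dtype=np.int64)
    for chunk, o in zip(probability_chunks, plan.offsets):
        if chunk.shape != (k, plan.window_depth) + first.shape[2:]:
            raise ValueError(f"chunk shape {chunk.shape} inconsistent with plan")
        out[:, o : o + plan.window_depth] += chunk
        count[o : o + plan.window_depth] += 1
    if (count == 0).any():
        raise RuntimeError("window plan left slices uncovered")  # plan invariant violated
    out /= count[None, :, None, None]
    sums = out.sum(axis=0, keepdims=True)
    np.divide(out, sums, out=out, where=sums > 0)
    return out.astype(np.float32)


def predict_labels(probabilities: np.ndarray) -> np.ndarray:
    """Per-voxel argmax over the leading class axis; ties break toward the
    lower class index (background-favouring). No post-processing."""
    return np.argmax(np.asarray(probabilities), axis=0).astype(np.int16)
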