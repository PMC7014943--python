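"""NIfTI volume I/O, multi-modality stacking, and intensity normalization.

Volumes are held in ``(z, y, x)`` order with ``z`` the slice axis, matching the
convention used throughout the package for slab windowing. NIfTI files store
data ``(x, y, z)``; the transpose happens at the I/O boundary and the affine is
carried so written files round-trip.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Sequence

import nibabel as nib
import numpy as np

__all__ = [
    "MultiModalVolume",
    "LabelVolume",
    "read_volume",
    "write_volume",
    "stack_modalities",
    "normalize",
]


@dataclass
class MultiModalVolume:
    """Co-registered stack of M modality volumes on one 3D grid.

    Parameters
    ----------
    data
        Float array of shape ``(M, z, y, x)``.
    modality_names
        Ordered modality identifiers, e.g. ``["T1", "T1c", "T2", "FLAIR"]``.
    spacing
        Voxel size in mm per ``(z, y, x)`` axis; metadata only.
    """

    data: np.ndarray
    modality_names: list[str] = field(default_factory=list)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 4:
            raise ValueError(f"expected 4D (modality, z, y, x) data, got {self.data.ndim}D")
        if self.data.shape[0] < 1:
            raise ValueError("at least one modality is required")
        if not self.modality_names:
            self.modality_names = [f"mod{i}" for i in range(self.data.shape[0])]
        if len(self.modality_names) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.modality_names)} modality names for {self.data.shape[0]} modalities"
            )

    @property
    def n_modalities(self) -> int:
        return self.data.shape[0]

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.data.shape[1:]


@dataclass
class LabelVolume:
    """Integer class labels on a 3D grid (ground truth or prediction)."""

    labels: np.ndarray
    class_set: frozenset[int] = frozenset({0, 1})

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError(f"expected 3D (z, y, x) labels, got {self.labels.ndim}D")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError(f"labels must be integer-typed, got {self.labels.dtype}")
        self.class_set = frozenset(int(c) for c in self.class_set)
        present = set(np.unique(self.labels).tolist())
        if not present <= self.class_set:
            raise ValueError(f"labels {sorted(present - self.class_set)} outside class set")

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.labels.shape


def read_volume(path: str | os.PathLike) -> tuple[np.ndarray, tuple[float, float, float]]:
    """Read one single-volume NIfTI file.

    Returns the array in ``(z, y, x)`` order together with its voxel spacing in
    mm. Raises ``FileNotFoundError`` for a missing file and ``ValueError`` for
    anything that is not a 3D image.
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise FileNotFoundError(f"no such volume: {path}")
    try:
        img = nib.load(path)
    except Exception as exc:  # nibabel raises a zoo of error types
        raise ValueError(f"not a readable NIfTI image: {path}") from exc
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"expected a 3D volume, got {data.ndim}D in {path}")
    zooms = img.header.get_zooms()[:3]
    # nibabel gives (x, y, z); we index (z, y, x)
    spacing = (float(zooms[2]), float(zooms[1]), float(zooms[0]))
    return np.ascontiguousarray(data.T), spacing


def write_volume(
    path: str | os.PathLike,
    array: np.ndarray,
    spacing: Sequence[float] = (1.0, 1.0, 1.0),
) -> None:
    """Write a ``(z, y, x)`` array to a NIfTI file with a diagonal affine."""
    array = np.asarray(array)
    if array.ndim != 3:
        raise ValueError(f"expected a 3D volume, got {array.ndim}D")
    sz, sy, sx = (float(s) for s in spacing)
    affine = np.diag([sx, sy, sz, 1.0])
    img = nib.Nifti1Image(np.ascontiguousarray(array.T), affine)
    img.header.set_zooms((sx, sy, sz))
    nib.save(img, os.fspath(path))


def stack_modalities(
    paths: Sequence[str | os.PathLike],
    modality_names: Sequence[str] | None = None,
) -> MultiModalVolume:
    """Assemble one multi-modality volume from per-modality NIfTI files.

    The modality axis follows the input order. All files must share one grid.
    """
    if len(paths) < 1:
        raise ValueError("at least one modality file is required")
    arrays, spacings = [], []
    for p in paths:
        arr, sp = read_volume(p)
        arrays.append(arr.astype(np.float32))
        spacings.append(sp)
    shapes = [a.shape for a in arrays]
    if len(set(shapes)) != 1:
        raise ValueError(f"modalities do not share one grid: shapes {shapes}")
    names = list(modality_names) if modality_names else [
        os.path.basename(os.fspath(p)).split(".")[0] for p in paths
    ]
    return MultiModalVolume(np.stack(arrays), names, spacings[0])


def normalize(volume: MultiModalVolume) -> MultiModalVolume:
    """Z-score each modality over its nonzero (foreground) voxels.

    Zero-valued background voxels stay exactly zero, so skull-stripped air
    remains a neutral input. A modality with zero foreground variance maps its
    foreground to zero rather than dividing by zero.
    """
    out = np.array(volume.data, dtype=np.float32, copy=True)
    for m in range(out.shape[0]):
        fg = out[m] != 0
        if not fg.any():
            raise ValueError(f"modality {volume.modality_names[m]!r} is identically zero")
        vals = out[m][fg]
        mu = vals.mean()
        sd = vals.std()
        out[m][fg] = 0.0 if sd == 0 else (vals - mu) / sd
    if not np.isfinite(out).all():
        raise ValueError("non-finite values after normalization")
    return MultiModalVolume(out, list(volume.modality_names), volume.spacing)
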