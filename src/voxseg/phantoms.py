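"""Synthetic multi-modality brain phantoms with nested lesion compartments.

The phantoms emulate the structure of co-registered multi-channel MRI with
labelled lesion tissue: an elliptical "brain" containing nested axis-aligned
lesion ellipsoids whose per-modality mean intensities differ by class, plus
additive Gaussian noise. Two modes are supported:

* ``brats`` — five classes (0 background, 1 necrotic core, 2 oedema,
  3 non-enhancing, 4 enhancing core) nested as oedema ⊃ non-enhancing ⊃
  enhancing ⊃ necrotic, mimicking glioma compartment geometry.
* ``binary`` — classes {0, 1}, with the lesion a union of 2–3 overlapping
  ellipsoids to emulate the irregular shape of stroke outcome masks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .volume_io import LabelVolume, MultiModalVolume

__all__ = ["PhantomConfig", "make_phantom", "make_dataset", "rasterize_nested_ellipsoids"]

# outer->inner label order for the nested glioma compartments
_BRATS_NEST_ORDER = (2, 3, 4, 1)


def _default_intensity_table(n_classes: int, n_modalities: int) -> np.ndarray:
    """Per-(class, modality) mean intensities, distinct between classes.

    Class 0 (background / normal tissue) sits at 0; lesion classes are spaced
    by at least one intensity unit with modality-dependent scaling so that each
    class has a distinct multi-modality signature.
    """
    table = np.zeros((n_classes, n_modalities), dtype=np.float32)
    for c in range(1, n_classes):
        for m in range(n_modalities):
            table[c, m] = c * (1.0 + 0.25 * m)
    return table


@dataclass
class PhantomConfig:
    """Geometry, contrast and noise settings for one phantom family.

    ``lesion_radius_fractions`` are radii of the nested compartments as
    fractions of the brain ellipsoid's semi-axes, strictly decreasing from the
    outermost compartment to the innermost.
    """

    shape: tuple[int, int, int] = (16, 64, 64)
    n_modalities: int = 4
    class_set: frozenset[int] = frozenset({0, 1, 2, 3, 4})
    intensity_table: np.ndarray | None = None
    noise_sigma: float = 0.1
    brain_radius_fraction: float = 0.9
    lesion_radius_fractions: tuple[float, ...] = (0.55, 0.42, 0.3, 0.16)
    brain_mean: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.class_set = frozenset(int(c) for c in self.class_set)
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        n_lesion = len(self.class_set) - 1
        if len(self.lesion_radius_fractions) != n_lesion:
            raise ValueError(
                f"{n_lesion} lesion classes need {n_lesion} radius fractions, "
                f"got {len(self.lesion_radius_fractions)}"
            )
        radii = self.lesion_radius_fractions
        if any(b >= a for a, b in zip(radii, radii[1:])):
            raise ValueError(f"lesion radii must strictly decrease outer->inner: {radii}")
        if radii and radii[0] >= self.brain_radius_fraction:
            raise ValueError("outermost lesion must nest inside the brain ellipsoid")
        if self.intensity_table is None:
            self.intensity_table = _default_intensity_table(
                len(self.class_set), self.n_modalities
            )
        self.intensity_table = np.asarray(self.intensity_table, dtype=np.float32)
        if self.intensity_table.shape != (len(self.class_set), self.n_modalities):
            raise ValueError(
                f"intensity table shape {self.intensity_table.shape} != "
                f"({len(self.class_set)}, {self.n_modalities})"
            )

    @property
    def mode(self) -> str:
        return "binary" if self.class_set == {0, 1} else "brats"


def _ellipsoid_mask(
    shape: tuple[int, int, int],
    center: np.ndarray,
    semiaxes: np.ndarray,
) -> np.ndarray:
    zz, yy, xx = np.ogrid[: shape[0], : shape[1], : shape[2]]
    coords = [zz, yy, xx]
    q = sum(((c - mu) / r) ** 2 for c, mu, r in zip(coords, center, semiaxes))
    return q <= 1.0


def rasterize_nested_ellipsoids(
    shape: tuple[int, int, int],
    center: np.ndarray,
    semiaxes_outer_to_inner: list[np.ndarray],
    classes_outer_to_inner: list[int],
) -> np.ndarray:
    """Label grid for concentric axis-aligned ellipsoids; inner wins.

    A voxel (z, y, x) belongs to an ellipsoid when
    sum(((coord - center) / semiaxis)^2) <= 1.
    """
    labels = np.zeros(shape, dtype=np.int16)
    for cls, axes in zip(classes_outer_to_inner, semiaxes_outer_to_inner):
        labels[_ellipsoid_mask(shape, np.asarray(center, float), np.asarray(axes, float))] = cls
    return labels


def _phantom_labels(config: PhantomConfig, rng: np.random.Generator) -> np.ndarray:
    shape = config.shape
    half = np.array(shape, dtype=float) / 2.0
    center = half * (1.0 + rng.uniform(-0.05, 0.05, size=3))
    brain_axes = half * config.brain_radius_fraction
    labels = np.zeros(shape, dtype=np.int16)

    if config.mode == "binary":
        # irregular lesion: union of 2-3 jittered ellipsoids
        n_lobes = int(rng.integers(2, 4))
        base = brain_axes * config.lesion_radius_fractions[0]
        mask = np.zeros(shape, dtype=bool)
        for _ in range(n_lobes):
            c = center + rng.uniform(-0.2, 0.2, size=3) * brain_axes
            axes = base * rng.uniform(0.6, 1.0, size=3)
            mask |= _ellipsoid_mask(shape, c, np.maximum(axes, 1.0))
        labels[mask] = 1
        return labels

    lesion_center = center + rng.uniform(-0.08, 0.08, size=3) * brain_axes
    semiaxes = [
        np.maximum(brain_axes * frac * rng.uniform(0.95, 1.05), 1.0)
        for frac in config.lesion_radius_fractions
    ]
    return rasterize_nested_ellipsoids(
        shape, lesion_center, semiaxes, list(_BRATS_NEST_ORDER)
    )


def make_phantom(
    config: PhantomConfig,
    rng: np.random.Generator | None = None,
) -> tuple[MultiModalVolume, LabelVolume]:
    """Generate one phantom; identical seed gives bit-identical output.

    Every voxel's intensity is ``intensity_table[label, modality]`` plus
    Gaussian noise of scale ``noise_sigma``; class-0 voxels inside the brain
    ellipsoid additionally get ``brain_mean`` so normal tissue can be made
    visible against air.
    """
    if min(config.shape) < 4:
        raise ValueError(f"grid {config.shape} too small to contain the phantom")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    labels = _phantom_labels(config, rng)
    missing = config.class_set - set(np.unique(labels).tolist())
    if missing:
        raise ValueError(f"radii too small to realize classes {sorted(missing)} on {config.shape}")

    classes = sorted(config.class_set)
    class_index = np.searchsorted(classes, labels)
    data = config.intensity_table[class_index].transpose(3, 0, 1, 2).astype(np.float32)
    if config.brain_mean != 0.0:
        half = np.array(config.shape, dtype=float) / 2.0
        brain = _ellipsoid_mask(config.shape, half, half * config.brain_radius_fraction)
        data[:, brain & (labels == 0)] += config.brain_mean
    if config.noise_sigma > 0:
        data += rng.normal(0.0, config.noise_sigma, size=data.shape).astype(np.float32)

    volume = MultiModalVolume(data, [f"mod{i}" for i in range(config.n_modalities)])
    return volume, LabelVolume(labels, config.class_set)


def make_dataset(
    n: int,
    config: PhantomConfig,
    seed: int | None = None,
) -> list[tuple[MultiModalVolume, LabelVolume]]:
    """Generate ``n`` phantoms with jittered geometry from one seeded stream."""
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    seed = config.seed if seed is None else seed
    # one stream per phantom, split by counter, so (n, seed) determine output
    children = np.random.SeedSequence(seed).spawn(n)
    return [make_phantom(config, np.random.default_rng(s)) for s in children]
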