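"""Segmentation evaluation: Dice, sensitivity, specificity, precision, and
the glioma label-merging scheme.

All scores operate on binary masks. Dice normalizes the true-positive count
by the average size of the two regions, 2·|P∩T| / (|P|+|T|), and equals the
F-measure. For multi-class glioma labels, evaluation runs on three merged
regions: *whole* tumor (all lesion classes), *core* tumor (classes 1, 3, 4)
and *enhancing* tumor (class 4 only).

Conventions for degenerate cases: Dice of two empty masks is 1.0 and of one
empty mask 0.0; sensitivity/specificity/precision with an empty denominator
return ``nan`` and are excluded from aggregates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .volume_io import LabelVolume

__all__ = [
    "BratsRegionScheme",
    "dice",
    "sensitivity",
    "specificity",
    "precision",
    "merge_brats_regions",
    "evaluate_case",
    "aggregate_scores",
]

UNDEFINED = float("nan")


@dataclass(frozen=True)
class BratsRegionScheme:
    """Merged tumor regions: enhancing ⊂ core ⊂ whole."""

    whole: frozenset[int] = frozenset({1, 2, 3, 4})
    core: frozenset[int] = frozenset({1, 3, 4})
    enhancing: frozenset[int] = frozenset({4})

    def __post_init__(self) -> None:
        if not (self.enhancing <= self.core <= self.whole):
            raise ValueError("regions must nest: enhancing ⊆ core ⊆ whole")

    @property
    def regions(self) -> dict[str, frozenset[int]]:
        return {"whole": self.whole, "core": self.core, "enhancing": self.enhancing}


def _as_masks(prediction: np.ndarray, truth: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    p = np.asarray(prediction)
    t = np.asarray(truth)
    if p.shape != t.shape:
        raise ValueError(f"prediction shape {p.shape} != truth shape {t.shape}")
    for name, arr in (("prediction", p), ("truth", t)):
        vals = np.unique(arr)
        if not np.isin(vals, (0, 1)).all():
            raise ValueError(f"{name} mask must be binary, found values {vals}")
    return p.astype(bool), t.astype(bool)


def dice(prediction: np.ndarray, truth: np.ndarray) -> float:
    """Overlap score 2·|P∩T| / (|P|+|T|) in [0, 1]."""
    p, t = _as_masks(prediction, truth)
    denom = int(p.sum()) + int(t.sum())
    if denom == 0:
        return 1.0  # both empty: perfect (vacuous) agreement
    return 2.0 * int((p & t).sum()) / denom


def sensitivity(prediction: np.ndarray, truth: np.ndarray) -> float:
    """True-positive rate |P∩T| / |T|; nan when the truth is empty."""
    p, t = _as_masks(prediction, truth)
    nt = int(t.sum())
    if nt == 0:
        return UNDEFINED
    return int((p & t).sum()) / nt


def specificity(prediction: np.ndarray, truth: np.ndarray) -> float:
    """True-negative rate |¬P∩¬T| / |¬T|; nan when the truth has no negatives."""
    p, t = _as_masks(prediction, truth)
    nn = int((~t).sum())
    if nn == 0:
        return UNDEFINED
    return int((~p & ~t).sum()) / nn


def precision(prediction: np.ndarray, truth: np.ndarray) -> float:
    """Positive predictive value |P∩T| / |P|; nan when the prediction is empty."""
    p, t = _as_masks(prediction, truth)
    np_ = int(p.sum())
    if np_ == 0:
        return UNDEFINED
    return int((p & t).sum()) / np_


def merge_brats_regions(
    labels: LabelVolume | np.ndarray,
    scheme: BratsRegionScheme | None = None,
) -> dict[str, np.ndarray]:
    """Binary masks for the whole/core/enhancing merged tumor regions."""
    scheme = scheme or BratsRegionScheme()
    arr = labels.labels if isinstance(labels, LabelVolume) else np.asarray(labels)
    allowed = {0} | set(scheme.whole)
    present = set(np.unique(arr).tolist())
    if not present <= allowed:
        raise ValueError(f"labels {sorted(present - allowed)} outside {sorted(allowed)}")
    return {
        name: np.isin(arr, sorted(classes)).astype(np.uint8)
        for name, classes in scheme.regions.items()
    }


def evaluate_case(
    prediction: LabelVolume | np.ndarray,
    truth: LabelVolume | np.ndarray,
    scheme: str = "brats",
) -> dict[str, dict[str, float]]:
    """All scores for one case, per merged region ('brats') or lesion ('binary')."""
    if scheme == "brats":
        pred_masks = merge_brats_regions(prediction)
        true_masks = merge_brats_regions(truth)
    elif scheme == "binary":
        parr = prediction.labels if isinstance(prediction, LabelVolume) else np.asarray(prediction)
        tarr = truth.labels if isinstance(truth, LabelVolume) else np.asarray(truth)
        pred_masks = {"lesion": (parr > 0).astype(np.uint8)}
        true_masks = {"lesion": (tarr > 0).astype(np.uint8)}
    else:
        raise ValueError(f"unknown scheme {scheme!r}; expected 'brats' or 'binary'")
    out: dict[str, dict[str, float]] = {}
    for region in pred_masks:
        p, t = pred_masks[region], true_masks[region]
        out[region] = {
            "dice": dice(p, t),
            "sensitivity": sensitivity(p, t),
            "specificity": specificity(p, t),
            "precision": precision(p, t),
        }
    return out


def aggregate_scores(cases: list[dict[str, dict[str, float]]]) -> dict[str, dict[str, float]]:
    """Unweighted mean over cases per region and score, skipping nan entries."""
    if not cases:
        return {}
    out: dict[str, dict[str, float]] = {}
    for region in cases[0]:
        out[region] = {}
        for score in cases[0][region]:
            vals = np.array([c[region][score] for c in cases])
            vals = vals[np.isfinite(vals)]
            out[region][score] = float(vals.mean()) if vals.size else UNDEFINED
    return out
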