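"""Focal loss for dense voxel classification, with cross-entropy as γ=0.

The focal loss re-weights per-voxel cross-entropy by ``(1 - p_t)^γ`` where
``p_t`` is the probability the model assigns to the voxel's true class:

    FL(p_t) = -(1 - p_t)^γ · log(p_t)

Well-classified ("easy") voxels, which dominate dense 3D training, are
smoothly down-weighted so the gradient signal concentrates on hard voxels —
typically lesion boundaries. γ = 0 recovers plain cross-entropy; larger γ
focuses harder. The reduction is the unweighted mean over all voxels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import softmax

__all__ = [
    "FocalParams",
    "focal_loss",
    "focal_loss_grad",
    "cross_entropy",
    "softmax_focal_with_logits",
]

_EPS = 1e-7


@dataclass
class FocalParams:
    """gamma: focusing strength (0 = cross-entropy). class_weights: optional
    per-class multipliers, default uniform."""

    gamma: float = 2.0
    class_weights: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.gamma < 0:
            raise ValueError(f"gamma must be >= 0, got {self.gamma}")
        if self.class_weights is not None:
            self.class_weights = np.asarray(self.class_weights, dtype=np.float64)


def _validate(probabilities: np.ndarray, targets: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Flatten (..., K, voxel-dims) probabilities and matching targets."""
    probabilities = np.asarray(probabilities, dtype=np.float64)
    targets = np.asarray(targets)
    if probabilities.ndim == targets.ndim:  # class axis expected at position 1 of a batch
        raise ValueError("probabilities must carry one extra class axis over targets")
    if probabilities.ndim == 2 and targets.ndim == 1:
        p = probabilities
        t = targets
    else:
        # (N, K, z, y, x) vs (N, z, y, x): move class axis last and flatten
        p = np.moveaxis(probabilities, 1, -1).reshape(-1, probabilities.shape[1])
        t = targets.reshape(-1)
    if p.shape[0] != t.shape[0]:
        raise ValueError(f"{p.shape[0]} probability rows for {t.shape[0]} targets")
    sums = p.sum(axis=1)
    if np.abs(sums - 1.0).max() > 1e-4:
        raise ValueError("probability rows must sum to 1 (within 1e-4)")
    if t.min() < 0 or t.max() >= p.shape[1]:
        raise ValueError("targets outside the class range")
    return p, t.astype(np.intp)


def focal_loss(
    probabilities: np.ndarray,
    targets: np.ndarray,
    params: FocalParams | None = None,
) -> float:
    """Mean focal loss over all voxels.

    ``probabilities`` is ``(n_voxels, K)`` or ``(N, K, z, y, x)``; ``targets``
    holds integer true classes of matching shape minus the class axis.
    """
    params = params or FocalParams()
    p, t = _validate(probabilities, targets)
    pt = np.clip(p[np.arange(p.shape[0]), t], _EPS, 1.0)
    terms = -((1.0 - pt) ** params.gamma) * np.log(pt)
    if params.class_weights is not None:
        terms = terms * params.class_weights[t]
    return float(terms.mean())


def focal_loss_grad(
    probabilities: np.ndarray,
    targets: np.ndarray,
    params: FocalParams | None = None,
) -> np.ndarray:
    """Gradient of :func:`focal_loss` w.r.t. the probabilities.

    Only the true-class entry of each voxel carries gradient:
    d/dp_t [-(1-p_t)^γ log p_t] = γ(1-p_t)^{γ-1} log p_t - (1-p_t)^γ / p_t,
    divided by the voxel count for the mean reduction.
    """
    params = params or FocalParams()
    p, t = _validate(probabilities, targets)
    n, k = p.shape
    pt = np.clip(p[np.arange(n), t], _EPS, 1.0)
    g = params.gamma
    d = -((1.0 - pt) ** g) / pt
    if g > 0:
        d = d + g * (1.0 - pt) ** (g - 1.0) * np.log(pt)
    if params.class_weights is not None:
        d = d * params.class_weights[t]
    grad = np.zeros((n, k))
    grad[np.arange(n), t] = d / n
    if np.asarray(probabilities).ndim == 2:
        return grad
    return np.moveaxis(grad.reshape(np.asarray(targets).shape + (k,)), -1, 1)


def cross_entropy(probabilities: np.ndarray, targets: np.ndarray) -> float:
    """Mean cross-entropy; bit-for-bit identical to focal loss at γ = 0."""
    return focal_loss(probabilities, targets, FocalParams(gamma=0.0))


def softmax_focal_with_logits(
    logits: np.ndarray,
    targets: np.ndarray,
    gamma: float = 0.0,
) -> tuple[float, np.ndarray]:
    """Fused softmax + focal loss used in training: returns (loss, dlogits).

    With p = softmax(z) and g = dFL/dp_t, the chain rule gives
    dFL/dz_k = g · p_t · (δ_{tk} - p_k), averaged over voxels.
    """
    if gamma < 0:
        raise ValueError(f"gamma must be >= 0, got {gamma}")
    logits = np.asarray(logits)
    p = softmax(logits, axis=1).astype(np.float64)
    t = np.asarray(targets).astype(np.intp)
    k = p.shape[1]
    pf = np.moveaxis(p, 1, -1).reshape(-1, k)
    tf = t.reshape(-1)
    n = pf.shape[0]
    idx = np.arange(n)
    pt = np.clip(pf[idx, tf], _EPS, 1.0)
    loss = float((-((1.0 - pt) ** gamma) * np.log(pt)).mean())

    dpt = -((1.0 - pt) ** gamma) / pt
    if gamma > 0:
        dpt = dpt + gamma * (1.0 - pt) ** (gamma - 1.0) * np.log(pt)
    onehot_minus_p = -pf
    onehot_minus_p[idx, tf] += 1.0
    dz = (dpt * pt)[:, None] * onehot_minus_p / n
    dlogits = np.moveaxis(dz.reshape(t.shape + (k,)), -1, 1).astype(logits.dtype)
    return loss, dlogits
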