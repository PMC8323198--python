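"""Loss functions for class-imbalanced multi-class segmentation.

All losses operate on a softmax probability map P and a one-hot target G with
matching shape ``(..., K)``, K = 5 classes, pooling the sums over every pixel
of every leading axis (so a batch behaves exactly like one large image).

* cross entropy:            -(1/N) sum_i sum_k g_ik log p_ik
* per-class Dice loss:      1 - 2 sum p_k g_k / (sum p_k + sum g_k)
* per-region Dice loss:     the class Dice applied to the summed member
                            channels of an evaluation region (background,
                            complete, core, enhancing)
* combined Dice loss:       DL_bg + DL_complete + DL_core + DL_enhancing
* sliced Dice loss:         sum of the five per-class Dice losses
* recall loss:              1 - sum p g / sum g over a class or region; it
                            penalizes only missed target pixels, shifting
                            emphasis to the minority tissue
* HL1:                      alpha*CE + beta*RL_com + gamma*RL_core + delta*RL_enh
* HL2:                      alpha*DL_combined + beta*RL_com + gamma*RL_core
                            + delta*RL_enh

A smoothing constant (default 1e-5) is added to both numerator and denominator
of every ratio loss so that an empty target yields loss 0 (a perfect score for
correctly predicting absence) rather than a division failure.  Probabilities
are clipped to [1e-7, 1 - 1e-7] before the cross-entropy log.

Every function optionally returns the analytic gradient with respect to P
(``return_grad=True``), which the training loop chains through the softmax.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Union

import numpy as np

from .regions import RegionSpec, resolve_region
from .types import NUM_CLASSES

#: Smoothing constant for Dice/recall ratios.
EPSILON = 1e-5
#: Probability clip bound for the cross-entropy log.
CLIP = 1e-7


@dataclass(frozen=True)
class LossWeights:
    """Weights (alpha, beta, gamma, delta) of the hybrid losses."""

    alpha: float
    beta: float
    gamma: float
    delta: float

    def __post_init__(self) -> None:
        if min(self.alpha, self.beta, self.gamma, self.delta) < 0:
            raise ValueError("loss weights must be nonnegative")


#: Published best weights for HL1 (cross-entropy + region recalls).
HL1_WEIGHTS = LossWeights(alpha=20.0, beta=0.5, gamma=1.0, delta=0.5)
#: Published best weights for HL2 (combined Dice + region recalls).
HL2_WEIGHTS = LossWeights(alpha=1.0, beta=0.1, gamma=1.3, delta=0.5)


def _check(P: np.ndarray, G: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    P = np.asarray(P, dtype=np.float64)
    G = np.asarray(G, dtype=np.float64)
    if P.shape != G.shape:
        raise ValueError(f"shape mismatch: P {P.shape} vs G {G.shape}")
    if P.shape[-1] != NUM_CLASSES:
        raise ValueError(f"last axis must have {NUM_CLASSES} channels, got {P.shape[-1]}")
    return P, G


def cross_entropy(P: np.ndarray, G: np.ndarray, return_grad: bool = False):
    """Mean per-pixel multi-class cross entropy."""
    P, G = _check(P, G)
    n_pixels = int(np.prod(P.shape[:-1]))
    Pc = np.clip(P, CLIP, 1.0 - CLIP)
    value = float(-(G * np.log(Pc)).sum() / n_pixels)
    if not return_grad:
        return value
    grad = -G / (n_pixels * Pc)
    return value, grad


def _ratio_loss(num: float, den: float, eps: float) -> float:
    return 1.0 - (num + eps) / (den + eps)


def dice_loss_class(
    P: np.ndarray, G: np.ndarray, k: int, eps: float = EPSILON, return_grad: bool = False
):
    """Soft Dice loss of class channel ``k`` (pooled over all pixels)."""
    P, G = _check(P, G)
    if not 0 <= k < NUM_CLASSES:
        raise ValueError(f"class index {k} outside 0..{NUM_CLASSES - 1}")
    p, g = P[..., k], G[..., k]
    inter = float((p * g).sum())
    den = float(p.sum() + g.sum())
    value = _ratio_loss(2.0 * inter, den, eps)
    if not return_grad:
        return value
    # d/dp_i [1 - (2A+e)/(B+e)] with A = sum p g, B = sum p + sum g
    num_s = 2.0 * inter + eps
    den_s = den + eps
    dp = -(2.0 * g * den_s - num_s) / den_s**2
    grad = np.zeros_like(P)
    grad[..., k] = dp
    return value, grad


def dice_loss_region(
    P: np.ndarray,
    G: np.ndarray,
    region: Union[str, RegionSpec],
    eps: float = EPSILON,
    return_grad: bool = False,
):
    """Soft Dice loss of an evaluation region (member channels summed first)."""
    P, G = _check(P, G)
    spec = resolve_region(region)
    members = list(spec.member_labels)
    p = P[..., members].sum(axis=-1)
    g = G[..., members].sum(axis=-1)
    inter = float((p * g).sum())
    den = float(p.sum() + g.sum())
    value = _ratio_loss(2.0 * inter, den, eps)
    if not return_grad:
        return value
    num_s = 2.0 * inter + eps
    den_s = den + eps
    dp = -(2.0 * g * den_s - num_s) / den_s**2
    grad = np.zeros_like(P)
    for k in members:
        grad[..., k] = dp
    return value, grad


def combined_dice_loss(
    P: np.ndarray, G: np.ndarray, eps: float = EPSILON, return_grad: bool = False
):
    """Sum of the region Dice losses: background + complete + core + enhancing."""
    parts = [
        dice_loss_region(P, G, r, eps=eps, return_grad=return_grad)
        for r in ("background", "complete", "core", "enhancing")
    ]
    if not return_grad:
        return float(sum(parts))
    value = float(sum(v for v, _ in parts))
    grad = sum(g for _, g in parts)
    return value, grad


def sliced_dice_loss(
    P: np.ndarray, G: np.ndarray, eps: float = EPSILON, return_grad: bool = False
):
    """Sum of the five per-class Dice losses."""
    parts = [
        dice_loss_class(P, G, k, eps=eps, return_grad=return_grad)
        for k in range(NUM_CLASSES)
    ]
    if not return_grad:
        return float(sum(parts))
    value = float(sum(v for v, _ in parts))
    grad = sum(g for _, g in parts)
    return value, grad


def recall_loss(
    P: np.ndarray,
    G: np.ndarray,
    target: Union[int, str, RegionSpec],
    eps: float = EPSILON,
    return_grad: bool = False,
):
    """Soft recall loss ``1 - sum(p g) / sum(g)`` for a class or a region.

    The ratio uses only the target's ground-truth mass in the denominator, so
    the loss ignores false positives entirely and drives sensitivity up.
    """
    P, G = _check(P, G)
    if isinstance(target, (int, np.integer)):
        if not 0 <= int(target) < NUM_CLASSES:
            raise ValueError(f"class index {target} outside 0..{NUM_CLASSES - 1}")
        members = [int(target)]
    else:
        members = list(resolve_region(target).member_labels)
    p = P[..., members].sum(axis=-1)
    g = G[..., members].sum(axis=-1)
    inter = float((p * g).sum())
    den = float(g.sum())
    value = _ratio_loss(inter, den, eps)
    if not return_grad:
        return value
    dp = -g / (den + eps)
    grad = np.zeros_like(P)
    for k in members:
        grad[..., k] = dp
    return value, grad


def _hybrid(base_value, base_grad, P, G, w: LossWeights, eps: float, return_grad: bool):
    regions = ("complete", "core", "enhancing")
    coeffs = (w.beta, w.gamma, w.delta)
    if not return_grad:
        total = w.alpha * base_value
        for r, c in zip(regions, coeffs):
            total += c * recall_loss(P, G, r, eps=eps)
        return float(total)
    value = w.alpha * base_value
    grad = w.alpha * base_grad
    for r, c in zip(regions, coeffs):
        v, g = recall_loss(P, G, r, eps=eps, return_grad=True)
        value += c * v
        grad = grad + c * g
    return float(value), grad


def hybrid_hl1(
    P: np.ndarray,
    G: np.ndarray,
    weights: Optional[LossWeights] = None,
    eps: float = EPSILON,
    return_grad: bool = False,
):
    """HL1 = alpha*CE + beta*RL_complete + gamma*RL_core + delta*RL_enhancing."""
    w = weights or HL1_WEIGHTS
    if return_grad:
        base_v, base_g = cross_entropy(P, G, return_grad=True)
        return _hybrid(base_v, base_g, P, G, w, eps, True)
    return _hybrid(cross_entropy(P, G), None, P, G, w, eps, False)


def hybrid_hl2(
    P: np.ndarray,
    G: np.ndarray,
    weights: Optional[LossWeights] = None,
    eps: float = EPSILON,
    return_grad: bool = False,
):
    """HL2 = alpha*DL_combined + beta*RL_complete + gamma*RL_core + delta*RL_enhancing."""
    w = weights or HL2_WEIGHTS
    if return_grad:
        base_v, base_g = combined_dice_loss(P, G, eps=eps, return_grad=True)
        return _hybrid(base_v, base_g, P, G, w, eps, True)
    return _hybrid(combined_dice_loss(P, G, eps=eps), None, P, G, w, eps, False)


#: Selectable training losses; each maps (P, G, weights) -> (value, dL/dP).
def _make_entry(fn, needs_weights):
    def entry(P, G, weights=None):
        if needs_weights:
            return fn(P, G, weights=weights, return_grad=True)
        return fn(P, G, return_grad=True)

    return entry


LOSS_REGISTRY = {
    "ce": _make_entry(cross_entropy, False),
    "sliced_dice": _make_entry(sliced_dice_loss, False),
    "combined_dice": _make_entry(combined_dice_loss, False),
    "hl1": _make_entry(hybrid_hl1, True),
    "hl2": _make_entry(hybrid_hl2, True),
}

DEFAULT_WEIGHTS = {"hl1": HL1_WEIGHTS, "hl2": HL2_WEIGHTS}
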