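"""Composite segmentation loss: soft Dice plus a Hausdorff surrogate.

The Dice term drives regional overlap; the Hausdorff term weights the
squared probability error by squared distance transforms of the truth and
of the thresholded prediction, pushing residual errors toward the object
boundary.  The exact symmetric Hausdorff distance is non-differentiable and
is used only for evaluation (see :mod:`desimri.metrics`); this surrogate is
smooth in the predicted probabilities (the distance maps are treated as
constants, the standard approximation).

All functions take per-channel probabilities ``p`` and boolean truth ``t``
of identical shape ``(..., C, H, W)`` and return scalar losses together
with analytic gradients with respect to ``p``.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .nn import sigmoid

_EPS = 1.0  # Dice smoothing; keeps empty-channel cases well defined


def _check(p, t):
    p = np.asarray(p)
    if not np.issubdtype(p.dtype, np.floating):
        p = p.astype(np.float32)
    t = np.asarray(t).astype(p.dtype)
    if p.shape != t.shape:
        raise ValueError(f"shape mismatch: pred {p.shape} vs truth {t.shape}")
    if p.ndim == 3:
        p, t = p[None], t[None]
    elif p.ndim != 4:
        raise ValueError("expected (C, H, W) or (N, C, H, W)")
    return p, t


def soft_dice_loss(pred_probs, truth, return_grad: bool = False):
    """1 - mean over (sample, channel) of (2*sum(p*t)+eps)/(sum p + sum t + eps).

    Zero when the (binary) prediction equals the truth; 1 for disjoint
    nonempty masks, up to the epsilon smoothing.
    """
    p, t = _check(pred_probs, truth)
    inter = (p * t).sum(axis=(2, 3))
    sums = p.sum(axis=(2, 3)) + t.sum(axis=(2, 3))
    num = 2.0 * inter + _EPS
    den = sums + _EPS
    loss = float(1.0 - (num / den).mean())
    if not return_grad:
        return loss
    n_terms = p.shape[0] * p.shape[1]
    # d/dp of -(num/den): (num/den^2 - 2 t/den), averaged over terms
    grad = (num / den ** 2)[:, :, None, None] - 2.0 * t / den[:, :, None, None]
    return loss, (grad / n_terms).astype(p.dtype)


def _dist_to_set(mask: np.ndarray) -> np.ndarray:
    """Distance (pixels) from every pixel to the nearest pixel of the set."""
    if not mask.any():
        return np.zeros(mask.shape, dtype=np.float32)
    return ndimage.distance_transform_edt(~mask).astype(np.float32)


def _boundary_distance(mask: np.ndarray) -> np.ndarray:
    """Unsigned distance to the mask boundary (0 on the boundary)."""
    if not mask.any() or mask.all():
        return np.zeros(mask.shape, dtype=np.float32)
    outside = ndimage.distance_transform_edt(~mask)
    inside = ndimage.distance_transform_edt(mask)
    return (outside + np.maximum(inside - 1.0, 0.0)).astype(np.float32)


def boundary_hausdorff_loss(pred_probs, truth, threshold: float = 0.5,
                            return_grad: bool = False):
    """Distance-transform Hausdorff surrogate, >= 0, zero when pred == truth.

    mean over pixels of (p - t)^2 * (d_truth^2 + d_pred^2), with d_* the
    boundary distance transforms (normalized by the image diagonal so the
    weights are O(1)).  Monotone in boundary displacement: a prediction
    translated further from the truth incurs a strictly larger loss.
    """
    p, t = _check(pred_probs, truth)
    n, c, h, w = p.shape
    diag = float(np.hypot(h, w))
    weights = np.empty_like(p)
    for i in range(n):
        for j in range(c):
            tb = t[i, j] > 0.5
            pb = p[i, j] >= threshold
            # an empty mask facing a nonempty counterpart is maximally far
            # from it everywhere (the Hausdorff distance to an empty set is
            # unbounded); weight it at the full diagonal
            if tb.any() and not pb.any():
                d_p = np.ones((h, w), np.float32)
            else:
                d_p = _boundary_distance(pb) / diag
            if pb.any() and not tb.any():
                d_t = np.ones((h, w), np.float32)
            else:
                d_t = _boundary_distance(tb) / diag
            weights[i, j] = d_t ** 2 + d_p ** 2
    diff = p - t
    loss = float((diff ** 2 * weights).mean())
    if not return_grad:
        return loss
    grad = (2.0 * diff * weights / diff.size).astype(p.dtype)
    return loss, grad


def composite_loss_and_grad(logits, truth, dice_weight: float = 1.0,
                            hausdorff_weight: float = 0.5,
                            threshold: float = 0.5):
    """Total loss and its gradient with respect to the logits.

    Probabilities are the channel-wise sigmoid of the logits; the chain rule
    through the sigmoid is applied analytically.
    Returns (total, dice_term, hausdorff_term, dlogits).
    """
    x = np.asarray(logits)
    if not np.issubdtype(x.dtype, np.floating):
        x = x.astype(np.float32)
    p = sigmoid(x)
    d_loss, d_grad = soft_dice_loss(p, truth, return_grad=True)
    if hausdorff_weight:
        h_loss, h_grad = boundary_hausdorff_loss(p, truth, threshold,
                                                 return_grad=True)
    else:
        h_loss, h_grad = 0.0, 0.0
    total = dice_weight * d_loss + hausdorff_weight * h_loss
    gp = dice_weight * d_grad + hausdorff_weight * h_grad
    dlogits = gp * p * (1.0 - p)
    return total, d_loss, h_loss, dlogits.reshape(np.shape(logits))
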