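"""Dual-task soft Dice loss.

The network trains on the negated soft Dice coefficient, averaged over
classes and batch: L(Y, Y~) = -(1/N) sum 2 Y Y~ / (Y + Y~), evaluated
per class with voxelwise products summed spatially and an epsilon in
numerator and denominator to keep absent classes finite. The total loss
weights the binary (whole hippocampus) and multi-class (subfield)
branches: L_total = lambda1 * L1 + lambda2 * L2 with both weights 0.5 by
default.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .nn import Tensor, as_tensor, softmax


@dataclasses.dataclass
class LossSpec:
    lambda1: float = 0.5   # binary (hippocampus) branch weight
    lambda2: float = 0.5   # subfield branch weight
    smooth: float = 1e-5   # epsilon in numerator and denominator

    def validate(self) -> None:
        if self.lambda1 < 0 or self.lambda2 < 0 or self.lambda1 + self.lambda2 <= 0:
            raise ValueError("loss weights must be >= 0 with a positive sum")


def one_hot(labels: np.ndarray, n_classes: int, dtype=np.float64) -> np.ndarray:
    """(B, D, H, W) integer labels -> (B, C, D, H, W) one-hot."""
    out = np.zeros((labels.shape[0], n_classes) + labels.shape[1:], dtype=dtype)
    for c in range(n_classes):
        out[:, c] = labels == c
    return out


def dice_loss(pred_probs: Tensor, target_onehot: np.ndarray,
              spec: LossSpec | None = None) -> Tensor:
    """Soft Dice loss in [-1, 0]; -1 at perfect overlap, ~0 when disjoint."""
    spec = spec or LossSpec()
    pred_probs = as_tensor(pred_probs)
    if pred_probs.shape != target_onehot.shape:
        raise ValueError(f"pred {pred_probs.shape} vs target "
                         f"{target_onehot.shape} shape mismatch")
    t = Tensor(np.asarray(target_onehot, dtype=pred_probs.dtype))
    axes = (2, 3, 4)
    inter = (pred_probs * t).sum(axis=axes)          # (B, C)
    denom = (pred_probs + t).sum(axis=axes)
    dice = (2.0 * inter + spec.smooth) / (denom + spec.smooth)
    return -dice.mean()


def total_loss(binary_logits: Tensor | None, subfield_logits: Tensor,
               labels: np.ndarray, spec: LossSpec | None = None) -> Tensor:
    """lambda1 * Dice(binary branch) + lambda2 * Dice(subfield branch).

    `labels` is the (B, D, H, W) integer subfield map; the binary target
    is labels > 0. With lambda1 == 0 (or a single-branch model) only the
    subfield term contributes.
    """
    spec = spec or LossSpec()
    spec.validate()
    subfield_logits = as_tensor(subfield_logits)
    n_sub = subfield_logits.shape[1]
    sub_probs = softmax(subfield_logits, axis=1)
    l2 = dice_loss(sub_probs, one_hot(labels, n_sub, subfield_logits.dtype), spec)
    if spec.lambda1 == 0:
        return spec.lambda2 * l2
    if binary_logits is None:
        raise ValueError("binary branch weight is nonzero but the model "
                         "produced no binary logits")
    binary_logits = as_tensor(binary_logits)
    bin_probs = softmax(binary_logits, axis=1)
    bin_target = one_hot((labels > 0).astype(np.int64),
                         binary_logits.shape[1], binary_logits.dtype)
    l1 = dice_loss(bin_probs, bin_target, spec)
    return spec.lambda1 * l1 + spec.lambda2 * l2
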