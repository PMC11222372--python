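"""Dice loss / Dice coefficient / HD95 against brute-force oracles."""

import numpy as np
import pytest
from scipy import ndimage
from scipy.spatial.distance import cdist

from hipposeg.grids import LabelMap
from hipposeg.losses import LossSpec, dice_loss, one_hot, total_loss
from hipposeg.metrics import (
    boundary_voxels, dice_coefficient, evaluate, hausdorff, hd95,
)
from hipposeg.nn import Tensor, softmax


# ------------------------------------------------------------- dice loss

def test_dice_loss_perfect_prediction_is_minus_one(rng):
    y = rng.integers(0, 4, (2, 4, 4, 4))
    t = one_hot(y, 4)
    loss = dice_loss(Tensor(t), t)
    assert abs(loss.item() + 1.0) < 1e-4


def test_dice_loss_disjoint_masks_is_zero():
    pred = np.zeros((1, 2, 2, 2, 2))
    targ = np.zeros((1, 2, 2, 2, 2))
    pred[0, 1, 0] = 1          # predicts class 1 in the z=0 slab
    pred[0, 0, 1] = 1
    targ[0, 1, 1] = 1          # truth has class 1 in the z=1 slab
    targ[0, 0, 0] = 1
    loss = dice_loss(Tensor(pred), targ)
    assert abs(loss.item()) < 1e-4


def test_dice_loss_matches_accumulation_oracle():
    rng = np.random.default_rng(9)
    logits = rng.normal(size=(2, 4, 3, 3, 3))
    probs = softmax(Tensor(logits), axis=1)
    y = rng.integers(0, 4, (2, 3, 3, 3))
    t = one_hot(y, 4)
    spec = LossSpec()
    got = dice_loss(probs, t, spec).item()
    # independent per-class, per-sample accumulation
    p = probs.data
    terms = []
    for b in range(2):
        for c in range(4):
            inter = float((p[b, c] * t[b, c]).sum())
            denom = float((p[b, c] + t[b, c]).sum())
            terms.append((2 * inter + spec.smooth) / (denom + spec.smooth))
    assert abs(got + np.mean(terms)) < 1e-9


def test_dice_loss_equals_negated_dice_for_hard_masks(rng):
    y = rng.integers(0, 2, (1, 4, 4, 4))
    t = one_hot(y, 2)
    pred = one_hot(rng.integers(0, 2, (1, 4, 4, 4)), 2)
    loss = dice_loss(Tensor(pred), t).item()
    d = np.mean([dice_coefficient(pred[0, c] > 0, t[0, c] > 0) for c in (0, 1)])
    assert abs(loss + d) < 1e-4


def test_total_loss_weights_and_degenerate_lambda(rng):
    y = rng.integers(0, 4, (1, 4, 4, 4))
    sub_logits = Tensor(rng.normal(size=(1, 4, 4, 4, 4)))
    bin_logits = Tensor(rng.normal(size=(1, 2, 4, 4, 4)))
    spec = LossSpec()
    got = total_loss(bin_logits, sub_logits, y, spec).item()
    l1 = dice_loss(softmax(bin_logits, axis=1),
                   one_hot((y > 0).astype(np.int64), 2), spec).item()
    l2 = dice_loss(softmax(sub_logits, axis=1), one_hot(y, 4), spec).item()
    assert abs(got - (0.5 * l1 + 0.5 * l2)) < 1e-9
    only_sub = total_loss(None, sub_logits, y, LossSpec(lambda1=0.0)).item()
    assert abs(only_sub - 0.5 * l2) < 1e-9


def test_total_loss_perfect_both_branches(rng):
    y = rng.integers(0, 4, (1, 4, 4, 4))
    sub = Tensor(1000.0 * (one_hot(y, 4) - 0.5))           # hard softmax
    binary = Tensor(1000.0 * (one_hot((y > 0).astype(np.int64), 2) - 0.5))
    assert abs(total_loss(binary, sub, y).item() + 1.0) < 1e-3


def test_total_loss_missing_binary_branch_raises(rng):
    y = rng.integers(0, 4, (1, 4, 4, 4))
    with pytest.raises(ValueError, match="binary"):
        total_loss(None, Tensor(rng.normal(size=(1, 4, 4, 4, 4))), y)


# ------------------------------------------------------------- dice metric

def test_dice_coefficient_examples():
    a = np.zeros((4, 4, 4), dtype=bool)
    a[:2] = True
    assert dice_coefficient(a, a) == 1.0
    b = np.zeros_like(a)
    assert dice_coefficient(b, b) == 1.0     # both empty
    assert dice_coefficient(a, b) == 0.0     # one empty
    a8 = np.zeros((4, 4, 4), dtype=bool)
    b8 = np.zeros_like(a8)
    a8.ravel()[:8] = True
    b8.ravel()[4:12] = True                  # |A|=|B|=8, overlap 4
    assert dice_coefficient(a8, b8) == 0.5


def test_dice_coefficient_matches_set_oracle_many_seeds():
    for seed in range(100):
        rng = np.random.default_rng(seed)
        a = rng.random((5, 5, 5)) < 0.3
        b = rng.random((5, 5, 5)) < 0.3
        got = dice_coefficient(a, b)
        na, nb = a.sum(), b.sum()
        inter = np.logical_and(a, b).sum()
        want = 1.0 if na + nb == 0 else 2 * inter / (na + nb)
        assert got == want


# ------------------------------------------------------------- hd95

def _hd95_bruteforce(a, b, spacing):
    """O(|A||B|) pairwise-distance oracle on boundary voxel sets."""
    pa = boundary_voxels(a) * np.asarray(spacing)
    pb = boundary_voxels(b) * np.asarray(spacing)
    d = cdist(pa, pb)
    pooled = np.sort(np.concatenate([d.min(axis=1), d.min(axis=0)]))
    return pooled[int(np.ceil(0.95 * pooled.size)) - 1]


def test_hd95_identical_masks_zero(rng):
    a = rng.random((6, 6, 6)) < 0.4
    a[0, 0, 0] = True
    assert hd95(a, a, (0.4, 0.4, 0.4)) == 0.0


def test_hd95_two_single_voxels():
    a = np.zeros((8, 8, 8), dtype=bool)
    b = np.zeros_like(a)
    a[1, 1, 1] = True
    b[6, 1, 1] = True  # 5 voxels apart along one axis
    assert abs(hd95(a, b, (0.4, 0.4, 0.4)) - 2.0) < 1e-12


def test_hd95_matches_bruteforce_oracle_many_seeds():
    spacing = (0.4, 0.4, 0.4)
    for seed in range(50):
        rng = np.random.default_rng(seed)
        a = np.zeros((7, 7, 7), dtype=bool)
        b = np.zeros_like(a)
        a.ravel()[rng.choice(343, size=rng.integers(1, 300), replace=False)] = True
        b.ravel()[rng.choice(343, size=rng.integers(1, 300), replace=False)] = True
        got = hd95(a, b, spacing)
        want = _hd95_bruteforce(a, b, spacing)
        assert abs(got - want) < 1e-9
        # symmetry, and never above the full Hausdorff distance
        assert abs(hd95(b, a, spacing) - got) < 1e-9
        h = hausdorff(a, b, spacing)
        assert got <= h + 1e-12


def test_hd95_empty_mask_is_undefined_not_an_error():
    a = np.zeros((4, 4, 4), dtype=bool)
    b = np.zeros_like(a)
    b[1, 1, 1] = True
    assert hd95(a, b) is None


# ------------------------------------------------------------- evaluate

def _ball_labels(shift=0):
    lab = np.zeros((16, 16, 16), dtype=np.int64)
    z, y, x = np.ogrid[:16, :16, :16]
    organ = (z - 8) ** 2 + (y - 8) ** 2 + (x - 8 - shift) ** 2 <= 25
    lab[organ & (z < 6)] = 1
    lab[organ & (z >= 6) & (z < 10)] = 2
    lab[organ & (z >= 10)] = 3
    return LabelMap(labels=lab, spacing=(0.4, 0.4, 0.4))


def test_evaluate_perfect_prediction():
    truth = _ball_labels()
    rep = evaluate(truth, truth)
    assert set(rep.dice) == {"CA1-3", "CA4/DG", "SUB", "Hippocampus"}
    assert all(v == 1.0 for v in rep.dice.values())
    assert all(v == 0.0 for v in rep.hd95.values())


def test_evaluate_missing_label_flags_undefined():
    truth = _ball_labels()
    pred_arr = truth.labels.copy()
    pred_arr[pred_arr == 2] = 1   # prediction never emits label 2
    pred = LabelMap(labels=pred_arr, spacing=truth.spacing)
    rep = evaluate(pred, truth)
    assert rep.dice["CA4/DG"] == 0.0
    assert rep.hd95["CA4/DG"] is None
    assert rep.dice["Hippocampus"] == 1.0  # union unchanged


def test_evaluate_dilated_label_matches_oracle():
    truth = _ball_labels()
    grown = truth.labels.copy()
    mask1 = ndimage.binary_dilation(truth.labels == 1)
    grown[mask1 & (truth.labels == 0)] = 1
    pred = LabelMap(labels=grown, spacing=truth.spacing)
    rep = evaluate(pred, truth)
    for name, lab in (("CA1-3", 1), ("CA4/DG", 2), ("SUB", 3)):
        want = dice_coefficient(grown == lab, truth.labels == lab)
        assert rep.dice[name] == want
    want_u = dice_coefficient(grown > 0, truth.labels > 0)
    assert rep.dice["Hippocampus"] == want_u


def test_evaluate_union_mask_is_set_union():
    truth = _ball_labels()
    pred = _ball_labels(shift=2)
    rep = evaluate(pred, truth)
    assert rep.dice["Hippocampus"] == dice_coefficient(
        pred.labels > 0, truth.labels > 0)


def test_evaluate_grid_mismatch_raises():
    with pytest.raises(ValueError, match="mismatch"):
        evaluate(_ball_labels(),
                 LabelMap(labels=np.zeros((8, 8, 8), dtype=np.int64)))
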