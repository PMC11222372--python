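"""Schedule, patch sampling, augmentation and the training loop."""

import dataclasses

import numpy as np
import pytest

from hipposeg.model import ModelConfig
from hipposeg.phantom import PhantomConfig, generate_phantom
from hipposeg.training import (
    CheckpointSet, TrainConfig, TrainResult, augment, poly_lr, sample_patch,
    train,
)


@pytest.fixture
def small_train_cfg():
    return TrainConfig(patch_size=(32, 32, 32), batch_size=2, max_epochs=10,
                       seed=0)


@pytest.fixture
def small_model_cfg():
    return ModelConfig(base_channels=2, token_dim=8, n_heads=2, cbam_reduction=2)


@pytest.fixture
def train_phantom():
    cfg = PhantomConfig(grid_shape=(32, 32, 32), organ_axes=(11, 8, 7),
                        n_distractors=0, noise_sd=0.02, bias_amplitude=0.05,
                        seed=21)
    from hipposeg.grids import zscore_normalize
    vol, lab = generate_phantom(cfg)
    return zscore_normalize(vol), lab


# ------------------------------------------------------------- schedule

def test_poly_lr_endpoints_and_midpoint():
    cfg = TrainConfig()
    assert poly_lr(0, 100, cfg) == 0.001
    assert poly_lr(100, 100, cfg) == 0.0
    assert abs(poly_lr(50, 100, cfg) - 0.001 * 0.5 ** 0.9) < 1e-15


def test_poly_lr_monotone_non_increasing():
    cfg = TrainConfig()
    lrs = [poly_lr(i, 200, cfg) for i in range(201)]
    assert all(a >= b for a, b in zip(lrs, lrs[1:]))
    with pytest.raises(ValueError):
        poly_lr(0, 0, cfg)


# ------------------------------------------------------------- sampling

def test_sample_patch_exact_size_is_identity(small_train_cfg, rng):
    vol = rng.normal(size=(2, 32, 32, 32))
    lab = rng.integers(0, 4, (32, 32, 32))
    p, l = sample_patch(vol, lab, small_train_cfg, rng)
    np.testing.assert_array_equal(p, vol)
    np.testing.assert_array_equal(l, lab)


def test_sample_patch_deterministic_with_seed(small_train_cfg, rng):
    vol = rng.normal(size=(2, 48, 48, 48))
    lab = rng.integers(0, 4, (48, 48, 48))
    a = sample_patch(vol, lab, small_train_cfg, np.random.default_rng(5))
    b = sample_patch(vol, lab, small_train_cfg, np.random.default_rng(5))
    np.testing.assert_array_equal(a[0], b[0])
    np.testing.assert_array_equal(a[1], b[1])


def test_sample_patch_pads_small_volumes(small_train_cfg, rng):
    vol = rng.normal(size=(2, 20, 32, 32))
    lab = rng.integers(0, 4, (20, 32, 32))
    p, l = sample_patch(vol, lab, small_train_cfg, rng)
    assert p.shape == (2, 32, 32, 32) and l.shape == (32, 32, 32)
    np.testing.assert_array_equal(p[:, 6:26], vol)


def test_sample_patch_corners_uniform(small_train_cfg):
    """Corner marginals over the 5^3 valid positions of a 36^3 volume."""
    vol = np.zeros((1, 36, 36, 36))
    for z in range(36):
        vol[0, z] = z  # encode the D-corner in the patch content
    lab = np.zeros((36, 36, 36), dtype=np.int64)
    rng = np.random.default_rng(17)
    n = 4000
    counts = np.zeros(5)
    for _ in range(n):
        p, _ = sample_patch(vol, lab, small_train_cfg, rng)
        counts[int(p[0, 0, 0, 0])] += 1
    expected = n / 5
    sigma = np.sqrt(n * 0.2 * 0.8)
    assert np.all(np.abs(counts - expected) < 4 * sigma)


# ------------------------------------------------------------- augmentation

def test_augment_degenerate_config_is_identity(rng):
    cfg = TrainConfig(patch_size=(16, 16, 16), mirror_prob=0.0,
                      intensity_shift_range=(0.0, 0.0), scale_range=(1.0, 1.0))
    p = rng.normal(size=(2, 16, 16, 16))
    l = rng.integers(0, 4, (16, 16, 16))
    p2, l2 = augment(p, l, cfg, rng)
    np.testing.assert_array_equal(p2, p)
    np.testing.assert_array_equal(l2, l)


def test_augment_mirror_is_involution(rng):
    cfg = TrainConfig(patch_size=(8, 8, 8), mirror_prob=1.0,
                      intensity_shift_range=(0.0, 0.0), scale_range=(1.0, 1.0))
    p = rng.normal(size=(1, 8, 8, 8))
    l = rng.integers(0, 4, (8, 8, 8))
    p1, l1 = augment(p, l, cfg, np.random.default_rng(0))
    p2, l2 = augment(p1, l1, cfg, np.random.default_rng(1))
    np.testing.assert_array_equal(p2, p)
    np.testing.assert_array_equal(l2, l)


def test_augment_scaling_shrinks_foreground_volume(rng):
    cfg = TrainConfig(patch_size=(32, 32, 32), mirror_prob=0.0,
                      intensity_shift_range=(0.0, 0.0), scale_range=(0.9, 0.9))
    z, y, x = np.ogrid[:32, :32, :32]
    ball = ((z - 16) ** 2 + (y - 16) ** 2 + (x - 16) ** 2 <= 100)
    lab = ball.astype(np.int64)
    p = lab[None].astype(float)
    _, l2 = augment(p, lab, cfg, rng)
    ratio = l2.sum() / lab.sum()
    assert abs(ratio - 0.9 ** 3) < 0.1 * 0.9 ** 3
    assert set(np.unique(l2)) <= {0, 1}  # no new classes


def test_augment_never_invents_labels(rng):
    cfg = TrainConfig(patch_size=(16, 16, 16))
    lab = (rng.random((16, 16, 16)) < 0.2).astype(np.int64) * 3
    p = rng.normal(size=(2, 16, 16, 16))
    for seed in range(5):
        _, l2 = augment(p, lab, cfg, np.random.default_rng(seed))
        assert set(np.unique(l2)) <= set(np.unique(lab))


# ------------------------------------------------------------- checkpoints

def test_checkpoint_ring_buffer_semantics():
    cs = CheckpointSet(capacity=4)
    for e in range(1, 11):
        cs.push(e, {"w": np.array([e])})
    assert cs.epochs == [7, 8, 9, 10]
    with pytest.raises(ValueError, match="increase"):
        cs.push(10, {})


# ------------------------------------------------------------- training loop

def test_training_smoke_and_wiring(small_model_cfg, small_train_cfg,
                                   train_phantom):
    result = train([train_phantom], small_model_cfg, small_train_cfg)
    assert isinstance(result, TrainResult)
    assert len(result.loss_curve) == 10
    assert np.all(np.isfinite(result.loss_curve))
    assert result.loss_curve[-1] < result.loss_curve[0]
    assert result.checkpoints.epochs == [7, 8, 9, 10]
    # lr trace equals the schedule at every step
    want = [poly_lr(i, 10, small_train_cfg) for i in range(10)]
    np.testing.assert_allclose(result.lr_trace, want, rtol=1e-12)


def test_training_is_deterministic(small_model_cfg, train_phantom):
    cfg = TrainConfig(patch_size=(32, 32, 32), batch_size=1, max_epochs=4,
                      seed=33)
    a = train([train_phantom], small_model_cfg, cfg)
    b = train([train_phantom], small_model_cfg, cfg)
    assert a.loss_curve == b.loss_curve
    for ka, kb in zip(a.checkpoints.states, b.checkpoints.states):
        for name in ka:
            np.testing.assert_array_equal(ka[name], kb[name])


def test_training_rejects_empty_dataset(small_model_cfg, small_train_cfg):
    with pytest.raises(ValueError, match="empty"):
        train([], small_model_cfg, small_train_cfg)
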