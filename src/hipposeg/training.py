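"""Training: Adam + poly learning-rate schedule, random patch sampling,
mirror / intensity-shift / scale augmentation, and last-k checkpointing.

Defaults follow the reference recipe: lr 0.001 with poly exponent 0.9
decaying to zero over training, batch size 4, 128^3 patches, per-axis
mirroring with probability 0.5, intensity shifts in [-0.1, 0.1] (applied
on the z-scored intensity scale), isotropic scaling in [0.9, 1.1], L2
weight decay 1e-5, 8000 epochs, and the last 4 per-epoch checkpoints
retained for output averaging. Everything is reproducible from the
config seed on a fixed machine.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Sequence

import numpy as np
from scipy import ndimage

from .grids import LabelMap, Volume
from .losses import LossSpec, total_loss
from .model import DSNet, ModelConfig
from .nn import Adam, Tensor

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class TrainConfig:
    lr0: float = 0.001
    poly_power: float = 0.9
    batch_size: int = 4
    patch_size: tuple[int, int, int] = (128, 128, 128)
    max_epochs: int = 8000
    weight_decay: float = 1e-5
    mirror_prob: float = 0.5
    intensity_shift_range: tuple[float, float] = (-0.1, 0.1)
    scale_range: tuple[float, float] = (0.9, 1.1)
    keep_last_k_checkpoints: int = 4
    seed: int = 0

    def validate(self, n_stages: int = 5) -> None:
        div = 2 ** (n_stages - 1)
        for s in self.patch_size:
            if s % div:
                raise ValueError(f"patch dim {s} not divisible by {div}")
        for name, (lo, hi) in (("intensity_shift_range", self.intensity_shift_range),
                               ("scale_range", self.scale_range)):
            if lo > hi:
                raise ValueError(f"{name} is not well-ordered: ({lo}, {hi})")


@dataclasses.dataclass
class CheckpointSet:
    """Ring buffer of the last k model states (strictly increasing epochs)."""
    states: list[dict[str, np.ndarray]] = dataclasses.field(default_factory=list)
    epochs: list[int] = dataclasses.field(default_factory=list)
    capacity: int = 4

    def push(self, epoch: int, state: dict[str, np.ndarray]) -> None:
        if self.epochs and epoch <= self.epochs[-1]:
            raise ValueError("checkpoint epochs must strictly increase")
        self.states.append(state)
        self.epochs.append(epoch)
        while len(self.states) > self.capacity:
            self.states.pop(0)
            self.epochs.pop(0)

    def __len__(self) -> int:
        return len(self.states)


@dataclasses.dataclass
class TrainResult:
    checkpoints: CheckpointSet
    loss_curve: list[float]          # per-epoch mean training loss
    lr_trace: list[float]            # per-iteration learning rate
    model: DSNet


class TrainingDiverged(RuntimeError):
    def __init__(self, epoch: int):
        super().__init__(f"non-finite loss at epoch {epoch}")
        self.epoch = epoch


def poly_lr(iteration: int, total: int, cfg: TrainConfig) -> float:
    """lr = lr0 * (1 - t/T)^p; monotone non-increasing, 0 at t = T."""
    if total <= 0:
        raise ValueError("total iteration count must be positive")
    if not 0 <= iteration <= total:
        raise ValueError(f"iteration {iteration} outside [0, {total}]")
    return cfg.lr0 * (1.0 - iteration / total) ** cfg.poly_power


def sample_patch(volume: np.ndarray, labels: np.ndarray, cfg: TrainConfig,
                 rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Uniformly random patch crop; image (C,D,H,W) and labels cropped
    identically. Undersized volumes are symmetrically zero-padded first."""
    ps = cfg.patch_size
    pad = [(0, 0)]
    lpad = []
    for ax, p in enumerate(ps):
        short = max(0, p - volume.shape[ax + 1])
        lo = short // 2
        pad.append((lo, short - lo))
        lpad.append((lo, short - lo))
    if any(p != (0, 0) for p in pad):
        volume = np.pad(volume, pad)
        labels = np.pad(labels, lpad)
    corner = [int(rng.integers(0, volume.shape[ax + 1] - p + 1))
              for ax, p in enumerate(ps)]
    sl = tuple(slice(c, c + p) for c, p in zip(corner, ps))
    return volume[(slice(None),) + sl].copy(), labels[sl].copy()


def augment(patch: np.ndarray, labels: np.ndarray, cfg: TrainConfig,
            rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Random mirroring / scaling / intensity shift.

    Each spatial axis is mirrored independently with cfg.mirror_prob; one
    isotropic zoom factor is drawn from cfg.scale_range (trilinear for
    the image, nearest-neighbour for labels, recentred to the patch
    size); one additive shift per channel from cfg.intensity_shift_range.
    All draws happen unconditionally so the random stream does not depend
    on which augmentations fire.
    """
    ps = patch.shape[1:]
    flips = rng.random(3) < cfg.mirror_prob
    zoom = float(rng.uniform(*cfg.scale_range))
    shifts = rng.uniform(*cfg.intensity_shift_range, size=patch.shape[0])

    for ax in range(3):
        if flips[ax]:
            patch = np.flip(patch, axis=ax + 1)
            labels = np.flip(labels, axis=ax)
    patch, labels = patch.copy(), labels.copy()

    if zoom != 1.0:
        zoomed = np.stack([ndimage.zoom(patch[c], zoom, order=1)
                           for c in range(patch.shape[0])])
        zlabels = ndimage.zoom(labels, zoom, order=0)
        patch = _recenter(zoomed, ps, spatial_offset=1)
        labels = _recenter(zlabels[None], ps, spatial_offset=1)[0]

    patch = patch + shifts.reshape(-1, 1, 1, 1)
    return patch, labels


def _recenter(arr: np.ndarray, target, spatial_offset: int = 1) -> np.ndarray:
    """Center crop / zero-pad spatial axes back to `target`."""
    for i, tgt in enumerate(target):
        ax = i + spatial_offset
        cur = arr.shape[ax]
        if cur > tgt:
            lo = (cur - tgt) // 2
            idx = [slice(None)] * arr.ndim
            idx[ax] = slice(lo, lo + tgt)
            arr = arr[tuple(idx)]
        elif cur < tgt:
            lo = (tgt - cur) // 2
            pad = [(0, 0)] * arr.ndim
            pad[ax] = (lo, tgt - cur - lo)
            arr = np.pad(arr, pad)
    return arr


def train(dataset: Sequence[tuple[Volume, LabelMap]], model_cfg: ModelConfig,
          train_cfg: TrainConfig, loss_spec: LossSpec | None = None,
          model: DSNet | None = None) -> TrainResult:
    """Train DSNet on (Volume, LabelMap) pairs; returns the last-k
    checkpoints, per-epoch loss curve and per-iteration lr trace."""
    if not dataset:
        raise ValueError("empty training dataset")
    train_cfg.validate(model_cfg.n_stages)
    loss_spec = loss_spec or LossSpec()
    if not model_cfg.dual_branch and loss_spec.lambda1 != 0:
        loss_spec = dataclasses.replace(loss_spec, lambda1=0.0)

    arrays = [(v.data.astype(np.float32), l.labels) for v, l in dataset]
    rng = np.random.default_rng(train_cfg.seed)
    if model is None:
        model = DSNet(model_cfg, seed=int(rng.integers(0, 2 ** 31 - 1)))
    model.train()
    opt = Adam(model, lr=train_cfg.lr0, weight_decay=train_cfg.weight_decay)

    n = len(arrays)
    steps_per_epoch = max(1, int(np.ceil(n / train_cfg.batch_size)))
    total_iters = train_cfg.max_epochs * steps_per_epoch

    ckpts = CheckpointSet(capacity=train_cfg.keep_last_k_checkpoints)
    loss_curve: list[float] = []
    lr_trace: list[float] = []
    it = 0
    for epoch in range(1, train_cfg.max_epochs + 1):
        order = rng.permutation(n)
        epoch_losses = []
        for s in range(steps_per_epoch):
            idx = order[s * train_cfg.batch_size:(s + 1) * train_cfg.batch_size]
            if idx.size == 0:
                idx = order[:1]
            patches, labs = [], []
            for i in idx:
                p, l = sample_patch(*arrays[i], train_cfg, rng)
                p, l = augment(p, l, train_cfg, rng)
                patches.append(p)
                labs.append(l)
            x = np.stack(patches).astype(np.float32)
            y = np.stack(labs)
            opt.zero_grad()
            bin_logits, sub_logits = model(Tensor(x))
            loss = total_loss(bin_logits, sub_logits, y, loss_spec)
            lval = loss.item()
            if not np.isfinite(lval):
                raise TrainingDiverged(epoch)
            loss.backward()
            opt.lr = poly_lr(it, total_iters, train_cfg)
            lr_trace.append(opt.lr)
            opt.step()
            it += 1
            epoch_losses.append(lval)
        loss_curve.append(float(np.mean(epoch_losses)))
        ckpts.push(epoch, model.state_dict())
        if epoch == 1 or epoch % 50 == 0:
            logger.info("epoch %d  loss %.4f  lr %.2e", epoch,
                        loss_curve[-1], lr_trace[-1])
    return TrainResult(checkpoints=ckpts, loss_curve=loss_curve,
                       lr_trace=lr_trace, model=model)
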