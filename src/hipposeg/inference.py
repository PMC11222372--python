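"""Inference: non-overlapping sliding-window prediction with checkpoint
averaging, and connected-component false-positive removal.

The volume is zero-padded symmetrically to a multiple of the window,
tiled by disjoint windows, and each window's per-class softmax output is
averaged arithmetically over the retained checkpoints before the tiles
are reassembled and the padding cropped. Predicted foreground islands
smaller than a voxel-count threshold (1000 voxels = 64 mm^3 at 0.4 mm
isotropic spacing) are relabelled as background.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Sequence

import numpy as np
from scipy import ndimage

from .grids import LabelMap, Volume
from .nn import as_tensor, no_grad, softmax

DEFAULT_MIN_COMPONENT_VOXELS = 1000


def window_grid(shape: tuple[int, int, int],
                window: tuple[int, int, int]) -> list[tuple[slice, ...]]:
    """Disjoint window slices tiling the padded grid (ceil(s/w) per axis)."""
    counts = [math.ceil(s / w) for s, w in zip(shape, window)]
    slices = []
    for i in range(counts[0]):
        for j in range(counts[1]):
            for k in range(counts[2]):
                slices.append(tuple(slice(c * w, (c + 1) * w)
                                    for c, w in zip((i, j, k), window)))
    return slices


def window_count(shape: tuple[int, int, int],
                 window: tuple[int, int, int]) -> int:
    return int(np.prod([math.ceil(s / w) for s, w in zip(shape, window)]))


def _pad_to_multiple(arr: np.ndarray, window) -> tuple[np.ndarray, list[tuple[int, int]]]:
    pads = [(0, 0)]
    for ax, w in enumerate(window):
        s = arr.shape[ax + 1]
        extra = (w - s % w) % w
        lo = extra // 2
        pads.append((lo, extra - lo))
    return np.pad(arr, pads), pads[1:]


@dataclasses.dataclass
class Prediction:
    subfield_probs: np.ndarray          # (n_classes, D, H, W), sums to 1
    binary_probs: np.ndarray | None     # (2, D, H, W) or None


def sliding_window_predict(volume: Volume | np.ndarray, model,
                           checkpoints: Sequence[dict] | None = None,
                           window: tuple[int, int, int] = (128, 128, 128),
                           ) -> Prediction:
    """Predict per-class probabilities for a whole volume.

    `model` is any callable mapping a (1, C, d, h, w) array to
    (binary_logits | None, subfield_logits). `checkpoints` is a sequence
    of state dicts whose softmax outputs are averaged; None uses the
    model's current weights.
    """
    arr = volume.data if isinstance(volume, Volume) else np.asarray(volume)
    if arr.ndim == 3:
        arr = arr[None]
    arr = arr.astype(np.float32)
    orig_shape = arr.shape[1:]
    padded, pads = _pad_to_multiple(arr, window)
    tiles = window_grid(padded.shape[1:], window)

    states = list(checkpoints) if checkpoints else [None]
    if hasattr(model, "warmup"):
        model.warmup(window)
    if hasattr(model, "eval"):
        model.eval()

    sub_out = None
    bin_out = None
    for state in states:
        if state is not None:
            model.load_state_dict(state)
        for sl in tiles:
            block = padded[(slice(None),) + sl][None]
            with no_grad():
                bin_logits, sub_logits = model(block)
                sub_probs = softmax(as_tensor(sub_logits), axis=1).data[0]
                bin_probs = (softmax(as_tensor(bin_logits), axis=1).data[0]
                             if bin_logits is not None else None)
            if sub_out is None:
                sub_out = np.zeros((sub_probs.shape[0],) + padded.shape[1:])
                if bin_probs is not None:
                    bin_out = np.zeros((bin_probs.shape[0],) + padded.shape[1:])
            sub_out[(slice(None),) + sl] += sub_probs
            if bin_probs is not None:
                bin_out[(slice(None),) + sl] += bin_probs
    sub_out /= len(states)
    if bin_out is not None:
        bin_out /= len(states)

    crop = tuple(slice(lo, lo + s) for (lo, _), s in zip(pads, orig_shape))
    sub_out = sub_out[(slice(None),) + crop]
    if bin_out is not None:
        bin_out = bin_out[(slice(None),) + crop]
    return Prediction(subfield_probs=sub_out, binary_probs=bin_out)


def probabilities_to_labels(pred: Prediction, spacing=(0.4, 0.4, 0.4),
                            legend=None) -> LabelMap:
    """Hard labels = argmax over averaged subfield probabilities (ties
    resolve to the lowest class index, numpy argmax convention)."""
    labels = np.argmax(pred.subfield_probs, axis=0).astype(np.int64)
    kwargs = {} if legend is None else {"legend": legend}
    return LabelMap(labels=labels, spacing=spacing, **kwargs)


@dataclasses.dataclass
class RemovedComponent:
    size_voxels: int
    volume_mm3: float


def threshold_volume_mm3(min_voxels: int = DEFAULT_MIN_COMPONENT_VOXELS,
                         spacing=(0.4, 0.4, 0.4)) -> float:
    """Physical volume of the component threshold: voxels * prod(spacing)."""
    return float(min_voxels * np.prod(np.asarray(spacing, dtype=float)))


def cc_filter(pred: LabelMap, min_voxels: int = DEFAULT_MIN_COMPONENT_VOXELS,
              spacing: tuple[float, float, float] | None = None,
              ) -> tuple[LabelMap, list[RemovedComponent]]:
    """Remove small foreground islands.

    Connected components (26-neighbourhood) of the binary union mask with
    size strictly below `min_voxels` are set to background across all
    labels; components at or above the threshold are untouched. Returns
    the filtered map plus a report of removed component sizes/volumes.
    """
    spacing = spacing or pred.spacing
    voxel_mm3 = float(np.prod(np.asarray(spacing, dtype=float)))
    structure = np.ones((3, 3, 3), dtype=bool)
    comps, n = ndimage.label(pred.foreground(), structure=structure)
    labels = pred.labels.copy()
    removed: list[RemovedComponent] = []
    if n:
        sizes = np.bincount(comps.ravel())
        for comp_id in range(1, n + 1):
            size = int(sizes[comp_id])
            if size < min_voxels:
                labels[comps == comp_id] = 0
                removed.append(RemovedComponent(size, size * voxel_mm3))
    out = LabelMap(labels=labels, spacing=pred.spacing, origin=pred.origin,
                   legend=pred.legend)
    return out, removed
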