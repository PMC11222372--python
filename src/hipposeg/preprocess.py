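"""Dataset-level preprocessing: bounding box, fixed-grid crop, histogram
matching and flip-based doubling.

The pipeline mirrors the usual hippocampus-cropping recipe: scan all
training label maps for the union foreground extent, expand by a margin
(default 32 voxels per direction), crop every image to that box and bring
it to a uniform grid (the source dataset uses 267 x 182 x 174), match
intensities to a reference subject per channel, and double the training
set by mirroring along the left-right (W) axis.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Sequence

import numpy as np
from skimage.exposure import match_histograms

from .grids import LabelMap, Volume

logger = logging.getLogger(__name__)

DEFAULT_MARGIN = 32
DEFAULT_TARGET_SHAPE = (267, 182, 174)


@dataclasses.dataclass(frozen=True)
class BoundingBox:
    """Axis-aligned voxel box, min inclusive / max exclusive."""
    min_corner: tuple[int, int, int]
    max_corner: tuple[int, int, int]

    def __post_init__(self):
        if any(lo >= hi for lo, hi in zip(self.min_corner, self.max_corner)):
            raise ValueError(f"degenerate box {self.min_corner}..{self.max_corner}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(hi - lo for lo, hi in zip(self.min_corner, self.max_corner))

    def slices(self) -> tuple[slice, slice, slice]:
        return tuple(slice(lo, hi) for lo, hi in zip(self.min_corner, self.max_corner))


def compute_bounding_box(labels: Sequence[LabelMap], margin: int = DEFAULT_MARGIN,
                         ) -> BoundingBox:
    """Union foreground extent over all maps, expanded by `margin`, clipped."""
    if not labels:
        raise ValueError("need at least one label map")
    grid = labels[0].shape
    mins = np.full(3, np.iinfo(np.int64).max)
    maxs = np.full(3, -1)
    for lab in labels:
        fg = np.argwhere(lab.labels > 0)
        if fg.size == 0:
            continue
        mins = np.minimum(mins, fg.min(axis=0))
        maxs = np.maximum(maxs, fg.max(axis=0))
    if np.any(maxs < 0):
        raise ValueError("all label maps are background-only")
    lo = np.clip(mins - margin, 0, None)
    hi = np.minimum(maxs + 1 + margin, grid)
    return BoundingBox(tuple(int(v) for v in lo), tuple(int(v) for v in hi))


def _sym_pad_trim(arr: np.ndarray, target: tuple[int, int, int],
                  spatial_axes: tuple[int, ...]) -> np.ndarray:
    """Symmetric zero-pad or trim to `target`; the extra voxel goes high."""
    for ax, tgt in zip(spatial_axes, target):
        cur = arr.shape[ax]
        if cur < tgt:
            lo = (tgt - cur) // 2
            hi = tgt - cur - lo
            pad = [(0, 0)] * arr.ndim
            pad[ax] = (lo, hi)
            arr = np.pad(arr, pad)
        elif cur > tgt:
            lo = (cur - tgt) // 2
            idx = [slice(None)] * arr.ndim
            idx[ax] = slice(lo, lo + tgt)
            arr = arr[tuple(idx)]
    return arr


def crop_to_box(obj: Volume | LabelMap, box: BoundingBox,
                target_shape: tuple[int, int, int] | None = None):
    """Crop to `box`, then symmetrically zero-pad / trim to `target_shape`.

    No interpolation ever happens; labels stay integer and their identity
    is preserved whenever the target contains the cropped extent.
    """
    grid = obj.shape
    if any(hi > g for hi, g in zip(box.max_corner, grid)):
        raise ValueError(f"box {box} exceeds grid {grid}")
    target = tuple(target_shape) if target_shape is not None else box.shape
    if isinstance(obj, LabelMap):
        arr = obj.labels[box.slices()]
        if any(t < s for t, s in zip(target, arr.shape)) and np.any(arr > 0):
            logger.warning("target %s smaller than cropped extent %s; "
                           "foreground may be trimmed", target, arr.shape)
        arr = _sym_pad_trim(arr, target, (0, 1, 2))
        return LabelMap(labels=arr, spacing=obj.spacing, origin=obj.origin,
                        legend=obj.legend)
    arr = obj.data[(slice(None),) + box.slices()]
    arr = _sym_pad_trim(arr, target, (1, 2, 3))
    return Volume(data=arr, channels=obj.channels, spacing=obj.spacing,
                  origin=obj.origin)


def histogram_match(src: Volume, ref: Volume) -> Volume:
    """Match each channel's intensity histogram to the reference volume."""
    if src.channels != ref.channels:
        raise ValueError(f"channel sets differ: {src.channels} vs {ref.channels}")
    out = np.empty_like(src.data, dtype=np.float64)
    for c, name in enumerate(src.channels):
        r = ref.data[c]
        s = src.data[c]
        if r.max() == r.min():
            raise ValueError(f"reference channel {name!r} is constant")
        if s.max() == s.min():
            # a single-quantile image sits at the distribution's centre
            out[c] = np.median(r)
        else:
            out[c] = match_histograms(s.astype(np.float64), r.astype(np.float64))
    return Volume(data=out, channels=src.channels, spacing=src.spacing,
                  origin=src.origin)


def flip_double(dataset: Sequence[tuple[Volume, LabelMap]]
                ) -> list[tuple[Volume, LabelMap]]:
    """Append a left-right mirrored copy of every subject (doubles the set)."""
    if not dataset:
        raise ValueError("empty dataset")
    out = list(dataset)
    for vol, lab in dataset:
        out.append((flip_lr(vol), flip_lr(lab)))
    return out


def flip_lr(obj: Volume | LabelMap):
    """Mirror along the W (left-right) axis; subfield identities unchanged."""
    if isinstance(obj, LabelMap):
        return LabelMap(labels=obj.labels[:, :, ::-1].copy(), spacing=obj.spacing,
                        origin=obj.origin, legend=obj.legend)
    return Volume(data=obj.data[:, :, :, ::-1].copy(), channels=obj.channels,
                  spacing=obj.spacing, origin=obj.origin)
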