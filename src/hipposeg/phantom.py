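"""Synthetic two-modality hippocampus-like phantoms with subfield labels.

The phantom is an ellipsoidal "organ" partitioned into three contiguous
bands along its long axis, standing in for the CA1-3 / CA4-DG / subiculum
subfields. Two channels with distinct per-label contrast emulate
co-registered T1w and T2w images; a smooth multiplicative bias field,
additive Gaussian noise and small bright distractor blobs (placed well
away from the organ) exercise normalization, segmentation and
false-positive removal downstream. Everything is deterministic in the
config seed.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
from scipy import ndimage

from .grids import LabelMap, SUBFIELD_LEGEND, Volume

#: default per-label mean intensities (label -> mean), chosen so the
#: orderings differ between the two channels the way T1w/T2w contrast does
DEFAULT_CONTRAST_T1 = {0: 0.20, 1: 0.55, 2: 0.75, 3: 0.95}
DEFAULT_CONTRAST_T2 = {0: 0.15, 1: 0.90, 2: 0.50, 3: 0.70}

#: intensity of distractor blobs (brighter than every tissue class)
DISTRACTOR_INTENSITY = 1.2

#: minimum gap (voxels) between a distractor and the organ surface
DISTRACTOR_CLEARANCE = 8


@dataclasses.dataclass
class PhantomConfig:
    grid_shape: tuple[int, int, int] = (48, 48, 48)
    spacing: tuple[float, float, float] = (0.4, 0.4, 0.4)
    organ_axes: tuple[float, float, float] = (16.0, 11.0, 9.0)
    n_subfields: int = 3
    contrast_t1: dict[int, float] = dataclasses.field(
        default_factory=lambda: dict(DEFAULT_CONTRAST_T1))
    contrast_t2: dict[int, float] = dataclasses.field(
        default_factory=lambda: dict(DEFAULT_CONTRAST_T2))
    noise_sd: float = 0.02
    bias_amplitude: float = 0.1
    n_distractors: int = 3
    distractor_size_range: tuple[int, int] = (50, 300)
    seed: int = 0
    center: tuple[float, float, float] | None = None  # defaults to grid center

    def validate(self) -> None:
        shape = np.asarray(self.grid_shape)
        axes = np.asarray(self.organ_axes)
        center = np.asarray(self.center if self.center is not None else shape / 2.0)
        if np.any(center - axes < 4) or np.any(center + axes > shape - 4):
            raise ValueError(
                f"organ (center {tuple(center)}, axes {self.organ_axes}) does not "
                f"fit grid {self.grid_shape} with a 4-voxel margin")
        for name, con in (("contrast_t1", self.contrast_t1),
                          ("contrast_t2", self.contrast_t2)):
            vals = list(con.values())
            if len(set(vals)) != len(vals):
                raise ValueError(f"{name} means must be pairwise distinct")
        lo, hi = self.distractor_size_range
        if not (0 < lo <= hi):
            raise ValueError("distractor_size_range must satisfy 0 < lo <= hi")


@dataclasses.dataclass
class PhantomParts:
    """Ground-truth decomposition of a generated phantom (for tests/QC)."""
    volume: Volume
    label_map: LabelMap
    organ_mask: np.ndarray
    distractor_masks: list[np.ndarray]


def _ball_of_size(shape, center, n_voxels: int) -> np.ndarray:
    """Connected quasi-spherical blob of exactly n_voxels around center."""
    r = int(np.ceil((3 * n_voxels / (4 * np.pi)) ** (1 / 3))) + 2
    zz, yy, xx = [np.arange(max(0, int(c) - r), min(s, int(c) + r + 1))
                  for c, s in zip(center, shape)]
    grid = np.meshgrid(zz, yy, xx, indexing="ij")
    d2 = sum((g - c) ** 2 for g, c in zip(grid, center))
    flat = np.argsort(d2, axis=None, kind="stable")[:n_voxels]
    mask = np.zeros(shape, dtype=bool)
    idx = np.unravel_index(flat, d2.shape)
    mask[grid[0][idx], grid[1][idx], grid[2][idx]] = True
    return mask


def _build(cfg: PhantomConfig) -> PhantomParts:
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    shape = tuple(int(s) for s in cfg.grid_shape)
    center = np.asarray(cfg.center if cfg.center is not None
                        else np.asarray(shape) / 2.0, dtype=float)
    axes = np.asarray(cfg.organ_axes, dtype=float)

    zz, yy, xx = np.meshgrid(*[np.arange(s, dtype=float) for s in shape],
                             indexing="ij")
    quad = (((zz - center[0]) / axes[0]) ** 2
            + ((yy - center[1]) / axes[1]) ** 2
            + ((xx - center[2]) / axes[2]) ** 2)
    organ = quad <= 1.0

    # contiguous bands along the long (D) axis -> subfield labels 1..n
    labels = np.zeros(shape, dtype=np.int64)
    zs = zz[organ]
    zmin, zmax = zs.min(), zs.max()
    n = cfg.n_subfields
    band = np.floor((zz - zmin) / (zmax - zmin + 1.0) * n).astype(np.int64)
    band = np.clip(band, 0, n - 1)
    labels[organ] = band[organ] + 1
    for lab in range(1, n + 1):
        if not np.any(labels == lab):
            raise ValueError(f"subfield {lab} empty after rasterization; "
                             "enlarge organ_axes or the grid")

    # intensities: per-label means, then bias and noise
    con = {"t1w": cfg.contrast_t1, "t2w": cfg.contrast_t2}
    data = np.empty((2,) + shape, dtype=np.float64)
    for c, name in enumerate(("t1w", "t2w")):
        lut_keys = sorted(con[name])
        lut = np.zeros(max(lut_keys) + 1)
        for k in lut_keys:
            lut[k] = con[name][k]
        data[c] = lut[labels]

    # distractor blobs: bright, small, kept clear of the organ
    dist_to_organ = ndimage.distance_transform_edt(~organ)
    distractors: list[np.ndarray] = []
    occupied = organ.copy()
    lo, hi = cfg.distractor_size_range
    for _ in range(cfg.n_distractors):
        size = int(rng.integers(lo, hi + 1))
        r_est = (3 * size / (4 * np.pi)) ** (1 / 3) + 1
        placed = False
        for _attempt in range(1000):
            cand = np.array([rng.uniform(r_est + 1, s - r_est - 1) for s in shape])
            if dist_to_organ[tuple(cand.astype(int))] < DISTRACTOR_CLEARANCE + r_est:
                continue
            blob = _ball_of_size(shape, cand, size)
            if dist_to_organ[blob].min() < DISTRACTOR_CLEARANCE:
                continue
            grown = ndimage.binary_dilation(blob, iterations=2)
            if np.any(grown & occupied):
                continue
            distractors.append(blob)
            occupied |= grown
            data[:, blob] = DISTRACTOR_INTENSITY
            placed = True
            break
        if not placed:
            raise ValueError("could not place a distractor; grid too crowded")

    if cfg.bias_amplitude:
        u, v, w = (zz / shape[0], yy / shape[1], xx / shape[2])
        bias = 1.0 + cfg.bias_amplitude * np.sin(np.pi * u) * np.sin(np.pi * v) * np.sin(np.pi * w)
        data *= bias[None]
    if cfg.noise_sd:
        data += rng.normal(0.0, cfg.noise_sd, size=data.shape)

    vol = Volume(data=data, channels=("t1w", "t2w"),
                 spacing=cfg.spacing, origin=(0.0, 0.0, 0.0))
    legend = {k: SUBFIELD_LEGEND.get(k, f"band-{k}") for k in range(1, n + 1)}
    lab = LabelMap(labels=labels, spacing=cfg.spacing, origin=(0.0, 0.0, 0.0),
                   legend=legend)
    return PhantomParts(volume=vol, label_map=lab, organ_mask=organ,
                        distractor_masks=distractors)


def generate_phantom(cfg: PhantomConfig) -> tuple[Volume, LabelMap]:
    """Generate one phantom subject; identical cfg+seed gives identical output."""
    parts = _build(cfg)
    return parts.volume, parts.label_map


def generate_phantom_parts(cfg: PhantomConfig) -> PhantomParts:
    """Like generate_phantom but also exposing organ/distractor masks."""
    return _build(cfg)


def generate_cohort(cfg: PhantomConfig, n_subjects: int,
                    seed: int | None = None) -> list[tuple[Volume, LabelMap]]:
    """Generate a cohort of subjects with jittered organ pose and axes.

    Subjects share the grid geometry; organ center is jittered by up to
    ±2 voxels and semi-axes by up to ±10%, all reproducible from `seed`
    (defaults to cfg.seed).
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    cfg.validate()  # the base organ must fit before jitter is attempted
    root = np.random.SeedSequence(cfg.seed if seed is None else seed)
    out = []
    for child in root.spawn(n_subjects):
        rng = np.random.default_rng(child)
        sub_seed = int(rng.integers(0, 2 ** 31 - 1))
        shape = np.asarray(cfg.grid_shape, dtype=float)
        base_center = np.asarray(cfg.center if cfg.center is not None
                                 else shape / 2.0)
        for _attempt in range(100):
            center = base_center + rng.uniform(-2.0, 2.0, size=3)
            axes = np.asarray(cfg.organ_axes) * rng.uniform(0.9, 1.1, size=3)
            sub_cfg = dataclasses.replace(
                cfg, center=tuple(center), organ_axes=tuple(axes), seed=sub_seed)
            try:
                sub_cfg.validate()
            except ValueError:
                continue  # jitter pushed the organ out of the grid; redraw
            break
        else:
            raise ValueError("could not jitter the organ to fit the grid")
        out.append(generate_phantom(sub_cfg))
    return out
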