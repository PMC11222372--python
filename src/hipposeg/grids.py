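"""Core grid data types (Volume, LabelMap) and NIfTI-backed serialization.

Index convention throughout the package: arrays are indexed (D, H, W) =
(axial slice, row, column), 0-based, with inclusive-exclusive ranges.
Multi-channel volumes are stored on disk as one single-channel NIfTI file
per modality, paired by a filename suffix (``_t1w`` / ``_t2w``).
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Mapping, Sequence

import nibabel as nib
import numpy as np

SUBFIELD_LEGEND: dict[int, str] = {1: "CA1-3", 2: "CA4/DG", 3: "SUB"}


@dataclasses.dataclass
class Volume:
    """A 3D multi-channel intensity grid with physical voxel spacing.

    data has shape (C, D, H, W); ``channels`` names each modality in order
    (e.g. ``("t1w", "t2w")``). ``spacing`` is the voxel size in mm along
    (D, H, W); ``origin`` is the world coordinate of voxel (0, 0, 0).
    """

    data: np.ndarray
    channels: tuple[str, ...] = ("image",)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim == 3:
            self.data = self.data[None]
        if self.data.ndim != 4:
            raise ValueError(f"Volume data must be (C,D,H,W), got {self.data.shape}")
        self.channels = tuple(self.channels)
        if len(self.channels) != self.data.shape[0]:
            raise ValueError("channel names do not match data channels")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("Volume contains non-finite voxels")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 strictly positive values, got {self.spacing}")
        self.origin = tuple(float(o) for o in self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(self.data.shape[1:])

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    def channel(self, name: str) -> np.ndarray:
        return self.data[self.channels.index(name)]


@dataclasses.dataclass
class LabelMap:
    """Integer segmentation on the same grid as a paired Volume.

    Labels: 0 = background, and the keys of ``legend`` for foreground
    structures (default 1=CA1-3, 2=CA4/DG, 3=SUB).
    """

    labels: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    legend: Mapping[int, str] = dataclasses.field(
        default_factory=lambda: dict(SUBFIELD_LEGEND))

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError(f"LabelMap must be 3D, got shape {self.labels.shape}")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("LabelMap requires an integer array")
        self.legend = {int(k): str(v) for k, v in self.legend.items()}
        allowed = {0} | set(self.legend)
        present = set(np.unique(self.labels).tolist())
        if not present <= allowed:
            raise ValueError(f"labels {sorted(present - allowed)} missing from legend")
        self.spacing = tuple(float(s) for s in self.spacing)
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be strictly positive")
        self.origin = tuple(float(o) for o in self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(self.labels.shape)

    def foreground(self) -> np.ndarray:
        """Binary union mask of all foreground structures."""
        return self.labels > 0


def _affine(spacing, origin) -> np.ndarray:
    aff = np.diag(list(spacing) + [1.0]).astype(float)
    aff[:3, 3] = origin
    return aff


def write_nifti(obj: Volume | LabelMap, path: str | Path) -> None:
    """Write a Volume or LabelMap to NIfTI.

    Labels are stored as uint8 (lossless for the 4-class legend); volumes
    as float32. A multi-channel Volume is written as one file per channel
    with ``_<channel>`` inserted before the extension.
    """
    path = Path(path)
    if isinstance(obj, LabelMap):
        img = nib.Nifti1Image(obj.labels.astype(np.uint8),
                              _affine(obj.spacing, obj.origin))
        img.header.set_zooms(obj.spacing)
        nib.save(img, str(path))
        return
    if obj.n_channels == 1:
        arrs = {None: obj.data[0]}
    else:
        arrs = {name: obj.channel(name) for name in obj.channels}
    for name, arr in arrs.items():
        p = path if name is None else _channel_path(path, name)
        img = nib.Nifti1Image(arr.astype(np.float32),
                              _affine(obj.spacing, obj.origin))
        img.header.set_zooms(obj.spacing)
        nib.save(img, str(p))


def _channel_path(path: Path, channel: str) -> Path:
    suffixes = "".join(path.suffixes[-2:]) if path.name.endswith(".nii.gz") else path.suffix
    stem = path.name[: len(path.name) - len(suffixes)]
    return path.with_name(f"{stem}_{channel}{suffixes}")


def read_nifti(path: str | Path, *, as_labels: bool | None = None,
               channel: str | None = None) -> Volume | LabelMap:
    """Read a single NIfTI file into a Volume or LabelMap.

    By default the on-disk dtype decides: integer data yields a LabelMap,
    floating data a single-channel Volume; ``as_labels`` overrides.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such image: {path}")
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3D image, got shape {data.shape}")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    origin = tuple(float(v) for v in img.affine[:3, 3])
    is_int = np.issubdtype(data.dtype, np.integer)
    if as_labels is None:
        as_labels = is_int
    if as_labels:
        if not is_int:
            if not np.all(np.isfinite(data)):
                raise ValueError(f"{path}: label image contains non-finite voxels")
            data = np.rint(data).astype(np.int64)
        present = set(np.unique(data).tolist()) - {0}
        legend = {k: SUBFIELD_LEGEND.get(k, f"label-{k}") for k in sorted(present)}
        return LabelMap(labels=data.astype(np.int64), spacing=spacing,
                        origin=origin, legend=legend or dict(SUBFIELD_LEGEND))
    if not np.all(np.isfinite(data)):
        raise ValueError(f"{path}: image contains NaN/Inf voxels")
    name = channel or _infer_channel_name(path)
    return Volume(data=data.astype(np.float64)[None], channels=(name,),
                  spacing=spacing, origin=origin)


def _infer_channel_name(path: Path) -> str:
    stem = path.name.split(".")[0]
    for known in ("t1w", "t2w"):
        if stem.endswith(f"_{known}"):
            return known
    return "image"


def read_multichannel(base_path: str | Path, channels: Sequence[str]) -> Volume:
    """Read the per-modality files written by write_nifti into one Volume."""
    base_path = Path(base_path)
    vols = [read_nifti(_channel_path(base_path, ch), as_labels=False, channel=ch)
            for ch in channels]
    ref = vols[0]
    for v in vols[1:]:
        if v.shape != ref.shape or not np.allclose(v.spacing, ref.spacing):
            raise ValueError("channel files disagree on grid geometry")
    return Volume(data=np.concatenate([v.data for v in vols], axis=0),
                  channels=tuple(channels), spacing=ref.spacing, origin=ref.origin)


def zscore_normalize(v: Volume) -> Volume:
    """Standardize each channel to zero mean / unit variance over all voxels."""
    out = np.empty_like(v.data, dtype=np.float64)
    for c in range(v.n_channels):
        ch = v.data[c]
        sd = ch.std()
        if sd == 0:
            raise ValueError(
                f"channel {v.channels[c]!r} is constant; cannot standardize "
                "(degenerate volume or phantom config)")
        out[c] = (ch - ch.mean()) / sd
    return Volume(data=out, channels=v.channels, spacing=v.spacing, origin=v.origin)
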