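"""Evaluation metrics: Dice overlap and the 95th-percentile Hausdorff
distance (HD95), reported per subfield and for the whole hippocampus.

Dice = 2 |A & B| / (|A| + |B|) on voxel sets (two empty masks score 1,
one empty scores 0). HD95 pools the directed boundary distances from
both directions in physical millimetres, sorts them ascending, and takes
the lower nearest-rank 95th percentile; boundary voxels are foreground
voxels with at least one face-adjacent background neighbour.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree

from .grids import LabelMap

HIPPOCAMPUS = "Hippocampus"


def dice_coefficient(a: np.ndarray, b: np.ndarray) -> float:
    """Overlap 2|A&B|/(|A|+|B|); 1.0 if both masks empty, 0.0 if one is."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"grid mismatch: {a.shape} vs {b.shape}")
    na, nb = int(a.sum()), int(b.sum())
    if na + nb == 0:
        return 1.0
    return 2.0 * int((a & b).sum()) / (na + nb)


def boundary_voxels(mask: np.ndarray) -> np.ndarray:
    """Foreground voxels with a 6-connected background neighbour, as an
    (n, 3) index array (out-of-grid counts as background)."""
    mask = np.asarray(mask, dtype=bool)
    structure = ndimage.generate_binary_structure(3, 1)
    interior = ndimage.binary_erosion(mask, structure=structure, border_value=0)
    return np.argwhere(mask & ~interior)


def _pooled_boundary_distances(a: np.ndarray, b: np.ndarray,
                               spacing) -> np.ndarray:
    pa = boundary_voxels(a) * np.asarray(spacing, dtype=float)
    pb = boundary_voxels(b) * np.asarray(spacing, dtype=float)
    d_ab = cKDTree(pb).query(pa)[0]
    d_ba = cKDTree(pa).query(pb)[0]
    return np.sort(np.concatenate([d_ab, d_ba]))


def hd95(a: np.ndarray, b: np.ndarray, spacing=(1.0, 1.0, 1.0)) -> float | None:
    """95th-percentile symmetric boundary distance in mm; None if a mask
    is empty (undefined rather than an exception mid-report)."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"grid mismatch: {a.shape} vs {b.shape}")
    if not a.any() or not b.any():
        return None
    pooled = _pooled_boundary_distances(a, b, spacing)
    rank = int(np.ceil(0.95 * pooled.size)) - 1  # lower nearest-rank
    return float(pooled[rank])


def hausdorff(a: np.ndarray, b: np.ndarray, spacing=(1.0, 1.0, 1.0)) -> float | None:
    """Full symmetric Hausdorff distance on the same boundary sets."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if not a.any() or not b.any():
        return None
    return float(_pooled_boundary_distances(a, b, spacing)[-1])


@dataclasses.dataclass
class MetricsReport:
    """Per-structure Dice and HD95; hd95 is None where undefined."""
    dice: dict[str, float]
    hd95: dict[str, float | None]

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {"dice": self.dice, "hd95": self.hd95}
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    def to_frame(self, subject: str = "subject-0") -> pd.DataFrame:
        rows = [{"subject": subject, "structure": s, "dice": self.dice[s],
                 "hd95": self.hd95[s]} for s in self.dice]
        return pd.DataFrame(rows)


def evaluate(pred: LabelMap, truth: LabelMap,
             spacing: tuple[float, float, float] | None = None) -> MetricsReport:
    """Per-subfield Dice/HD95 plus the whole-hippocampus union scores."""
    if pred.shape != truth.shape:
        raise ValueError(f"grid mismatch: {pred.shape} vs {truth.shape}")
    if set(pred.legend) - set(truth.legend):
        raise ValueError("prediction legend contains labels unknown to truth")
    spacing = spacing or truth.spacing
    dice: dict[str, float] = {}
    hd: dict[str, float | None] = {}
    structures: list[tuple[str, int | None]] = \
        [(name, lab) for lab, name in sorted(truth.legend.items())] + \
        [(HIPPOCAMPUS, None)]
    for name, lab in structures:
        if lab is None:
            pm, tm = pred.foreground(), truth.foreground()
        else:
            pm, tm = pred.labels == lab, truth.labels == lab
        dice[name] = dice_coefficient(pm, tm)
        hd[name] = hd95(pm, tm, spacing)
    return MetricsReport(dice=dice, hd95=hd)


def reports_to_csv(reports: Mapping[str, MetricsReport], path: str | Path) -> None:
    """Flat CSV: one row per subject x structure."""
    frames = [rep.to_frame(subject) for subject, rep in reports.items()]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
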