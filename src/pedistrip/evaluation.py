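"""Conforming and mask-comparison metrics.

Volumes are conformed to a canonical grid (default 256³, 1 mm isotropic,
left-inferior-anterior axes) before training or evaluation. Accuracy is
reported as volumetric Dice overlap and Hausdorff distance between mask
boundaries (max and 95th-percentile variants), in world mm. Cohort-level
spatial error structure comes from a voxel-wise error-proportion map on the
shared conformed grid.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .core import BrainMask, IntensityVolume, LabelMap, Volume
from .targets import boundary_voxels

# world directions (RAS+) each voxel axis points along, for L-I-A orientation
_LIA_DIRECTIONS = np.array(
    [
        [-1.0, 0.0, 0.0],  # axis 0 -> Left
        [0.0, 0.0, -1.0],  # axis 1 -> Inferior
        [0.0, 1.0, 0.0],  # axis 2 -> Anterior
    ]
).T


def conform_affine(size: int = 256, spacing_mm: float = 1.0, world_center=None) -> np.ndarray:
    """Voxel-to-world affine of the conformed LIA grid, centered on a point."""
    aff = np.eye(4)
    aff[:3, :3] = _LIA_DIRECTIONS * spacing_mm
    c = np.zeros(3) if world_center is None else np.asarray(world_center, float)
    aff[:3, 3] = c - aff[:3, :3] @ (np.full(3, (size - 1) / 2.0))
    return aff


def conform(
    vol: Volume,
    size: int = 256,
    spacing_mm: float = 1.0,
    is_labels: bool = False,
) -> Volume:
    """Resample onto the canonical grid (trilinear; nearest for label data).

    The output field of view is centered on the input volume's world center,
    so conforming an axis-permuted or flipped copy of a volume yields the
    same array as conforming the original.
    """
    affine = np.asarray(vol.affine, float)
    if abs(np.linalg.det(affine[:3, :3])) < 1e-12:
        raise ValueError("input affine is missing or singular")
    in_center = (np.asarray(vol.shape) - 1) / 2.0
    world_center = affine[:3, :3] @ in_center + affine[:3, 3]
    out_aff = conform_affine(size, spacing_mm, world_center)

    m = np.linalg.inv(affine) @ out_aff  # output voxel -> input voxel
    order = 0 if is_labels else 1

    if isinstance(vol, LabelMap):
        arr = vol.data
        order = 0
    elif isinstance(vol, BrainMask):
        arr = vol.data.astype(np.uint8)
        order = 0
    else:
        arr = np.asarray(vol.data, dtype=np.float32)

    out = ndimage.affine_transform(
        arr,
        m[:3, :3],
        offset=m[:3, 3],
        output_shape=(size, size, size),
        order=order,
        mode="constant",
        cval=0,
    )
    if isinstance(vol, LabelMap):
        return LabelMap(out.astype(vol.data.dtype), out_aff, roles=vol.roles)
    if isinstance(vol, BrainMask):
        return BrainMask(out > 0, out_aff)
    return IntensityVolume(out, out_aff)


def dice_metric(a: BrainMask, b: BrainMask) -> float:
    """Volumetric Dice overlap 2|A∩B| / (|A|+|B|); 1.0 when both masks empty."""
    if a.shape != b.shape:
        raise ValueError(f"mask grids differ: {a.shape} vs {b.shape}")
    na, nb = int(a.data.sum()), int(b.data.sum())
    if na + nb == 0:
        return 1.0
    inter = int(np.logical_and(a.data, b.data).sum())
    return 2.0 * inter / (na + nb)


def _boundary_points_mm(mask: BrainMask) -> np.ndarray:
    idx = np.argwhere(boundary_voxels(mask.data))
    return idx @ mask.affine[:3, :3].T + mask.affine[:3, 3]


def hausdorff_metric(a: BrainMask, b: BrainMask, percentile: float = 100) -> float:
    """Symmetric Hausdorff distance (mm) between mask boundaries.

    Boundary = mask voxels with a background face-neighbor, taken at voxel
    centers in world coordinates. ``percentile`` 100 gives the classical
    Hausdorff; 95 the robust variant (max of the two directed percentiles).
    """
    if a.shape != b.shape:
        raise ValueError(f"mask grids differ: {a.shape} vs {b.shape}")
    if not a.data.any() or not b.data.any():
        raise ValueError("Hausdorff distance is undefined for an empty mask")
    pa, pb = _boundary_points_mm(a), _boundary_points_mm(b)
    d_ab = cKDTree(pb).query(pa)[0]
    d_ba = cKDTree(pa).query(pb)[0]
    if percentile >= 100:
        return float(max(d_ab.max(), d_ba.max()))
    return float(max(np.percentile(d_ab, percentile), np.percentile(d_ba, percentile)))


def error_map(cases: Sequence[Tuple[BrainMask, BrainMask]]) -> IntensityVolume:
    """Voxel-wise mean absolute prediction error across cases, in [0, 1]."""
    if not cases:
        raise ValueError("error_map needs at least one (predicted, reference) pair")
    first_pred = cases[0][0]
    acc = np.zeros(first_pred.shape, dtype=np.float64)
    for pred, ref in cases:
        if pred.shape != first_pred.shape or ref.shape != first_pred.shape:
            raise ValueError("all masks must share one common grid")
        acc += np.abs(pred.data.astype(np.int8) - ref.data.astype(np.int8))
    return IntensityVolume((acc / len(cases)).astype(np.float32), first_pred.affine)


@dataclass
class MetricsReport:
    """Per-case Dice / Hausdorff metrics plus cohort summary."""

    case_ids: List[str]
    dice: List[float]
    hausdorff_mm: List[float]
    hausdorff95_mm: List[float]
    summary: Dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if not self.summary and self.dice:
            self.summary = {
                "dice_mean": float(np.mean(self.dice)),
                "dice_sd": float(np.std(self.dice)),
                "hausdorff_mean_mm": float(np.mean(self.hausdorff_mm)),
                "hausdorff_sd_mm": float(np.std(self.hausdorff_mm)),
                "hausdorff95_mean_mm": float(np.mean(self.hausdorff95_mm)),
                "hausdorff95_sd_mm": float(np.std(self.hausdorff95_mm)),
            }

    def to_json(self, path=None) -> str:
        payload = {
            "cases": [
                {"id": i, "dice": d, "hausdorff_mm": h, "hausdorff95_mm": h95}
                for i, d, h, h95 in zip(
                    self.case_ids, self.dice, self.hausdorff_mm, self.hausdorff95_mm
                )
            ],
            "summary": self.summary,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def evaluate_cohort(
    pairs: Sequence[Tuple[BrainMask, BrainMask]], case_ids: Sequence[str] = None
) -> MetricsReport:
    """Dice and Hausdorff metrics for (predicted, reference) mask pairs."""
    ids = list(case_ids) if case_ids else [f"case_{i:03d}" for i in range(len(pairs))]
    dice, hd, hd95 = [], [], []
    for pred, ref in pairs:
        dice.append(dice_metric(pred, ref))
        hd.append(hausdorff_metric(pred, ref, percentile=100))
        hd95.append(hausdorff_metric(pred, ref, percentile=95))
    return MetricsReport(ids, dice, hd, hd95)
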