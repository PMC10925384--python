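"""Core volumetric containers and NIfTI / sidecar I/O.

All volumes pair a 3D array with a 4x4 voxel-to-world affine (NIfTI
convention, RAS+ world axes). Label maps additionally carry a label-role
table assigning each integer label one of three roles:

``brain``
    structures merged into the target brain mask (ventricles included);
``csf_nonvent``
    extracerebral / sulcal CSF, excluded from the mask;
``nonbrain``
    skull, scalp, background, and synthesis-only pseudo-labels.

The role table serializes to a tab-separated sidecar with columns
``label_id``, ``name``, ``role``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, Mapping, Tuple

import nibabel as nib
import numpy as np

ROLE_BRAIN = "brain"
ROLE_CSF_NONVENT = "csf_nonvent"
ROLE_NONBRAIN = "nonbrain"
_ROLES = (ROLE_BRAIN, ROLE_CSF_NONVENT, ROLE_NONBRAIN)


@dataclass(frozen=True)
class LabelRoles:
    """Immutable mapping label_id -> (name, role)."""

    table: Mapping[int, Tuple[str, str]]

    def __post_init__(self):
        for lid, (name, role) in self.table.items():
            if role not in _ROLES:
                raise ValueError(f"unknown role {role!r} for label {lid} ({name})")

    def ids_with_role(self, role: str) -> Tuple[int, ...]:
        return tuple(sorted(l for l, (_, r) in self.table.items() if r == role))

    @property
    def brain_ids(self) -> Tuple[int, ...]:
        return self.ids_with_role(ROLE_BRAIN)

    @property
    def csf_nonvent_ids(self) -> Tuple[int, ...]:
        return self.ids_with_role(ROLE_CSF_NONVENT)

    @property
    def nonbrain_ids(self) -> Tuple[int, ...]:
        return self.ids_with_role(ROLE_NONBRAIN)

    def name_of(self, label_id: int) -> str:
        return self.table[label_id][0]

    def extended(self, extra: Mapping[int, Tuple[str, str]]) -> "LabelRoles":
        clash = set(self.table) & set(extra)
        if clash:
            raise ValueError(f"label-id collision extending role table: {sorted(clash)}")
        merged = dict(self.table)
        merged.update(extra)
        return LabelRoles(merged)

    def to_tsv(self, path) -> None:
        lines = ["label_id\tname\trole"]
        for lid in sorted(self.table):
            name, role = self.table[lid]
            lines.append(f"{lid}\t{name}\t{role}")
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_tsv(cls, path) -> "LabelRoles":
        rows = Path(path).read_text().strip().splitlines()
        if not rows or rows[0].split("\t") != ["label_id", "name", "role"]:
            raise ValueError(f"malformed label-role table {path}")
        table = {}
        for row in rows[1:]:
            lid, name, role = row.split("\t")
            table[int(lid)] = (name, role)
        return cls(table)


def _check_affine(affine) -> np.ndarray:
    affine = np.asarray(affine, dtype=float)
    if affine.shape != (4, 4):
        raise ValueError("affine must be 4x4")
    if abs(np.linalg.det(affine[:3, :3])) < 1e-12:
        raise ValueError("affine is singular")
    return affine


@dataclass
class Volume:
    """A 3D array with a voxel-to-world affine."""

    data: np.ndarray
    affine: np.ndarray

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected 3D data, got shape {self.data.shape}")
        self.affine = _check_affine(self.affine)

    @property
    def shape(self) -> Tuple[int, int, int]:
        return self.data.shape

    @property
    def spacing(self) -> np.ndarray:
        """Voxel edge lengths in mm, per axis."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    def same_grid_as(self, other: "Volume", atol: float = 1e-4) -> bool:
        return self.shape == other.shape and np.allclose(
            self.affine, other.affine, atol=atol
        )


@dataclass
class IntensityVolume(Volume):
    """Scalar head image, synthesized or acquired."""

    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        super().__post_init__()
        self.data = self.data.astype(np.float32, copy=False)


@dataclass
class LabelMap(Volume):
    """Integer-labeled volume with a label-role table."""

    roles: LabelRoles = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        super().__post_init__()
        if not np.issubdtype(self.data.dtype, np.integer):
            raise ValueError("label map data must be an integer dtype")
        if self.roles is None:
            raise ValueError("label map requires a label-role table")

    def brain_union(self) -> np.ndarray:
        """Binary union of all role-brain labels (ventricles in, sulcal CSF out)."""
        return np.isin(self.data, self.roles.brain_ids)


@dataclass
class WholeHeadLabelMap(LabelMap):
    """Spliced training label map; provenance 1 = manual, 2 = GMM."""

    PROV_MANUAL = 1
    PROV_GMM = 2
    provenance: np.ndarray = None

    def __post_init__(self):
        super().__post_init__()
        if self.provenance is None:
            raise ValueError("whole-head label map requires per-voxel provenance")
        self.provenance = np.asarray(self.provenance, dtype=np.uint8)
        if self.provenance.shape != self.data.shape:
            raise ValueError("provenance shape mismatch")


@dataclass
class BrainMask(Volume):
    def __post_init__(self):
        super().__post_init__()
        arr = np.asarray(self.data)
        if arr.dtype != bool:
            uniq = np.unique(arr)
            if not np.all(np.isin(uniq, (0, 1))):
                raise ValueError("mask values must be binary")
            arr = arr.astype(bool)
        self.data = arr


@dataclass
class DistanceMap(Volume):
    """Signed Euclidean distance to the brain boundary, mm, negative inside."""

    def __post_init__(self):
        super().__post_init__()
        self.data = self.data.astype(np.float32, copy=False)


# ---------------------------------------------------------------------------
# NIfTI I/O


def _roles_sidecar(path) -> Path:
    p = Path(path)
    name = p.name
    for suf in (".nii.gz", ".nii"):
        if name.endswith(suf):
            name = name[: -len(suf)]
            break
    return p.with_name(name + ".labels.tsv")


def save_volume(vol: Volume, path) -> None:
    """Write a volume as NIfTI-1; label maps also write their role sidecar."""
    if isinstance(vol, LabelMap):
        data = vol.data.astype(np.int32)
        vol.roles.to_tsv(_roles_sidecar(path))
    elif isinstance(vol, BrainMask):
        data = vol.data.astype(np.uint8)
    else:
        data = vol.data.astype(np.float32)
    nib.save(nib.Nifti1Image(data, vol.affine), str(path))


def load_intensity(path) -> IntensityVolume:
    img = nib.load(str(path))
    return IntensityVolume(np.asarray(img.dataobj, dtype=np.float32), img.affine)


def load_labelmap(path, roles_path=None) -> LabelMap:
    img = nib.load(str(path))
    roles_path = roles_path or _roles_sidecar(path)
    roles = LabelRoles.from_tsv(roles_path)
    return LabelMap(np.asarray(img.dataobj).astype(np.int32), img.affine, roles=roles)


def load_mask(path) -> BrainMask:
    img = nib.load(str(path))
    return BrainMask(np.asarray(img.dataobj) > 0, img.affine)
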