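"""Seeded head-like phantoms: nested label maps and paired scan-like images.

The phantom emulates the gross geometry of a pediatric head scan: a brain
composed of several structures (white matter, cortical gray, deep gray,
ventricles, cerebellum, brainstem) wrapped in concentric extracerebral CSF,
skull and scalp shells, embedded in background. Geometry is a jittered
superellipsoid, deliberately non-convex so the morphological closing in the
mask-derivation stage has gaps to bridge. All outputs are pure functions of
the spec (bit-identical for equal seeds).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
from scipy import ndimage

from .core import (
    ROLE_BRAIN,
    ROLE_CSF_NONVENT,
    ROLE_NONBRAIN,
    IntensityVolume,
    LabelMap,
    LabelRoles,
)

BACKGROUND = 0
# brain structure ids (role brain; ventricles are brain per the mask definition)
WHITE_MATTER = 1
CORTICAL_GRAY = 2
DEEP_GRAY = 3
VENTRICLES = 4
CEREBELLUM = 5
BRAINSTEM = 6
CSF_SHELL = 10
SKULL = 11
SCALP = 12

_BRAIN_NAMES = {
    WHITE_MATTER: "white_matter",
    CORTICAL_GRAY: "cortical_gray",
    DEEP_GRAY: "deep_gray",
    VENTRICLES: "ventricles",
    CEREBELLUM: "cerebellum",
    BRAINSTEM: "brainstem",
}


class PhantomSizingError(ValueError):
    """Grid too small to fit the requested shells around the brain."""


@dataclass(frozen=True)
class PhantomSpec:
    grid_size: int = 64
    voxel_size_mm: float = 1.0
    seed: int = 0
    n_brain_labels: int = 6
    csf_thickness_mm: float = 1.5
    skull_thickness_mm: float = 2.0
    scalp_thickness_mm: float = 2.0
    shape_jitter: float = 1.0
    # brain semi-axes in mm; None derives them from the grid size
    brain_radii_mm: Optional[Tuple[float, float, float]] = None

    def __post_init__(self):
        if self.grid_size < 16:
            raise ValueError("grid_size must be >= 16")
        for t in (self.csf_thickness_mm, self.skull_thickness_mm, self.scalp_thickness_mm):
            if t < 0:
                raise ValueError("shell thicknesses must be >= 0")
        if not 1 <= self.n_brain_labels <= 6:
            raise ValueError("n_brain_labels must be in 1..6")

    @property
    def radii_mm(self) -> np.ndarray:
        if self.brain_radii_mm is not None:
            return np.asarray(self.brain_radii_mm, dtype=float)
        ext = self.grid_size * self.voxel_size_mm
        return np.array([0.29, 0.33, 0.27]) * ext


def phantom_roles(spec: PhantomSpec) -> LabelRoles:
    table = {BACKGROUND: ("background", ROLE_NONBRAIN)}
    for lid in list(_BRAIN_NAMES)[: spec.n_brain_labels]:
        table[lid] = (_BRAIN_NAMES[lid], ROLE_BRAIN)
    if spec.csf_thickness_mm > 0:
        table[CSF_SHELL] = ("csf_extracerebral", ROLE_CSF_NONVENT)
    if spec.skull_thickness_mm > 0:
        table[SKULL] = ("skull", ROLE_NONBRAIN)
    if spec.scalp_thickness_mm > 0:
        table[SCALP] = ("scalp", ROLE_NONBRAIN)
    return LabelRoles(table)


def _smooth_field(shape, rng, control: int, sd: float) -> np.ndarray:
    """Zero-mean smooth random field from a coarse Gaussian control grid."""
    coarse = rng.normal(0.0, sd, size=(control,) * 3)
    factors = [s / control for s in shape]
    f = ndimage.zoom(coarse, factors, order=3, mode="nearest", grid_mode=True)
    return f[: shape[0], : shape[1], : shape[2]]


def _superellipsoid(coords_mm, radii_mm, power: float = 2.5) -> np.ndarray:
    """Normalized radius: <1 inside, 1 on the surface."""
    t = np.abs(coords_mm) / np.asarray(radii_mm)[:, None, None, None]
    return np.power(np.sum(np.power(t, power), axis=0), 1.0 / power)


def make_phantom_labelmap(spec: PhantomSpec) -> LabelMap:
    """Generate a nested head phantom label map.

    Shells are built outward from the brain by exact Euclidean dilation, so the
    CSF/skull/scalp layers have their requested metric thickness regardless of
    the jittered brain shape.
    """
    n = spec.grid_size
    vs = spec.voxel_size_mm
    radii = spec.radii_mm

    shells = spec.csf_thickness_mm + spec.skull_thickness_mm + spec.scalp_thickness_mm
    # the head must stay inside the field of view with a 1-voxel margin
    budget = (n / 2.0 - 1.5) * vs
    if radii.max() + spec.shape_jitter + shells > budget:
        for name, t in (
            ("scalp", spec.scalp_thickness_mm),
            ("skull", spec.skull_thickness_mm),
            ("csf", spec.csf_thickness_mm),
        ):
            if radii.max() + spec.shape_jitter + shells - t <= budget:
                raise PhantomSizingError(
                    f"grid {n} too small for the {name} shell at the requested radii"
                )
        raise PhantomSizingError(
            f"grid {n} too small for brain radii {tuple(np.round(radii, 1))} mm plus shells"
        )

    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 7001]))
    center = (n - 1) / 2.0
    idx = np.indices((n, n, n), dtype=np.float64)
    coords = (idx - center) * vs  # mm, centered

    r = _superellipsoid(coords, radii)
    if spec.shape_jitter > 0:
        jitter = _smooth_field((n, n, n), rng, control=6, sd=1.0)
        r = r + jitter * (spec.shape_jitter / radii.mean())
    brain = r <= 1.0
    brain[[0, -1], :, :] = brain[:, [0, -1], :] = brain[:, :, [0, -1]] = False

    labels = np.zeros((n, n, n), dtype=np.int32)

    # brain substructures, carved by normalized radius and position
    labels[brain] = CORTICAL_GRAY if spec.n_brain_labels >= 2 else WHITE_MATTER
    if spec.n_brain_labels >= 2:
        labels[brain & (r <= 0.80)] = WHITE_MATTER
    if spec.n_brain_labels >= 5:  # cerebellum: posterior-inferior lobe
        cb = _superellipsoid(
            coords - np.array([0.0, -0.55, -0.55])[:, None, None, None] * radii[:, None, None, None],
            radii * np.array([0.45, 0.35, 0.30]),
        )
        labels[brain & (cb <= 1.0)] = CEREBELLUM
    if spec.n_brain_labels >= 6:  # brainstem: inferior central column
        bs = _superellipsoid(
            coords - np.array([0.0, 0.0, -0.75])[:, None, None, None] * radii[:, None, None, None],
            radii * np.array([0.18, 0.18, 0.35]),
        )
        labels[brain & (bs <= 1.0)] = BRAINSTEM
    if spec.n_brain_labels >= 3:  # deep gray nuclei around the ventricles
        dg = _superellipsoid(coords, radii * 0.38)
        labels[brain & (dg <= 1.0)] = DEEP_GRAY
    if spec.n_brain_labels >= 4:  # ventricles strictly interior
        vent = _superellipsoid(
            coords, radii * np.array([0.22, 0.30, 0.18])
        )
        labels[brain & (vent <= 1.0)] = VENTRICLES

    # guarantee each declared brain label occupies >= 1 voxel on coarse grids
    ci = int(round(center))
    anchor = {
        WHITE_MATTER: (ci, ci, ci + max(1, n // 8)),
        DEEP_GRAY: (ci + max(1, n // 16), ci, ci),
        VENTRICLES: (ci, ci, ci),
        CEREBELLUM: (ci, ci - max(1, n // 6), ci - max(1, n // 8)),
        BRAINSTEM: (ci, ci, ci - max(1, n // 5)),
    }
    for lid in list(_BRAIN_NAMES)[: spec.n_brain_labels]:
        if not np.any(labels == lid):
            p = anchor.get(lid, (ci, ci, ci))
            if brain[p]:
                labels[p] = lid

    # shells by exact metric dilation of the brain
    dist_out = ndimage.distance_transform_edt(~brain, sampling=(vs,) * 3)
    t_csf = spec.csf_thickness_mm
    t_skull = t_csf + spec.skull_thickness_mm
    t_scalp = t_skull + spec.scalp_thickness_mm
    outside = ~brain
    if spec.csf_thickness_mm > 0:
        labels[outside & (dist_out <= t_csf)] = CSF_SHELL
    if spec.skull_thickness_mm > 0:
        labels[outside & (dist_out > t_csf) & (dist_out <= t_skull)] = SKULL
    if spec.scalp_thickness_mm > 0:
        labels[outside & (dist_out > t_skull) & (dist_out <= t_scalp)] = SCALP

    affine = np.diag([vs, vs, vs, 1.0])
    affine[:3, 3] = -center * vs
    return LabelMap(labels, affine, roles=phantom_roles(spec))


# fixed per-label means for "acquired-like" phantom images; t2 flips the
# gray/white ordering and brightens fluid, mirroring the contrast flip seen
# in early development
_T1_MEANS = {
    BACKGROUND: 0.0,
    WHITE_MATTER: 110.0,
    CORTICAL_GRAY: 80.0,
    DEEP_GRAY: 90.0,
    VENTRICLES: 30.0,
    CEREBELLUM: 85.0,
    BRAINSTEM: 95.0,
    CSF_SHELL: 35.0,
    SKULL: 20.0,
    SCALP: 70.0,
}
_T2_MEANS = {
    BACKGROUND: 0.0,
    WHITE_MATTER: 70.0,
    CORTICAL_GRAY: 100.0,
    DEEP_GRAY: 95.0,
    VENTRICLES: 180.0,
    CEREBELLUM: 98.0,
    BRAINSTEM: 80.0,
    CSF_SHELL: 170.0,
    SKULL: 25.0,
    SCALP: 60.0,
}
CONTRAST_MEANS = {"t1_like": _T1_MEANS, "t2_like": _T2_MEANS}


def make_phantom_image(
    labelmap: LabelMap, contrast: str, noise_sd: float, seed: int
) -> IntensityVolume:
    """Render an acquired-like image: fixed per-label means + Gaussian noise."""
    if contrast not in CONTRAST_MEANS:
        raise ValueError(f"unknown contrast {contrast!r}; use 't1_like' or 't2_like'")
    means = CONTRAST_MEANS[contrast]
    lut_size = max(means) + 1
    lut = np.zeros(lut_size, dtype=np.float32)
    for lid, m in means.items():
        lut[lid] = m
    img = lut[labelmap.data]
    if noise_sd > 0:
        rng = np.random.default_rng(np.random.SeedSequence([seed, 7002]))
        img = img + rng.normal(0.0, noise_sd, size=img.shape).astype(np.float32)
        np.maximum(img, 0.0, out=img)
    return IntensityVolume(img, labelmap.affine, meta={"contrast": contrast})
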