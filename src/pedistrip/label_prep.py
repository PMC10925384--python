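"""Whole-head training label maps from brain-only manual labels.

A manual segmentation covers the brain but says nothing about skull, scalp,
eyes, or shoulders — yet the synthesis engine needs labels *everywhere* to
generate variable non-brain content. The pipeline here: (1) remove smooth
multiplicative intensity inhomogeneity so non-brain clusters reflect tissue
rather than coil shading, (2) cluster the non-brain intensities with a
Gaussian mixture (default six components; the components carry no anatomical
meaning), (3) splice GMM pseudo-labels outside the brain with the manual
labels inside it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.mixture import GaussianMixture

from .core import (
    ROLE_NONBRAIN,
    BrainMask,
    IntensityVolume,
    LabelMap,
    WholeHeadLabelMap,
)


class DegenerateInputError(ValueError):
    pass


class ReduceComponentsError(ValueError):
    """Fewer distinct intensities than mixture components; lower n_components."""


# ---------------------------------------------------------------------------
# Non-uniformity correction


def _poly_basis(coords: np.ndarray, order: int) -> np.ndarray:
    """3D polynomial basis up to total degree `order`; coords (n, 3) in [-1, 1]."""
    cols = []
    for i in range(order + 1):
        for j in range(order + 1 - i):
            for k in range(order + 1 - i - j):
                cols.append(coords[:, 0] ** i * coords[:, 1] ** j * coords[:, 2] ** k)
    return np.stack(cols, axis=1)


def correct_nonuniformity(
    image: IntensityVolume, field_order: int = 2
) -> IntensityVolume:
    """Divide out a smooth multiplicative bias field.

    The field is estimated as a low-order 3D polynomial least-squares fit to
    the log-intensity of nonzero voxels (background zeros are excluded and
    preserved exactly). The output is rescaled so its mean over nonzero
    voxels matches the input's.
    """
    data = np.asarray(image.data, dtype=np.float64)
    nz = data > 0
    if not nz.any():
        raise DegenerateInputError("cannot correct an all-zero image")
    idx = np.argwhere(nz)
    extent = np.maximum(np.asarray(data.shape) - 1, 1)
    coords = 2.0 * idx / extent - 1.0
    basis = _poly_basis(coords, field_order)
    logi = np.log(data[nz])
    coef, *_ = np.linalg.lstsq(basis, logi, rcond=None)
    logfield = basis @ coef
    bias = np.exp(logfield - logfield.mean())  # unit geometric mean
    out = data.copy()
    out[nz] = data[nz] / bias
    out[nz] *= data[nz].mean() / out[nz].mean()
    res = IntensityVolume(out.astype(np.float32), image.affine, meta=dict(image.meta))
    res.meta["bias_coefficients"] = coef
    return res


def estimated_bias_field(image: IntensityVolume, field_order: int = 2) -> np.ndarray:
    """The multiplicative field that `correct_nonuniformity` would divide out."""
    data = np.asarray(image.data, dtype=np.float64)
    nz = data > 0
    if not nz.any():
        raise DegenerateInputError("cannot estimate a field on an all-zero image")
    idx = np.argwhere(nz)
    extent = np.maximum(np.asarray(data.shape) - 1, 1)
    basis = _poly_basis(2.0 * idx / extent - 1.0, field_order)
    coef, *_ = np.linalg.lstsq(basis, np.log(data[nz]), rcond=None)
    logfield = basis @ coef
    field = np.ones_like(data)
    field[nz] = np.exp(logfield - logfield.mean())
    return field


# ---------------------------------------------------------------------------
# GMM over non-brain intensities


@dataclass
class GMMFit:
    """EM-fitted 1D intensity mixture over the non-brain region.

    Components are canonicalized by ascending mean so ids are reproducible.
    ``responsibilities`` holds the per-voxel arg-max component (0-based) over
    the fitted region, shaped like the image, with -1 inside the brain mask.
    """

    n_components: int
    means: np.ndarray
    variances: np.ndarray
    weights: np.ndarray
    responsibilities: np.ndarray
    log_likelihood: float

    def __post_init__(self):
        if abs(self.weights.sum() - 1.0) > 1e-9:
            raise ValueError("mixture weights must sum to 1")
        if np.any(self.variances <= 0):
            raise ValueError("variances must be positive")
        if not (len(self.means) == len(self.variances) == len(self.weights) == self.n_components):
            raise ValueError("component count mismatch")


def _fit_em(values: np.ndarray, n_components: int, seed: int, max_iter: int = 200):
    gm = GaussianMixture(
        n_components=n_components,
        covariance_type="full",
        max_iter=max_iter,
        init_params="k-means++",
        random_state=int(seed) % (2**31),
        reg_covar=1e-6,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        gm.fit(values)
    return gm


def fit_gmm_nonbrain(
    image: IntensityVolume,
    brainmask: BrainMask,
    n_components: int = 6,
    seed: int = 0,
) -> GMMFit:
    """EM fit of a Gaussian mixture to intensities outside the brain mask."""
    if not image.same_grid_as(brainmask):
        raise ValueError("image and brain mask grids differ")
    outside = ~brainmask.data
    vals = np.asarray(image.data, dtype=np.float64)[outside]
    if np.unique(vals).size < n_components:
        raise ReduceComponentsError(
            f"only {np.unique(vals).size} distinct non-brain intensities; "
            f"reduce n_components below {n_components}"
        )
    gm = _fit_em(vals.reshape(-1, 1), n_components, seed)
    means = gm.means_[:, 0]
    order = np.argsort(means, kind="stable")  # canonical: ascending mean
    means = means[order]
    variances = gm.covariances_[order, 0, 0]
    weights = gm.weights_[order]

    # hard assignment: arg-max responsibility, ties to the lowest component id
    post = gm.predict_proba(vals.reshape(-1, 1))[:, order]
    hard = np.argmax(post, axis=1)

    resp = np.full(image.shape, -1, dtype=np.int32)
    resp[outside] = hard
    return GMMFit(
        n_components=n_components,
        means=means,
        variances=variances,
        weights=weights,
        responsibilities=resp,
        log_likelihood=float(gm.score(vals.reshape(-1, 1)) * vals.size),
    )


def em_log_likelihood_path(
    values: np.ndarray, n_components: int, seed: int, n_iters: int = 20
) -> np.ndarray:
    """Per-iteration training log-likelihood (lower bound) of the EM fit.

    Steps EM one iteration at a time from the same seeded initialization;
    exposed so the monotone-ascent property of EM can be checked directly.
    """
    vals = np.asarray(values, dtype=np.float64).reshape(-1, 1)
    gm = GaussianMixture(
        n_components=n_components,
        covariance_type="full",
        max_iter=1,
        init_params="k-means++",
        random_state=int(seed) % (2**31),
        reg_covar=1e-6,
        warm_start=True,
        tol=0.0,
    )
    path = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for _ in range(n_iters):
            gm.fit(vals)
            path.append(gm.lower_bound_)
    return np.asarray(path)


# ---------------------------------------------------------------------------
# Splicing


def splice_labels(
    manual: LabelMap, gmm: GMMFit, brainmask: BrainMask
) -> WholeHeadLabelMap:
    """Manual labels inside the brain, offset GMM component ids outside.

    GMM component c maps to label id ``offset + c`` with
    ``offset = max(manual ids) + 1``, keeping the two ranges disjoint.
    """
    if not manual.same_grid_as(brainmask):
        raise ValueError("manual label map and brain mask grids differ")
    if gmm.responsibilities.shape != manual.shape:
        raise ValueError("GMM responsibilities grid differs from the label map")
    manual_ids = sorted(int(v) for v in np.unique(manual.data))
    offset = max(max(manual_ids), max(manual.roles.table, default=0)) + 1
    gmm_ids = list(range(offset, offset + gmm.n_components))
    collision = set(gmm_ids) & set(manual.roles.table)
    if collision:
        raise ValueError(f"label-id collision after offsetting GMM components: {sorted(collision)}")

    inside = brainmask.data
    data = np.where(inside, manual.data, 0).astype(np.int32)
    outside = ~inside
    data[outside] = offset + np.maximum(gmm.responsibilities[outside], 0)

    provenance = np.where(
        inside, WholeHeadLabelMap.PROV_MANUAL, WholeHeadLabelMap.PROV_GMM
    ).astype(np.uint8)
    roles = manual.roles.extended(
        {lid: (f"gmm_{i}", ROLE_NONBRAIN) for i, lid in enumerate(gmm_ids)}
    )
    return WholeHeadLabelMap(
        data, manual.affine, roles=roles, provenance=provenance
    )
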