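"""Synthesis engine: spatial augmentation, intensity rendering, corruption.

Each training step turns one whole-head label map into an (image, label map)
pair. The label map is warped first (nearest-neighbor) and the image is
rendered from the warped labels, so image and labels correspond exactly by
construction. Intensities are randomized per label — a synthesized brain can
be darker than its skull one step and brighter the next — which is what
pushes the downstream network to key on shape rather than contrast.

Corruptions mimic acquisition artifacts, each firing independently with a
configured probability, in a fixed order: multiplicative bias field,
min-max normalization plus gamma exponentiation, edge cropping, block
downsampling with nearest re-upsampling, and Gaussian blurring.

Randomness: one seed sequence per (config.seed, step_seed), split into
independent streams per sub-operation by fixed stream ids, so whether one
corruption fires never changes the draws of another.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, asdict
from typing import Optional, Tuple

import numpy as np
import yaml
from scipy import ndimage

from .core import IntensityVolume, LabelMap

# fixed stream ids for RNG splitting
_S_TRANSFORM, _S_INTENSITY, _S_CORRUPT = 11, 22, 33


def _as_rng(rng_state) -> np.random.Generator:
    if isinstance(rng_state, np.random.Generator):
        return rng_state
    return np.random.default_rng(rng_state)


@dataclass
class SynthConfig:
    """Full parameterization of the generative model.

    Ranges follow the principle that training variability should exceed what
    plausible scans show. Spatial ranges are in mm / degrees on the conformed
    grid; ``desk_scale`` shrinks the metric ones proportionally for small
    test grids.
    """

    translation_range: Tuple[float, float] = (-15.0, 15.0)  # mm
    rotation_range: Tuple[float, float] = (-45.0, 45.0)  # degrees, per axis
    scale_range: Tuple[float, float] = (0.7, 1.3)
    shear_range: Tuple[float, float] = (-0.1, 0.1)
    warp_control_spacing: float = 16.0  # mm
    warp_sd: float = 3.0  # mm
    intensity_mean_range: Tuple[float, float] = (0.0, 255.0)
    intensity_sd_range: Tuple[float, float] = (1.0, 15.0)
    bias_field_sd: float = 0.3  # log-field amplitude
    bias_control_spacing: float = 32.0  # mm
    gamma_log_sd: float = 0.3
    crop_max_fraction: float = 0.2
    downsample_factors: Tuple[int, ...] = (1, 2, 4)
    blur_sigma_range: Tuple[float, float] = (0.1, 2.0)  # mm
    bias_prob: float = 0.9
    gamma_prob: float = 0.9
    crop_prob: float = 0.2
    downsample_prob: float = 0.3
    blur_prob: float = 0.9
    seed: int = 0

    def __post_init__(self):
        for name in (
            "translation_range",
            "rotation_range",
            "scale_range",
            "shear_range",
            "intensity_mean_range",
            "intensity_sd_range",
            "blur_sigma_range",
        ):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"{name} is not well-ordered: ({lo}, {hi})")
        for name in ("bias_prob", "gamma_prob", "crop_prob", "downsample_prob", "blur_prob"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if not 0.0 <= self.crop_max_fraction < 1.0:
            raise ValueError("crop_max_fraction must lie in [0, 1)")

    @classmethod
    def desk_scale(cls, grid_mm: float = 48.0, **overrides) -> "SynthConfig":
        """Preset for small fields of view and short optimization budgets.

        Metric spatial ranges shrink with the grid, and corruption rates are
        roughly halved: the full-scale rates assume optimization runs long
        enough to average over rare hard corruptions, which a few hundred
        batch-1 steps cannot. Intensity randomization — the core of the
        contrast-agnostic strategy — is unchanged.
        """
        f = grid_mm / 256.0
        base = dict(
            translation_range=(-15.0 * f * 2, 15.0 * f * 2),
            # the phantom head fills ~90% of the desk field of view (vs ~65%
            # at 256³), so upscaling beyond the remaining headroom would clip
            # the head on a large fraction of draws
            scale_range=(0.7, 1.1),
            warp_control_spacing=max(4.0, 16.0 * f * 2),
            warp_sd=3.0 * f * 4,
            bias_control_spacing=max(8.0, 32.0 * f * 2),
            crop_max_fraction=0.1,
            # factor 4 at a 48 mm field of view would leave ~4 voxels across
            # the brain; {1, 2} matches the relative resolution loss at 256³
            downsample_factors=(1, 2),
            blur_sigma_range=(0.1, 1.0),
            gamma_log_sd=0.2,
            bias_prob=0.5,
            gamma_prob=0.5,
            crop_prob=0.1,
            downsample_prob=0.2,
            blur_prob=0.5,
        )
        base.update(overrides)
        return cls(**base)

    def to_yaml(self, path=None) -> str:
        d = asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        text = yaml.safe_dump(d, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_yaml(cls, source) -> "SynthConfig":
        if hasattr(source, "read"):
            d = yaml.safe_load(source.read())
        else:
            text = str(source)
            if "\n" not in text and text.endswith((".yaml", ".yml")):
                with open(text) as fh:
                    d = yaml.safe_load(fh)
            else:
                d = yaml.safe_load(text)
        tuple_fields = {
            f.name for f in dataclasses.fields(cls) if "Tuple" in str(f.type)
        }
        for k in tuple_fields & set(d):
            d[k] = tuple(d[k])
        return cls(**d)


@dataclass
class SpatialTransform:
    """Resampling map: output voxel u -> source voxel F_inv @ (u + d(u)).

    ``affine`` stores the forward voxel-to-voxel matrix F (translation,
    rotation, scale, shear about the grid center); the smooth displacement
    ``displacement`` (3, D, H, W), in voxels, carries the nonlinear part and
    composes after the affine in the forward direction.
    """

    affine: np.ndarray
    displacement: Optional[np.ndarray] = None

    def __post_init__(self):
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-9:
            raise ValueError("affine is not invertible")
        if self.displacement is not None:
            self.displacement = np.asarray(self.displacement, dtype=np.float32)
            if not np.all(np.isfinite(self.displacement)):
                raise ValueError("displacement must be finite")

    def content_hash(self) -> str:
        import hashlib

        h = hashlib.sha256(np.ascontiguousarray(self.affine).tobytes())
        if self.displacement is not None:
            h.update(np.ascontiguousarray(self.displacement).tobytes())
        return h.hexdigest()

    def source_coordinates(self, shape) -> np.ndarray:
        """Pullback coordinates (3, D, H, W) into the source grid."""
        idx = np.indices(shape, dtype=np.float32)
        if self.displacement is not None:
            idx = idx + self.displacement
        inv = np.linalg.inv(self.affine).astype(np.float32)
        flat = idx.reshape(3, -1)
        src = inv[:3, :3] @ flat + inv[:3, 3:4]
        return src.reshape((3,) + tuple(shape))


def _rotation_matrix(angles_deg: np.ndarray) -> np.ndarray:
    ax, ay, az = np.deg2rad(angles_deg)
    cx, sx = np.cos(ax), np.sin(ax)
    cy, sy = np.cos(ay), np.sin(ay)
    cz, sz = np.cos(az), np.sin(az)
    rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    return rz @ ry @ rx


def _smooth_grid_field(shape, rng, spacing_vox: float, sd: float, n_fields: int):
    """n_fields smooth fields from coarse Gaussian control grids.

    Control values are upsampled trilinearly: continuous, with variation only
    at the control-spacing scale, and cheap enough for per-step use.
    """
    ctrl = [max(2, int(np.ceil(s / spacing_vox)) + 1) for s in shape]
    fields = np.empty((n_fields,) + tuple(shape), dtype=np.float32)
    for i in range(n_fields):
        coarse = rng.normal(0.0, sd, size=ctrl)
        f = ndimage.zoom(
            coarse,
            [s / c for s, c in zip(shape, ctrl)],
            order=1,
            mode="nearest",
            grid_mode=True,
        )
        fields[i] = f[: shape[0], : shape[1], : shape[2]]
    return fields


def sample_transform(
    config: SynthConfig, rng_state, shape=None, spacing: float = 1.0
) -> SpatialTransform:
    """Draw a random affine (uniform parameters) plus a smooth nonlinear warp.

    ``shape`` is required when ``warp_sd > 0`` so the dense displacement can
    be materialized; pass None for a purely affine draw.
    """
    rng = _as_rng(rng_state)
    t = rng.uniform(*config.translation_range, size=3) / spacing  # mm -> voxels
    angles = rng.uniform(*config.rotation_range, size=3)
    scales = rng.uniform(*config.scale_range, size=3)
    shears = rng.uniform(*config.shear_range, size=3)

    rot = _rotation_matrix(angles)
    sh = np.eye(3)
    sh[0, 1], sh[0, 2], sh[1, 2] = shears
    lin = rot @ sh @ np.diag(scales)

    affine = np.eye(4)
    affine[:3, :3] = lin
    affine[:3, 3] = t
    if shape is not None:
        center = (np.asarray(shape) - 1) / 2.0
        affine[:3, 3] += center - lin @ center  # rotate/scale about grid center

    disp = None
    if config.warp_sd > 0 and shape is not None:
        disp = _smooth_grid_field(
            tuple(shape),
            rng,
            spacing_vox=config.warp_control_spacing / spacing,
            sd=config.warp_sd / spacing,
            n_fields=3,
        )
    return SpatialTransform(affine, disp)


def apply_transform(labelmap: LabelMap, t: SpatialTransform) -> LabelMap:
    """Resample a label map through the transform (nearest-neighbor).

    Out-of-field voxels receive the background label 0; the role table is
    carried over unchanged.
    """
    src = t.source_coordinates(labelmap.shape)
    warped = ndimage.map_coordinates(
        labelmap.data, src, order=0, mode="constant", cval=0
    )
    return LabelMap(
        warped.astype(labelmap.data.dtype),
        labelmap.affine,
        roles=labelmap.roles,
        meta={"transform_hash": t.content_hash()},
    )


def synthesize_intensities(
    labelmap: LabelMap, config: SynthConfig, rng_state
) -> IntensityVolume:
    """Render a gray-scale image: one mean per label, one global noise sd."""
    rng = _as_rng(rng_state)
    present = np.unique(labelmap.data)
    lut = np.zeros(int(present.max()) + 1, dtype=np.float32)
    # one independent mean per declared label (declared order fixes the draws)
    declared = sorted(labelmap.roles.table)
    means = rng.uniform(*config.intensity_mean_range, size=len(declared))
    for lid, m in zip(declared, means):
        if lid < lut.size:
            lut[lid] = m
    sd = rng.uniform(*config.intensity_sd_range)
    img = lut[labelmap.data]
    if sd > 0:
        img = img + rng.normal(0.0, sd, size=img.shape).astype(np.float32)
    np.maximum(img, 0.0, out=img)
    return IntensityVolume(
        img,
        labelmap.affine,
        meta={"drawn_means": {int(l): float(m) for l, m in zip(declared, means)},
              "drawn_sd": float(sd)},
    )


def _minmax(img: np.ndarray) -> np.ndarray:
    lo, hi = float(img.min()), float(img.max())
    if hi - lo < 1e-12:
        return np.zeros_like(img)
    return (img - lo) / (hi - lo)


def corrupt(
    image: IntensityVolume,
    config: SynthConfig,
    rng_state,
    bias_field: Optional[np.ndarray] = None,
) -> IntensityVolume:
    """Apply randomized acquisition-like corruptions.

    Order: bias -> normalize(+gamma) -> crop -> downsample -> blur. Min-max
    normalization to [0, 1] is unconditional; the remaining stages fire with
    their configured probabilities. ``bias_field`` injects a fixed
    multiplicative field (testing hook) in place of a sampled one.
    """
    rng = _as_rng(rng_state)
    img = np.asarray(image.data, dtype=np.float32)
    if np.any(img < 0):
        raise ValueError("corrupt expects a non-negative image")
    shape = img.shape
    spacing = float(np.min(image.spacing))

    # draws happen unconditionally so firing one stage never shifts another
    fire = rng.uniform(size=5)
    log_bias_sd = config.bias_field_sd
    gamma = float(np.exp(rng.normal(0.0, config.gamma_log_sd)))
    crop_fracs = rng.uniform(0.0, config.crop_max_fraction, size=3)
    crop_sides = rng.integers(0, 2, size=3)
    ds_factor = int(rng.choice(np.asarray(config.downsample_factors)))
    blur_sigma = float(rng.uniform(*config.blur_sigma_range))
    bias_rng = np.random.default_rng(rng.integers(0, 2**31))

    if bias_field is not None:
        img = img * np.asarray(bias_field, dtype=np.float32)
    elif fire[0] < config.bias_prob and log_bias_sd > 0:
        logf = _smooth_grid_field(
            shape, bias_rng, config.bias_control_spacing / spacing, log_bias_sd, 1
        )[0]
        img = img * np.exp(logf)

    img = _minmax(img)
    if fire[1] < config.gamma_prob:
        img = np.power(img, gamma, dtype=np.float32)

    if fire[2] < config.crop_prob:
        for ax in range(3):
            k = int(round(crop_fracs[ax] * shape[ax]))
            if k == 0:
                continue
            sl = [slice(None)] * 3
            sl[ax] = slice(0, k) if crop_sides[ax] == 0 else slice(shape[ax] - k, None)
            img[tuple(sl)] = 0.0

    if fire[3] < config.downsample_prob and ds_factor > 1:
        f = ds_factor
        pad = [(0, (-s) % f) for s in shape]
        p = np.pad(img, pad, mode="edge")
        ps = p.shape
        blocks = p.reshape(ps[0] // f, f, ps[1] // f, f, ps[2] // f, f)
        small = blocks.mean(axis=(1, 3, 5))
        up = np.repeat(np.repeat(np.repeat(small, f, 0), f, 1), f, 2)
        img = up[: shape[0], : shape[1], : shape[2]].astype(np.float32)

    if fire[4] < config.blur_prob and blur_sigma > 0:
        img = ndimage.gaussian_filter(img, sigma=blur_sigma / spacing).astype(np.float32)

    np.maximum(img, 0.0, out=img)
    meta = dict(image.meta)
    meta["corrupt_gamma"] = gamma if fire[1] < config.gamma_prob else 1.0
    return IntensityVolume(img, image.affine, meta=meta)


def generate_training_pair(
    labelmap: LabelMap, config: SynthConfig, step_seed: int
) -> Tuple[IntensityVolume, LabelMap]:
    """One training sample: corrupted synthetic image + augmented label map.

    Deterministic in (labelmap, config, step_seed); image and label map share
    the same spatial transform by construction (the image is rendered from
    the warped labels).
    """
    spacing = float(np.min(np.linalg.norm(np.asarray(labelmap.affine)[:3, :3], axis=0)))
    streams = {
        k: np.random.default_rng(np.random.SeedSequence([int(config.seed), int(step_seed), k]))
        for k in (_S_TRANSFORM, _S_INTENSITY, _S_CORRUPT)
    }
    t = sample_transform(
        config, streams[_S_TRANSFORM], shape=labelmap.shape, spacing=spacing
    )
    warped = apply_transform(labelmap, t)
    img = synthesize_intensities(warped, config, streams[_S_INTENSITY])
    img = corrupt(img, config, streams[_S_CORRUPT])
    img.meta["transform_hash"] = warped.meta["transform_hash"]
    return img, warped
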