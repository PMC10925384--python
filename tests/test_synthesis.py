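import numpy as np
import pytest

from pedistrip import (
    IntensityVolume,
    SynthConfig,
    apply_transform,
    corrupt,
    generate_training_pair,
    sample_transform,
    synthesize_intensities,
)
from pedistrip.synthesis import SpatialTransform

from conftest import simple_labelmap


def identity_config(**overrides):
    """Config with every range collapsed and corruptions off."""
    base = dict(
        translation_range=(0.0, 0.0),
        rotation_range=(0.0, 0.0),
        scale_range=(1.0, 1.0),
        shear_range=(0.0, 0.0),
        warp_sd=0.0,
        intensity_mean_range=(100.0, 100.0),
        intensity_sd_range=(0.0, 0.0),
        bias_prob=0.0,
        gamma_prob=0.0,
        crop_prob=0.0,
        downsample_prob=0.0,
        blur_prob=0.0,
    )
    base.update(overrides)
    return SynthConfig(**base)


@pytest.fixture
def checker_labelmap():
    data = np.zeros((16, 16, 16), dtype=np.int32)
    data[4:12, 4:12, 4:12] = 1
    data[6:10, 6:10, 6:10] = 2
    return simple_labelmap(data, brain_ids=(1, 2))


def test_zero_width_ranges_give_identity_transform(checker_labelmap):
    t = sample_transform(identity_config(), 0, shape=(16, 16, 16))
    assert np.allclose(t.affine, np.eye(4), atol=1e-12)
    assert t.displacement is None
    out = apply_transform(checker_labelmap, t)
    assert np.array_equal(out.data, checker_labelmap.data)


def test_warp_sd_zero_is_purely_affine():
    cfg = identity_config(rotation_range=(-10.0, 10.0), warp_sd=0.0)
    t = sample_transform(cfg, 1, shape=(16, 16, 16))
    assert t.displacement is None


def test_sampled_rotations_cover_range_with_zero_mean():
    cfg = SynthConfig(rotation_range=(-45.0, 45.0))
    rng = np.random.default_rng(5)
    angles = rng.uniform(*cfg.rotation_range, size=(10_000, 3))  # distribution ref
    draws = []
    r = np.random.default_rng(5)
    for _ in range(10_000):
        draws.append(r.uniform(*cfg.rotation_range, size=3))
    draws = np.asarray(draws)
    assert draws.min() >= -45 and draws.max() <= 45
    se = (90 / np.sqrt(12)) / np.sqrt(draws.size)
    assert abs(draws.mean()) < 3 * se


def test_integer_translation_shifts_labels_exactly(checker_labelmap):
    aff = np.eye(4)
    aff[:3, 3] = [3, 0, -2]
    out = apply_transform(checker_labelmap, SpatialTransform(aff))
    expected = np.roll(np.roll(checker_labelmap.data, 3, axis=0), -2, axis=2)
    # compare away from the wrap-around border
    core = (slice(4, 12),) * 3
    assert np.array_equal(out.data[core], expected[core])
    # label counts conserved when content stays in-field
    for lid in (1, 2):
        assert (out.data == lid).sum() == (checker_labelmap.data == lid).sum()


def test_half_turn_rotation_is_an_involution(checker_labelmap):
    from pedistrip.synthesis import _rotation_matrix

    aff = np.eye(4)
    aff[:3, :3] = _rotation_matrix(np.array([180.0, 0.0, 0.0]))
    center = (np.array([16, 16, 16]) - 1) / 2.0
    aff[:3, 3] = center - aff[:3, :3] @ center
    t = SpatialTransform(aff)
    once = apply_transform(checker_labelmap, t)
    twice = apply_transform(once, t)
    assert np.array_equal(twice.data, checker_labelmap.data)


def test_non_invertible_affine_rejected():
    bad = np.eye(4)
    bad[0, 0] = 0.0
    with pytest.raises(ValueError, match="invertible"):
        SpatialTransform(bad)


def test_degenerate_sd_gives_piecewise_constant(checker_labelmap):
    cfg = identity_config(intensity_mean_range=(0.0, 255.0))
    img = synthesize_intensities(checker_labelmap, cfg, 3)
    for lid in np.unique(checker_labelmap.data):
        vals = img.data[checker_labelmap.data == lid]
        assert np.all(vals == vals.flat[0])


def test_sample_sd_within_chi_square_bound():
    data = np.zeros((24, 24, 24), dtype=np.int32)  # one big label, n > 10^4
    lm = simple_labelmap(data + 1)
    cfg = identity_config(
        intensity_mean_range=(150.0, 150.0), intensity_sd_range=(10.0, 10.0)
    )
    img = synthesize_intensities(lm, cfg, 4)
    assert 9.0 <= img.data.std() <= 11.0


def test_label_means_drawn_independently(checker_labelmap):
    cfg = identity_config(intensity_mean_range=(0.0, 255.0))
    m1, m2 = [], []
    for s in range(1000):
        img = synthesize_intensities(checker_labelmap, cfg, s)
        m1.append(img.meta["drawn_means"][1])
        m2.append(img.meta["drawn_means"][2])
    r = np.corrcoef(m1, m2)[0, 1]
    assert abs(r) < 0.1


def test_no_corruptions_is_minmax_normalization(checker_labelmap):
    lut = np.array([0.0, 120.0, 60.0], dtype=np.float32)
    img = IntensityVolume(lut[checker_labelmap.data], checker_labelmap.affine)
    out = corrupt(img, identity_config(), 6)
    lo, hi = img.data.min(), img.data.max()
    assert np.allclose(out.data, (img.data - lo) / (hi - lo), atol=1e-6)


def test_injected_bias_field_recovered_from_log_ratio(checker_labelmap):
    lut = np.array([0.0, 200.0, 40.0], dtype=np.float32)
    img = IntensityVolume(lut[checker_labelmap.data], checker_labelmap.affine)
    ramp = np.linspace(-0.4, 0.4, 16)[:, None, None] * np.ones((16, 16, 16))
    out = corrupt(
        img, identity_config(), 8, bias_field=np.exp(ramp).astype(np.float64)
    )
    nz = img.data > 0
    log_ratio = np.log(out.data[nz].astype(np.float64)) - np.log(
        img.data[nz].astype(np.float64)
    )
    # normalization adds a constant; the ramp must be reproduced mean-free
    resid = (log_ratio - log_ratio.mean()) - (ramp[nz] - ramp[nz].mean())
    assert np.max(np.abs(resid)) < 1e-6


def test_pair_is_deterministic_and_transform_shared(phantom):
    cfg = SynthConfig.desk_scale(48.0, seed=9)
    a_img, a_lab = generate_training_pair(phantom, cfg, step_seed=12)
    b_img, b_lab = generate_training_pair(phantom, cfg, step_seed=12)
    assert np.array_equal(a_img.data, b_img.data)
    assert np.array_equal(a_lab.data, b_lab.data)
    assert a_img.meta["transform_hash"] == a_lab.meta["transform_hash"]
    c_img, _ = generate_training_pair(phantom, cfg, step_seed=13)
    assert not np.array_equal(a_img.data, c_img.data)


def test_uncorrupted_pair_respects_drawn_parameters(phantom):
    """Per-label stats of the rendered image recover the drawn mean/sd."""
    cfg = identity_config(
        translation_range=(-3.0, 3.0),
        rotation_range=(-20.0, 20.0),
        intensity_mean_range=(20.0, 235.0),
        intensity_sd_range=(5.0, 5.0),
        seed=2,
    )
    from pedistrip.synthesis import apply_transform as at, sample_transform as st, synthesize_intensities as si

    t = st(cfg, 1, shape=phantom.shape)
    warped = at(phantom, t)
    img = si(warped, cfg, 2)
    sd = img.meta["drawn_sd"]
    for lid, mean in img.meta["drawn_means"].items():
        sel = warped.data == lid
        n = int(sel.sum())
        if n < 10_000 or mean < 4 * sd:  # clamping skews small means
            continue
        assert abs(img.data[sel].mean() - mean) <= 3 * sd / np.sqrt(n)
        assert abs(img.data[sel].std() - sd) <= 0.5


def test_parameter_coverage_over_200_draws():
    cfg = SynthConfig()
    rots, scales, trans = [], [], []
    for s in range(200):
        rng = np.random.default_rng(s)
        t = rng.uniform(*cfg.translation_range, size=3)
        a = rng.uniform(*cfg.rotation_range, size=3)
        sc = rng.uniform(*cfg.scale_range, size=3)
        trans.extend(t); rots.extend(a); scales.extend(sc)
    for vals, (lo, hi) in ((trans, cfg.translation_range),
                           (rots, cfg.rotation_range),
                           (scales, cfg.scale_range)):
        vals = np.asarray(vals)
        assert (vals.max() - vals.min()) / (hi - lo) >= 0.9


def test_no_nans_under_default_config(phantom):
    cfg = SynthConfig.desk_scale(48.0, seed=21)
    for s in range(30):
        img, lab = generate_training_pair(phantom, cfg, step_seed=s)
        assert np.all(np.isfinite(img.data))
        assert img.data.min() >= 0


def test_synth_config_yaml_roundtrip(tmp_path):
    cfg = SynthConfig.desk_scale(48.0, seed=3)
    p = tmp_path / "synth.yaml"
    cfg.to_yaml(p)
    assert SynthConfig.from_yaml(str(p)) == cfg
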