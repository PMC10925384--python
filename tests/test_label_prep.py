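import numpy as np
import pytest

from pedistrip import (
    BrainMask,
    IntensityVolume,
    correct_nonuniformity,
    fit_gmm_nonbrain,
    splice_labels,
)
from pedistrip.label_prep import (
    DegenerateInputError,
    ReduceComponentsError,
    em_log_likelihood_path,
    estimated_bias_field,
)

from conftest import simple_labelmap


def test_uniform_image_passes_through():
    img = IntensityVolume(np.full((12, 12, 12), 80.0), np.eye(4))
    out = correct_nonuniformity(img)
    assert np.allclose(out.data, img.data, rtol=1e-6)


def test_known_linear_ramp_field_is_recovered(phantom):
    from pedistrip import make_phantom_image

    img = make_phantom_image(phantom, "t1_like", noise_sd=0.0, seed=1)
    ramp = np.exp(np.linspace(-0.3, 0.3, 48))[:, None, None] * np.ones(img.shape)
    biased = IntensityVolume(img.data * ramp, img.affine)
    nz = biased.data > 0
    # a first-order model cannot absorb the phantom's radial anatomy, so the
    # fit isolates the injected linear ramp
    est = estimated_bias_field(biased, field_order=1)
    r = np.corrcoef(est[nz], ramp[nz])[0, 1]
    assert r > 0.95
    # corrected image is closer to the unbiased one than the biased image was
    corrected = correct_nonuniformity(biased, field_order=1)
    err_before = np.abs(biased.data[nz] - img.data[nz]).mean()
    err_after = np.abs(corrected.data[nz] - img.data[nz]).mean()
    assert err_after < 0.5 * err_before


def test_zero_background_preserved_exactly(phantom):
    from pedistrip import make_phantom_image

    img = make_phantom_image(phantom, "t2_like", noise_sd=0.0, seed=2)
    out = correct_nonuniformity(img)
    assert np.all(out.data[img.data == 0] == 0)
    assert np.all(out.data[img.data > 0] > 0)


def test_mean_intensity_preserved(phantom):
    from pedistrip import make_phantom_image

    img = make_phantom_image(phantom, "t1_like", noise_sd=0.0, seed=3)
    out = correct_nonuniformity(img)
    nz = img.data > 0
    assert out.data[nz].mean() == pytest.approx(img.data[nz].mean(), rel=1e-5)


def test_all_zero_image_rejected():
    with pytest.raises(DegenerateInputError):
        correct_nonuniformity(IntensityVolume(np.zeros((8, 8, 8)), np.eye(4)))


def _two_population_fixture(mu=(40.0, 160.0), sd=(5.0, 8.0), seed=0):
    rng = np.random.default_rng(seed)
    n = 16
    data = np.zeros((n, n, n), dtype=np.float32)
    brain = np.zeros((n, n, n), dtype=bool)
    brain[5:11, 5:11, 5:11] = True
    outside = ~brain
    half = int(outside.sum()) // 2
    vals = np.concatenate(
        [rng.normal(mu[0], sd[0], half), rng.normal(mu[1], sd[1], int(outside.sum()) - half)]
    )
    data[outside] = rng.permutation(vals).astype(np.float32)
    img = IntensityVolume(data, np.eye(4))
    return img, BrainMask(brain, np.eye(4))


def test_two_component_means_recovered_within_two_percent():
    img, brain = _two_population_fixture()
    fit = fit_gmm_nonbrain(img, brain, n_components=2, seed=1)
    assert fit.means[0] == pytest.approx(40.0, rel=0.02)
    assert fit.means[1] == pytest.approx(160.0, rel=0.02)
    assert fit.means[0] < fit.means[1]  # canonical ascending order


def test_default_component_count_is_six(phantom):
    from pedistrip import make_phantom_image

    img = make_phantom_image(phantom, "t1_like", noise_sd=3.0, seed=4)
    brain = BrainMask(phantom.brain_union(), phantom.affine)
    fit = fit_gmm_nonbrain(img, brain, seed=2)
    assert fit.n_components == 6
    assert fit.weights.sum() == pytest.approx(1.0, abs=1e-9)
    assert np.all(fit.variances > 0)


def test_constant_nonbrain_single_component():
    data = np.full((10, 10, 10), 7.0, dtype=np.float32)
    brain = np.zeros((10, 10, 10), dtype=bool)
    brain[3:7, 3:7, 3:7] = True
    fit = fit_gmm_nonbrain(
        IntensityVolume(data, np.eye(4)), BrainMask(brain, np.eye(4)),
        n_components=1, seed=0,
    )
    assert fit.means[0] == pytest.approx(7.0, abs=1e-6)
    assert fit.variances[0] <= 1e-5  # at the regularization floor


def test_too_few_distinct_values_raises():
    data = np.zeros((8, 8, 8), dtype=np.float32)
    data[::2] = 1.0
    brain = np.zeros((8, 8, 8), dtype=bool)
    with pytest.raises(ReduceComponentsError, match="reduce"):
        fit_gmm_nonbrain(IntensityVolume(data, np.eye(4)), BrainMask(brain, np.eye(4)),
                         n_components=6, seed=0)


def test_gmm_fit_is_deterministic():
    img, brain = _two_population_fixture(seed=3)
    a = fit_gmm_nonbrain(img, brain, n_components=3, seed=7)
    b = fit_gmm_nonbrain(img, brain, n_components=3, seed=7)
    assert np.array_equal(a.responsibilities, b.responsibilities)
    assert np.allclose(a.means, b.means)


def test_em_log_likelihood_nondecreasing():
    img, brain = _two_population_fixture(seed=5)
    vals = img.data[~brain.data]
    path = em_log_likelihood_path(vals, n_components=3, seed=1, n_iters=15)
    assert np.all(np.diff(path) >= -1e-8)


def _splice_fixture(phantom):
    from pedistrip import make_phantom_image

    manual = simple_labelmap(
        np.where(phantom.brain_union(), phantom.data, 0),
        brain_ids=(1, 2, 3, 4, 5, 6),
        affine=phantom.affine,
    )
    img = make_phantom_image(phantom, "t1_like", noise_sd=3.0, seed=6)
    brain = BrainMask(phantom.brain_union(), phantom.affine)
    gmm = fit_gmm_nonbrain(img, brain, n_components=4, seed=3)
    return manual, gmm, brain


def test_splice_partitions_the_grid(phantom):
    manual, gmm, brain = _splice_fixture(phantom)
    spliced = splice_labels(manual, gmm, brain)
    counts = {int(l): int(c) for l, c in zip(*np.unique(spliced.data, return_counts=True))}
    assert sum(counts.values()) == 48**3
    assert np.all(spliced.data[brain.data] == manual.data[brain.data])
    assert np.all(spliced.provenance[brain.data] == spliced.PROV_MANUAL)
    assert np.all(spliced.provenance[~brain.data] == spliced.PROV_GMM)
    # spliced GMM labels are role nonbrain and disjoint from manual ids
    gmm_ids = [l for l, (n, r) in spliced.roles.table.items() if n.startswith("gmm_")]
    assert all(spliced.roles.table[l][1] == "nonbrain" for l in gmm_ids)
    assert not set(gmm_ids) & set(manual.roles.table)


def test_splice_empty_and_full_masks(phantom):
    manual, gmm, _ = _splice_fixture(phantom)
    empty = BrainMask(np.zeros(phantom.shape, dtype=bool), phantom.affine)
    out = splice_labels(manual, gmm, empty)
    offset = min(l for l, (n, _) in out.roles.table.items() if n.startswith("gmm_"))
    assert np.array_equal(out.data, offset + np.maximum(gmm.responsibilities, 0))
    full = BrainMask(np.ones(phantom.shape, dtype=bool), phantom.affine)
    out2 = splice_labels(manual, gmm, full)
    assert np.array_equal(out2.data, manual.data)


def test_splice_is_idempotent(phantom):
    manual, gmm, brain = _splice_fixture(phantom)
    a = splice_labels(manual, gmm, brain)
    b = splice_labels(manual, gmm, brain)
    assert np.array_equal(a.data, b.data)
    assert np.array_equal(a.provenance, b.provenance)
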