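import numpy as np
import pytest

from pedistrip import (
    BrainMask,
    LabelMap,
    LabelRoles,
    PhantomSpec,
    make_phantom_labelmap,
)
from pedistrip.core import ROLE_BRAIN, ROLE_CSF_NONVENT, ROLE_NONBRAIN


@pytest.fixture(scope="session")
def phantom_spec():
    return PhantomSpec(grid_size=48, seed=1)


@pytest.fixture(scope="session")
def phantom(phantom_spec):
    return make_phantom_labelmap(phantom_spec)


@pytest.fixture(scope="session")
def small_phantom():
    return make_phantom_labelmap(
        PhantomSpec(
            grid_size=32,
            seed=2,
            csf_thickness_mm=1.0,
            skull_thickness_mm=1.5,
            scalp_thickness_mm=1.5,
            shape_jitter=0.5,
            brain_radii_mm=(8.0, 9.0, 7.5),
        )
    )


def cube_mask(n, lo, hi, spacing=1.0):
    m = np.zeros((n, n, n), dtype=bool)
    m[lo:hi, lo:hi, lo:hi] = True
    return BrainMask(m, np.diag([spacing, spacing, spacing, 1.0]))


def simple_labelmap(data, brain_ids=(1,), csf_ids=(), spacing=1.0, affine=None):
    data = np.asarray(data, dtype=np.int32)
    table = {0: ("background", ROLE_NONBRAIN)}
    for i in brain_ids:
        table[int(i)] = (f"brain_{i}", ROLE_BRAIN)
    for i in csf_ids:
        table[int(i)] = (f"csf_{i}", ROLE_CSF_NONVENT)
    for i in np.unique(data):
        if int(i) not in table:
            table[int(i)] = (f"other_{i}", ROLE_NONBRAIN)
    if affine is None:
        affine = np.diag([spacing, spacing, spacing, 1.0])
    return LabelMap(data, affine, roles=LabelRoles(table))


def random_blob_mask(rng, n, n_blobs=3):
    """Union of a few random boxes/balls: irregular but structured test masks."""
    m = np.zeros((n, n, n), dtype=bool)
    idx = np.indices((n, n, n))
    for _ in range(n_blobs):
        if rng.random() < 0.5:
            c = rng.integers(2, n - 2, size=3)
            r = rng.integers(2, max(3, n // 3))
            m |= ((idx - c[:, None, None, None]) ** 2).sum(axis=0) <= r**2
        else:
            lo = rng.integers(0, n - 3, size=3)
            hi = lo + rng.integers(2, n // 2 + 1, size=3)
            m[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] = True
    return m
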