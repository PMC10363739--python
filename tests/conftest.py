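"""Shared fixtures: small deterministic phantoms and geometric primitives."""

from __future__ import annotations

import numpy as np
import pytest

from cmbkit.imaging import BrainMask, Volume
from cmbkit.phantom import PhantomSpec, generate_subject


def make_ball(shape, center, radius, spacing=(1.0, 1.0, 1.0)):
    """Binary digital ball: voxels whose mm distance to center <= radius."""
    grids = np.meshgrid(
        *[np.arange(n) * s for n, s in zip(shape, spacing)], indexing="ij"
    )
    c_mm = [ci * si for ci, si in zip(center, spacing)]
    d = np.sqrt(sum((g - c) ** 2 for g, c in zip(grids, c_mm)))
    return (d <= radius).astype(np.uint8)


def make_tube(shape, axis=0, through=None, radius=1.0, spacing=(1.0, 1.0, 1.0)):
    """Binary straight tube along ``axis`` passing through ``through``."""
    through = through or tuple(n // 2 for n in shape)
    grids = np.meshgrid(
        *[np.arange(n) * s for n, s in zip(shape, spacing)], indexing="ij"
    )
    others = [a for a in range(3) if a != axis]
    d = np.sqrt(
        sum((grids[a] - through[a] * spacing[a]) ** 2 for a in others)
    )
    return (d <= radius).astype(np.uint8)


@pytest.fixture(scope="session")
def swi_phantom():
    """One deterministic SWI phantom subject (64^3, 1 mm isotropic)."""
    return generate_subject(PhantomSpec(seed=11))


@pytest.fixture(scope="session")
def qsm_phantom():
    return generate_subject(PhantomSpec(seed=12, modality="QSM"))


@pytest.fixture(scope="session")
def gre_phantom():
    return generate_subject(PhantomSpec(seed=13, modality="T2*GRE"))


@pytest.fixture()
def small_volume():
    rng = np.random.default_rng(3)
    data = rng.random((20, 22, 24)).astype(np.float32) * 100
    return Volume(data=data, spacing=(1.0, 1.0, 1.0))


@pytest.fixture()
def small_mask(small_volume):
    m = np.zeros(small_volume.shape, dtype=np.uint8)
    m[3:17, 4:19, 5:20] = 1
    return BrainMask(data=m, spacing=small_volume.spacing)
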