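"""Shared fixtures: small deterministic phantoms and masks."""

import numpy as np
import pytest

from perturbrad import (ImageVolume, PhantomConfig, ROIMask, make_ct_phantom,
                        make_roi_masks)


@pytest.fixture(scope="session")
def small_config():
    return PhantomConfig(shape=(48, 48, 8), seed=7)


@pytest.fixture(scope="session")
def ct_volume(small_config):
    return make_ct_phantom(small_config)


@pytest.fixture(scope="session")
def roi_masks(small_config):
    return make_roi_masks(small_config)


@pytest.fixture(scope="session")
def ctv_mask(roi_masks):
    return roi_masks[0]


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


@pytest.fixture()
def random_volume(rng):
    """32^3 random volume on the anisotropic planning-CT grid."""
    return ImageVolume(rng.normal(size=(32, 32, 32)), spacing=(0.98, 0.98, 5.0))


def make_ellipsoid_mask(shape, center, semi, spacing=(0.98, 0.98, 5.0),
                        name="ROI"):
    grids = np.meshgrid(*[np.arange(n) for n in shape], indexing="ij")
    ell = sum(((g - c) / s) ** 2 for g, c, s in zip(grids, center, semi)) <= 1.0
    return ROIMask(voxels=ell.astype(np.uint8), spacing=spacing, roi_name=name)
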