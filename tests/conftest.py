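"""Shared fixtures: all test data is generated in memory."""

import numpy as np
import pytest

from gincseg import (
    ModelParams,
    REFERENCE_BIAS_COEFFS,
    build_basis,
    make_phantom,
    make_scene,
    standard_phantom,
)


@pytest.fixture(scope="session")
def basis64():
    return build_basis((64, 64), order=4)


@pytest.fixture(scope="session")
def basis128():
    return build_basis((128, 128), order=4)


@pytest.fixture(scope="session")
def phantom_sigma5():
    """Standard fixture: 128x128, disc on background, C=(60,140), sigma=5."""
    return standard_phantom(noise_sigma=5.0, seed=1)


@pytest.fixture(scope="session")
def phantom_noiseless():
    return standard_phantom(noise_sigma=0.0, seed=1)


@pytest.fixture(scope="session")
def small_phantom():
    """Cheap 64x64 two-class phantom for fast solver tests."""
    labels = make_scene((64, 64), 2, "discs", seed=3)
    return make_phantom(labels, np.array([60.0, 140.0]),
                        REFERENCE_BIAS_COEFFS, noise_sigma=3.0, seed=3)


@pytest.fixture
def default_params():
    return ModelParams()
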