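import numpy as np
import pytest

from wmpipeline.phantom import (
    BiomarkerTable,
    make_label_phantom,
    synthesize_parametric,
    synthesize_structural,
)

SMALL_SHAPE = (48, 48, 48)
ISO2 = (2.0, 2.0, 2.0)


@pytest.fixture(scope="session")
def labels_score2():
    return make_label_phantom(SMALL_SHAPE, ISO2, target_score=2, seed=11)


@pytest.fixture(scope="session")
def labels_score3():
    return make_label_phantom(SMALL_SHAPE, ISO2, target_score=3, seed=11)


@pytest.fixture(scope="session")
def clean_structural(labels_score2):
    """Zero-noise structural volumes: piecewise-constant images of the labels."""
    return synthesize_structural(labels_score2, seed=1, noise_scale=0.0)


@pytest.fixture(scope="session")
def noisy_structural(labels_score2):
    return synthesize_structural(labels_score2, seed=1, noise_scale=1.0)


@pytest.fixture(scope="session")
def clean_parametric(labels_score2):
    return synthesize_parametric(labels_score2, BiomarkerTable(), penumbra=None,
                                 seed=2, noise_scale=0.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
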