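"""Shared fixtures: phantom suites and trained cascade models.

Session scope keeps the expensive integration-scale training to a single
run shared by the pipeline, cascade and acceptance tests.
"""

from __future__ import annotations

import warnings

import numpy as np
import pytest

from organelleseg.synthetic import make_fixture_suite
from organelleseg.training import TrainingSet, split_train_test
from organelleseg.chm import train_chm, apply_chm


@pytest.fixture(scope="session")
def unit_suite():
    return make_fixture_suite("unit", seed=7)


@pytest.fixture(scope="session")
def integration_suite():
    return make_fixture_suite("integration", seed=7)


@pytest.fixture(scope="session")
def unit_split(unit_suite):
    tset = TrainingSet(unit_suite["images"], unit_suite["labels"]["textured"],
                       organelle_tag="textured")
    return split_train_test(tset, 7, rng_seed=1)


@pytest.fixture(scope="session")
def unit_model(unit_split):
    train, _ = unit_split
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return train_chm(train, S=2, L=2, rng_seed=7)


@pytest.fixture(scope="session")
def integration_split(integration_suite):
    tset = TrainingSet(integration_suite["images"],
                       integration_suite["labels"]["textured"],
                       organelle_tag="textured")
    return split_train_test(tset, 40, rng_seed=1)


@pytest.fixture(scope="session")
def integration_model(integration_split):
    train, _ = integration_split
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return train_chm(train, S=2, L=2, rng_seed=7)


@pytest.fixture(scope="session")
def integration_heldout_maps(integration_model, integration_split):
    """Raw (unnormalized) cascade output maps for the held-out tiles."""
    _, test = integration_split
    return np.stack([np.asarray(apply_chm(integration_model, img).values)
                     for img in test.images])


@pytest.fixture(scope="session")
def blob_probability_map():
    """Multimodal fixture map: a strong plateau blob (~0.9) and a weak
    distractor blob (~0.4) over near-zero background."""
    from scipy import ndimage
    yy, xx = np.mgrid[0:80, 0:80]
    m = np.zeros((80, 80))
    m[np.hypot(yy - 25, xx - 25) <= 10] = 0.9
    m[np.hypot(yy - 60, xx - 60) <= 8] = 0.4
    m = ndimage.gaussian_filter(m, 1.5)
    return np.clip(m / m.max(), 0, 1)
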