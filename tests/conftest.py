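"""Shared fixtures: synthetic datasets, grid populations, trained models.

Expensive objects (440x440 rate-map banks, rendered datasets, trained
stores) are session-scoped; tests must not mutate them.
"""

import numpy as np
import pytest

import gridsaccade as gs


@pytest.fixture(scope="session")
def pop():
    """Default 5-module, 125-cell population over the canonical map."""
    return gs.build_population(seed=1)


@pytest.fixture(scope="session")
def small_pop():
    """Small map for fast grid-code unit tests."""
    specs = gs.default_module_specs(n_modules=3, base_period=14.0,
                                    cells_per_module=12, seed=3)
    return gs.build_population(specs, map_size=128, seed=3)


@pytest.fixture(scope="session")
def dataset():
    """10 identities x 3 medium probes, the default study conditions."""
    return gs.make_dataset(n_identities=10, n_variants=3,
                           difficulty="medium", seed=1)


@pytest.fixture(scope="session")
def trained(dataset, pop):
    """(store, descriptors) one-shot-trained on the dataset gallery."""
    return gs.train_model(dataset.gallery, pop, fovea_size=101, seed=1)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
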