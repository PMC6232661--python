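import numpy as np
import pytest

from hfacsbn.network import (
    BayesianNetworkModel,
    build_hfacs_structure,
    build_variable_catalog,
    random_cpts,
    uniform_cpts,
)
from hfacsbn.simulate import GeneratorConfig, make_ground_truth, make_study


@pytest.fixture(scope="session")
def catalog():
    return build_variable_catalog()


@pytest.fixture(scope="session")
def structure(catalog):
    return build_hfacs_structure(catalog)


@pytest.fixture(scope="session")
def uniform_model(structure):
    return BayesianNetworkModel(structure, uniform_cpts(structure))


@pytest.fixture
def random_model(structure):
    """Factory: a seeded random-CPT model over the HFACS structure."""

    def make(seed: int) -> BayesianNetworkModel:
        return BayesianNetworkModel(
            structure, random_cpts(structure, np.random.default_rng(seed))
        )

    return make


@pytest.fixture(scope="session")
def ground_truth():
    """The calibrated default generating model (deterministic)."""
    return make_ground_truth(GeneratorConfig())


@pytest.fixture(scope="session")
def default_study():
    """(train, test, ground truth, quality report) at the default 408/14 design."""
    return make_study(GeneratorConfig())
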