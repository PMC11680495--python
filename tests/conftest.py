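import numpy as np
import pytest

from densefc.atlas import toy_labels
from densefc.datasets import CohortParams, generate_behavior, generate_connectomes
from densefc.edge_models import build_observation_table


@pytest.fixture(scope="session")
def toy_params():
    """Small null cohort: 6 subjects × 4 sessions × 3 conditions, 9 nodes."""
    return CohortParams(
        n_subjects=6, n_sessions=4, node_labels=toy_labels(), seed=11, null_mode=True
    )


@pytest.fixture(scope="session")
def toy_behavior(toy_params):
    return generate_behavior(toy_params)


@pytest.fixture(scope="session")
def toy_dataset(toy_params, toy_behavior):
    conns, truth = generate_connectomes(toy_params, toy_behavior)
    return conns, truth


@pytest.fixture(scope="session")
def toy_table(toy_dataset, toy_behavior):
    conns, _ = toy_dataset
    return build_observation_table(conns, toy_behavior)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
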