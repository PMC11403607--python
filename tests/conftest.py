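import numpy as np
import pytest

from brewomics import preprocessing, synthetic_data
from brewomics.synthetic_data import GeneratorConfig


@pytest.fixture(scope="session")
def small_experiment():
    """A reduced synthetic experiment shared by unit tests (fast to build)."""
    cfg = GeneratorConfig(seed=42, n_features=400, n_t_markers=20, n_k_markers=20)
    return synthetic_data.generate_experiment(cfg)


@pytest.fixture(scope="session")
def small_group_matrix(small_experiment):
    return preprocessing.build_group_matrix(
        small_experiment.peaklists, small_experiment.metadata
    )


@pytest.fixture(scope="session")
def small_sample_matrix(small_experiment):
    return preprocessing.build_sample_matrix(
        small_experiment.peaklists, small_experiment.metadata
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
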