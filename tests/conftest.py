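import numpy as np
import pytest

from ensemblemage import hog
from ensemblemage.directives import generate_ensemble
from ensemblemage.synth import (
    SyntheticConfig,
    build_truth_model,
    generate_fitting_dataset,
    generate_noise_free_dataset,
)


@pytest.fixture(scope="session")
def master():
    return hog.build_master()


@pytest.fixture(scope="session")
def ensemble(master):
    """All 12 generated candidates as {name: (model, provenance)}."""
    results, errors = generate_ensemble(master, hog.candidate_specs())
    assert not errors, errors
    return {m.name: (m, rec) for m, rec in results}


@pytest.fixture(scope="session")
def candidate_models(ensemble):
    return {name: m for name, (m, _rec) in ensemble.items()}


@pytest.fixture(scope="session")
def truth_model():
    return build_truth_model()


@pytest.fixture(scope="session")
def fitting_data():
    return generate_fitting_dataset(SyntheticConfig(seed=1))


@pytest.fixture(scope="session")
def noise_free_data():
    return generate_noise_free_dataset()


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20110330)
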