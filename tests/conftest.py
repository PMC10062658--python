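import numpy as np
import pytest

from pthpulse import (
    ActivityCoefficients,
    KineticParameters,
    load_config,
    load_scenarios,
)


@pytest.fixture(scope="session")
def config():
    return load_config()


@pytest.fixture(scope="session")
def registry():
    return load_scenarios()


@pytest.fixture(scope="session")
def params(config):
    """Detailed-balance kinetics used throughout the model."""
    return config.params


@pytest.fixture(scope="session")
def printed_params():
    """Kinetics with the literature value of the inactive-complex constant."""
    return KineticParameters.from_dissociation_constants(detailed_balance=False)


@pytest.fixture(scope="session")
def coeffs(params):
    """Exact-adaptation activity weights at unit scale."""
    return ActivityCoefficients.exact_adaptation(1.0, 0.0, 0.0, params)


@pytest.fixture()
def rng():
    return np.random.default_rng(20230330)
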