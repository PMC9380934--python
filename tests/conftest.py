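import numpy as np
import pytest

from aba_cea import default_parameters
from aba_cea.calibration import Variant, apply_variant


@pytest.fixture(scope="session")
def params():
    """Packaged default configuration (spec defaults)."""
    return default_parameters()


@pytest.fixture(scope="session")
def best_params():
    """Defaults under the calibration-selected conventions (24-month
    comparator cost window, annual-step discounting, IQ frozen in the
    utility equation)."""
    return apply_variant(default_parameters(), Variant(24, "annual", False))


@pytest.fixture()
def fresh_params():
    """A mutable copy for tests that tweak settings."""
    return default_parameters()


@pytest.fixture(scope="session")
def independence_model():
    """Independence model fitted once to the configured simulated records."""
    from aba_cea.pipeline import independence_model_from_config

    return independence_model_from_config(default_parameters())


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20230816)
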