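import numpy as np
import pytest

from oxyrelax import FitConfig, ModelParameters, load_table1, resample_fit

#: Published calibration constants (median and 95% CI) the pipeline is
#: expected to reproduce on the bundled dataset, 1e-4 s^-1/mmHg scale.
PUBLISHED_FIT = {
    "c1": (4.87, 4.70, 5.04),
    "c2": (1.99, 1.59, 2.38),
    "c3": (0.844, 0.452, 1.24),
    "c_temp": (0.0323, 0.0211, 0.0434),
}

PUBLISHED_MEDIANS = ModelParameters(4.87, 1.99, 0.844, 0.0323)


@pytest.fixture(scope="session")
def table1():
    return load_table1()


@pytest.fixture(scope="session")
def table1_printed():
    return load_table1(corrected=False)


@pytest.fixture(scope="session")
def ensemble(table1):
    """The full 1000-iteration resampled fit, shared across tests."""
    return resample_fit(table1, FitConfig(n_iterations=1000, master_seed=42))


@pytest.fixture(scope="session")
def medians(ensemble):
    return ensemble.medians
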