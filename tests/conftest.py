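import numpy as np
import pytest

from hzclines import ClineModel, FitConfig, ZoneConfig, generate_bin_table


@pytest.fixture(scope="session")
def model_i():
    return ClineModel("I", center=0.0, width=2000.0, pmin=0.1, pmax=0.9)


@pytest.fixture(scope="session")
def bin_distances():
    return np.linspace(-5000.0, 5000.0, 19)


@pytest.fixture(scope="session")
def freq_table(model_i, bin_distances):
    return generate_bin_table(model_i, bin_distances, [40] * 19, seed=42)


@pytest.fixture()
def light_config():
    """Short chains for unit tests; recovery tests set their own sizes."""
    return FitConfig(n_chains=2, n_steps=3000, burn_in=500, seed=0)


@pytest.fixture(scope="session")
def small_zone_config():
    return ZoneConfig(n_trees=300, n_snps=20, seed=7)
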