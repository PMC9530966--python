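import pytest

from ttemu import (DGPConfig, DiscreteDGPConfig,
                   enumerate_observational_cohort, simulate_cohort)


@pytest.fixture(scope="session")
def dconfig():
    """Reference discrete replica: binary severity, horizon 3."""
    return DiscreteDGPConfig()


@pytest.fixture(scope="session")
def pop_cohort(dconfig):
    """Exactly weighted population cohort of the discrete process."""
    return enumerate_observational_cohort(dconfig)


@pytest.fixture(scope="session")
def small_cohort():
    """A small observational cohort under the default study conditions."""
    return simulate_cohort(DGPConfig(n_patients=600, seed=42))
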