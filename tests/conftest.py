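import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_dataset():
    """A 20-trap, 2-year synthetic study shared across read-only tests."""
    from rootworm.synthetic_data import SyntheticConfig, simulate_dataset

    return simulate_dataset(SyntheticConfig(n_traps=20, years=(2004, 2005), seed=3))


@pytest.fixture(scope="session")
def small_fit(small_dataset):
    """A short MCMC fit of the small study (mixing-quality tests excluded)."""
    from rootworm.model import MCMCSettings, ModelSpec, sample
    from rootworm.synthetic_data import to_model_data

    spec = ModelSpec()
    data = to_model_data(small_dataset, spec)
    settings_ = MCMCSettings(n_iter=800, burn_in=400, thin=2, n_chains=2, seed=5)
    return data, sample(data, spec, settings_)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
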