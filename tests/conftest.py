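import numpy as np
import pytest

from driftwatch.datamodel import MonitorConfig
from driftwatch.synthetic import GeneratorConfig, make_reference, simulate_stream


def small_generator(seed: int = 123, **overrides) -> GeneratorConfig:
    """Desk-scale generator used across tests: 6 features, 20 days."""
    defaults = dict(
        n_features_continuous=4,
        n_features_binary=2,
        n_reference=300,
        calls_per_day=60,
        n_days=20,
        n_risk_continuous=2,
        n_risk_binary=1,
        risk_coefficients=(0.9, -0.6, 0.8),
        seed=seed,
    )
    defaults.update(overrides)
    return GeneratorConfig(**defaults)


@pytest.fixture(scope="session")
def small_cfg():
    return small_generator()


@pytest.fixture(scope="session")
def reference(small_cfg):
    return make_reference(small_cfg)


@pytest.fixture(scope="session")
def null_stream(small_cfg):
    return simulate_stream(small_cfg)


@pytest.fixture()
def monitor_cfg():
    return MonitorConfig(n_permutations=300, seed=5)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
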