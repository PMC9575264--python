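import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from negsel import SyntheticConfig, generate, kr_nssm

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def default_dataset():
    """One default-configuration synthetic dataset (60 x 40, 3 blocks)."""
    return generate(SyntheticConfig(seed=0))


@pytest.fixture(scope="session")
def default_run(default_dataset):
    """Pipeline result on the default dataset, shared across tests."""
    assoc, simM, simD, truth = default_dataset
    return kr_nssm(assoc, simM, simD), truth


def random_screen_instance(rng: np.random.Generator):
    """A small random (P, U) instance for oracle-equivalence checks.

    At most 20 samples in at most 5 dimensions; mostly non-negative
    similarity-like profiles, occasionally centred noise.
    """
    dim = int(rng.integers(2, 6))
    n_pos = int(rng.integers(1, 6))
    n_unl = int(rng.integers(4, 16))
    if rng.random() < 0.7:
        P = rng.random((n_pos, dim))
        U = rng.random((n_unl, dim))
    else:
        P = rng.normal(0.5, 1.0, (n_pos, dim))
        U = rng.normal(-0.5, 1.0, (n_unl, dim))
    return P, U
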