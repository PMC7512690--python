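import numpy as np
import pytest

from phimip import ARModel, NetworkSpec, generate_network, joint_gaussian


def random_model(n: int, seed: int, kind: str = "normal", sigma: float = 0.1) -> ARModel:
    """Random stationary AR model from the benchmark ensembles."""
    return generate_network(NetworkSpec(kind=kind, n=n, sigma=sigma, seed=seed))


@pytest.fixture(scope="session")
def small_joint():
    """A fixed 6-element stationary joint Gaussian."""
    return joint_gaussian(random_model(6, seed=42))


@pytest.fixture(scope="session")
def block_model_8():
    """8-element block model: two decoupled 4-element subsystems."""
    return random_model(8, seed=7, kind="block")


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
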