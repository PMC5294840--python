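import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_sim1():
    """A small length-biased Poisson dataset shared by pipeline tests."""
    from seqgsa.synthetic import Sim1Design, generate_sim1

    return generate_sim1(
        Sim1Design(n_genes=200, n_sets=10, set_size=20, beta=0.15, n_de=2, seed=7)
    )
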