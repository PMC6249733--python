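import numpy as np
import pytest

from sidemc import Hyperparameters, generate_problem


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def tiny_problem():
    """20x20 problem with 3 features per side, 30% missing, mild noise."""
    return generate_problem("I", 30, seed=7, dims=dict(m=20, n=20, d1=3, d2=3))


@pytest.fixture
def tiny_noiseless_problem():
    return generate_problem(
        "I", 30, seed=7, dims=dict(m=20, n=20, d1=3, d2=3), noise_std=0.0
    )


@pytest.fixture
def fast_hp():
    return Hyperparameters(lambda_E=1e-2, lambda_G=1e-2, max_iter=60, seed=11)
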