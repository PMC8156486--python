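import numpy as np
import pytest

from catkinetics import generative as G


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def reaction_model():
    """Two-substrate / two-product model with alpha = 1/4."""
    return G.two_substrate_two_product_model(0.25)


@pytest.fixture
def enzyme_model():
    return G.enzymatic_model(0.8, 0.8)


@pytest.fixture
def chain():
    return G.chain_model()
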