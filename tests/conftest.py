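import numpy as np
import pytest

import ireplan as ir


@pytest.fixture(scope="session")
def small_domain():
    return ir.make_domain(7.5, 32)


@pytest.fixture(scope="session")
def tiny_domain():
    return ir.make_domain(7.5, 16)


@pytest.fixture(scope="session")
def square_electrodes():
    return ir.place_electrode_grid(4, 1.8, 1.5)


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)
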