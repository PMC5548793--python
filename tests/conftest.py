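import numpy as np
import pytest

import tfspec
from tfspec import chain


@pytest.fixture(scope="session")
def baseline():
    """Baseline parameters: L=5, eps=3, n_G=2, Ns=25."""
    return tfspec.ModelParams()


@pytest.fixture(scope="session")
def baseline_space(baseline):
    return tfspec.enumerate_states(baseline)


@pytest.fixture(scope="session")
def baseline_chain(baseline, baseline_space):
    return chain.build_chain(baseline, baseline_space)


@pytest.fixture(scope="session")
def tiny():
    """Smallest full-enumeration-checkable model: L=2, one gene."""
    return tfspec.ModelParams(L=2, n_G=1)


@pytest.fixture(scope="session")
def tiny_space(tiny):
    return tfspec.enumerate_states(tiny)


@pytest.fixture(scope="session")
def tiny_chain(tiny, tiny_space):
    return chain.build_chain(tiny, tiny_space)


@pytest.fixture(scope="session")
def small():
    """L=3 with both genes; big enough for nontrivial macrostate dynamics."""
    return tfspec.ModelParams(L=3, n_G=2)


@pytest.fixture(scope="session")
def small_space(small):
    return tfspec.enumerate_states(small)


@pytest.fixture(scope="session")
def small_chain(small, small_space):
    return chain.build_chain(small, small_space)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
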