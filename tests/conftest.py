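import numpy as np
import pytest

from hissbrn.brn import MCMCOptions
from hissbrn.design import build_design
from hissbrn.simulate import ReactionNormParams, simulate_brn


@pytest.fixture(scope="session")
def paper_design():
    return build_design(104, "paper", seed=11)


@pytest.fixture(scope="session")
def table1_params():
    return ReactionNormParams()


@pytest.fixture(scope="session")
def paper_trials(paper_design, table1_params):
    return simulate_brn(paper_design, table1_params, seed=101)


@pytest.fixture
def short_mcmc():
    """Chain settings for fast unit-test fits."""
    return MCMCOptions(n_iter=1_500, burn_in=300, thin=3)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
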