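import numpy as np
import pytest

from cardioavatar import literature_parameters, simulate, extract_periodic_cycle
from cardioavatar.estimation import FitConfig
from cardioavatar.initialization import build_initial_parameters
from cardioavatar.synthetic import make_virtual_subject


@pytest.fixture(scope="session")
def lit_params():
    return literature_parameters()


@pytest.fixture(scope="session")
def lit_sim(lit_params):
    """Reference 20 s / 1 ms simulation of the literature parameter set."""
    return simulate(lit_params, duration=20.0, dt=1e-3)


@pytest.fixture(scope="session")
def lit_cycle(lit_params, lit_sim):
    return extract_periodic_cycle(lit_sim, lit_params.T)


@pytest.fixture(scope="session")
def fast_cfg():
    """Scaled-down solver settings for optimizer-in-the-loop tests."""
    return FitConfig(dt=2e-3, duration=10.0)


@pytest.fixture(scope="session")
def noisefree_subject():
    """Noise-free virtual subject used by several estimation tests."""
    return make_virtual_subject(seed=3, jitter=0.10, noise_sd=0.0)


@pytest.fixture(scope="session")
def noisefree_init(noisefree_subject):
    return build_initial_parameters(noisefree_subject.meas)
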