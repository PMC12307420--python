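import copy

import pytest

from pupilsim import build_pupil_network


@pytest.fixture(scope="session")
def base_network():
    """One shared default pupil network; tests copy it before mutating."""
    return build_pupil_network()


@pytest.fixture()
def pupil_network(base_network):
    """A private, freshly reset copy of the default pupil network."""
    net = copy.deepcopy(base_network)
    net.reset(full=True)
    return net
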