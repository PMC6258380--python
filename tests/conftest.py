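import numpy as np
import pytest

from oscbind.params import StimulusProtocol, StimulusPulse, preset
from oscbind.model import simulate


@pytest.fixture(scope="session")
def default_params():
    return preset("paper-default")


@pytest.fixture(scope="session")
def so_trajectory(default_params):
    """One population ignited at the default parameter set, settled."""
    proto = StimulusProtocol((StimulusPulse(0, 2.0, 20.0, 100.0),))
    return simulate(default_params, proto, t_end=1300.0)


@pytest.fixture(scope="session")
def op2_trajectory(default_params):
    """Two populations loaded out of phase."""
    proto = StimulusProtocol((StimulusPulse(0, 2.0, 20.0, 100.0),
                              StimulusPulse(1, 2.0, 20.0, 625.0)))
    return simulate(default_params, proto, t_end=2000.0)


@pytest.fixture(scope="session")
def limit_cycle(default_params):
    from oscbind.weak_coupling import compute_limit_cycle
    return compute_limit_cycle(default_params)


@pytest.fixture(scope="session")
def adjoint(limit_cycle, default_params):
    from oscbind.weak_coupling import compute_adjoint
    return compute_adjoint(limit_cycle, default_params)
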