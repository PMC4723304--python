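import numpy as np
import pytest

import vascrad as vr


@pytest.fixture(scope="session")
def params():
    return vr.default_parameters()


@pytest.fixture(scope="session")
def config(params):
    return vr.AutomatonConfig.from_params(params)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def _relaxed_state_master(params):
    """Quasi-steady healthy tissue around a central vessel on a small
    domain (session-cached; tests receive copies)."""
    pattern = vr.VesselPattern(N=21, coords=np.array([[10, 10]]))
    state = vr.TissueState.from_pattern(pattern, fill="healthy")
    m = vr.build_consumption(state, params)
    vr.relax_to_quasi_steady(state, m, params)
    return state


@pytest.fixture()
def relaxed_state(_relaxed_state_master):
    return _relaxed_state_master.copy()
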