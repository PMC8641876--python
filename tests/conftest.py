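import numpy as np
import pytest

import yaptaz as yz

SWEEP_RANGE = (-0.012, 0.03)
SWEEP_STEPS = 300


@pytest.fixture(scope="session")
def std():
    return yz.standard_parameters()


@pytest.fixture(scope="session")
def std_diagram(std):
    """Standard one-parameter bifurcation diagram (shared across tests)."""
    return yz.sweep_bifurcation(std, sweep_range=SWEEP_RANGE, steps=SWEEP_STEPS)


@pytest.fixture(scope="session")
def std_sns(std_diagram):
    return std_diagram.saddle_nodes


@pytest.fixture(scope="session")
def sensitivity_records(std, std_sns):
    """Full +/-15% scan (expensive; computed once per session)."""
    from yaptaz.sensitivity import scan_all

    return scan_all(std, fraction=0.15, sweep_range=SWEEP_RANGE, steps=250,
                    baseline=std_sns)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260924)
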