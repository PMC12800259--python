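import numpy as np
import pytest

from hairbundle import (CouplingConfig, EfferentDrive, StimulusProtocol,
                        default_params, simulate_bundles)

FS = 500.0


@pytest.fixture(scope="session")
def fs():
    return FS


@pytest.fixture(scope="session")
def free_running_cell():
    """One noisy oscillatory bundle (20 Hz target), 10 s at 500 fps."""
    p = default_params(1, seed=2)
    c = CouplingConfig.uniform(1, k=0.0, attached=[False])
    out = simulate_bundles(p, c, EfferentDrive(), fs=FS, duration=10,
                           seed=2, protocol=StimulusProtocol(10, 0, 0))
    return out.traces[0]


@pytest.fixture(scope="session")
def coupled_ensemble():
    """Six plate-coupled bundles plus membrane, 10 s, no drive."""
    p = default_params(6, seed=4)
    c = CouplingConfig.uniform(6, k=0.35)
    return simulate_bundles(p, c, EfferentDrive(), fs=FS, duration=10,
                            seed=4, protocol=StimulusProtocol(10, 0, 0))


@pytest.fixture(scope="session")
def step_protocol_run():
    """Full 10/10/10 s protocol with a 150 uA step on a mixed ensemble."""
    par = default_params(8, seed=7)
    att = [True] * 6 + [False] * 2
    cpl = CouplingConfig.uniform(8, k=0.35, attached=att)
    drv = EfferentDrive(kind="step", intensity=150.0)
    return simulate_bundles(par, cpl, drv, fs=FS, duration=30, seed=7)
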