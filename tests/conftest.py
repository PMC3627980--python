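import numpy as np
import pytest

from phaseloop import network as net


@pytest.fixture(scope="session")
def tiny_config():
    """Down-scaled single-area network for fast structural tests."""
    return net.NetworkConfig(N_E=80, N_I=20)


@pytest.fixture(scope="session")
def tiny_run(tiny_config):
    return net.simulate(tiny_config, 1000.0)


@pytest.fixture(scope="session")
def reference_run():
    """Scaled reference network (N_E=400, N_I=100), >= 500 cycles; shared
    across spectral, waveform-phase and synchrony tests."""
    cfg = net.NetworkConfig()
    res = net.simulate(cfg, 13500.0)
    return cfg, res


def reference_lfp(res, settle=500.0):
    keep = res.t_lfp > settle
    return res.lfp[0][keep]
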