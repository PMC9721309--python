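import numpy as np
import pytest

from seizprop import (NetworkConfig, PerturbationParams, build_network,
                      run_simulation, RecordSpec)


@pytest.fixture(scope="session")
def fixture_network():
    """100-neuron network with full-scale mean in-degrees (p scaled x100)."""
    cfg = NetworkConfig(N_total=100, p_default=0.5, p_ie=0.5, p_ii=0.5,
                        connectivity_seed=11, drive_seed=12)
    return build_network(cfg)


@pytest.fixture(scope="session")
def basal_result(fixture_network):
    """500 ms basal-drive run on the 100-neuron fixture."""
    pert = PerturbationParams(alpha=0.0)
    return run_simulation(fixture_network, pert, duration=500.0, dt=0.1,
                          drive_seed=12,
                          record=RecordSpec(vm_populations=("RS", "FS")))


@pytest.fixture(scope="session")
def desk_network():
    """Desk-scale network (N=2000, probabilities x5, in-degrees preserved)."""
    cfg = NetworkConfig(connectivity_seed=1).desk_scaled(5)
    return build_network(cfg)
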