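import pytest

from snailo2.colburn_transport import TransportParams, run_transport
from snailo2.constants import DEFAULT_CONSTANTS
from snailo2.hemodynamics import solve_network_flow
from snailo2.vein_geometry import build_network


@pytest.fixture(scope="session")
def constants():
    return DEFAULT_CONSTANTS


@pytest.fixture(scope="session")
def network():
    """Calibrated default vein network (53.9 mm2 at fraction 0.5)."""
    return build_network()


@pytest.fixture(scope="session")
def flow(network):
    """Laminar network flow at the default outlet velocity 0.0035 m/s."""
    return solve_network_flow(network)


@pytest.fixture(scope="session")
def transport_params():
    return TransportParams()


@pytest.fixture(scope="session")
def transport_result(network, transport_params, flow):
    """Full default transport march (37 capillaries + main vein)."""
    return run_transport(network, transport_params, flow=flow)
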