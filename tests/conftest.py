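import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import redoxsim as rx
from redoxsim import antioxidant as ax
from redoxsim import ros as rs

settings.register_profile(
    "ci", deadline=None, derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def ros_network():
    return rs.build_ros_network()


@pytest.fixture(scope="session")
def aged_ros_network():
    return rs.apply_aging_condition(rs.build_ros_network(), 2.0)


@pytest.fixture(scope="session")
def antiox_network():
    return ax.build_antioxidant_network()


@pytest.fixture(scope="session")
def aged_control_state(aged_ros_network):
    """Steady state of the aged (two-fold NOX) zero-dose ROS model."""
    result = rx.integrate(aged_ros_network)
    reached, state = rx.detect_steady_state(result)
    assert reached
    return state


@pytest.fixture(scope="session")
def antiox_control_state(antiox_network):
    result = rx.integrate(antiox_network)
    reached, state = rx.detect_steady_state(result)
    assert reached
    return state


def random_states(network, n, seed, scale=100.0):
    rng = np.random.default_rng(seed)
    return rng.uniform(0.0, scale, size=(n, len(network.species)))
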