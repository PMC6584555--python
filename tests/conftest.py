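import numpy as np
import pytest

import plateletuq as pq


@pytest.fixture(scope="session")
def nobili():
    return pq.builtin_parameters("nobili")


@pytest.fixture(scope="session")
def soares():
    return pq.builtin_parameters("soares")


@pytest.fixture(scope="session")
def consolo():
    return pq.builtin_parameters("consolo")


@pytest.fixture(scope="session")
def const_500():
    """Constant τ = 500 dyn/cm² (50 Pa) for 1 s."""
    return pq.generate_uniform_stress(500.0, 0.0, duration=1.0, dt=1e-4)


@pytest.fixture(scope="session")
def const_2kpa():
    return pq.generate_uniform_stress(2e4, 0.0, duration=1.0, dt=1e-4)


@pytest.fixture(scope="session")
def const_15kpa():
    return pq.generate_uniform_stress(1.5e5, 0.0, duration=1.0, dt=1e-4)


@pytest.fixture(scope="session")
def oscillating_50pa():
    """50 Pa mean with 10% oscillation at 50 Hz, the benchmark signal."""
    return pq.generate_uniform_stress(500.0, 0.1, freq=50.0, duration=1.0, dt=1e-4)


@pytest.fixture()
def shear_tensor():
    """Pure-shear tensor history: τ_xy = 100, all else 0."""
    times = np.linspace(0, 1, 11)
    comp = np.zeros((11, 6))
    comp[:, 3] = 100.0
    return pq.TensorStressHistory(times, comp)
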