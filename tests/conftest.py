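import numpy as np
import pytest

from spatialsfs.params import PopulationParams, SamplingKernel


@pytest.fixture
def pop_reference() -> PopulationParams:
    """Human-scale reference parameters (sigma=10, rho=20, mu=1e-9, L=1000)."""
    return PopulationParams(sigma=10.0, rho=20.0, mu=1e-9, s=0.01, L=1000.0)


@pytest.fixture
def pop_desk() -> PopulationParams:
    """Desk-scale simulation parameters (short lifetimes, small habitat)."""
    return PopulationParams(sigma=2.0, rho=20.0, mu=1e-9, s=0.1, L=1000.0)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture
def gaussian_kernel() -> SamplingKernel:
    return SamplingKernel.gaussian(width=50.0, center=(500.0, 500.0))


@pytest.fixture
def uniform_kernel() -> SamplingKernel:
    return SamplingKernel.uniform()
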