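import numpy as np
import pytest

from timefuse import ExperimentConfig, KernelSpec


@pytest.fixture(scope="session")
def kernel() -> KernelSpec:
    """Natural-statistics kernel: lambda = 0.01 /s, sigma = 0.1."""
    return KernelSpec()


@pytest.fixture(scope="session")
def fast_kernel() -> KernelSpec:
    """Short-correlation kernel for tests that need mixing within seconds."""
    return KernelSpec(decay_rate=1.0)


@pytest.fixture(scope="session")
def config() -> ExperimentConfig:
    return ExperimentConfig()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(0)
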