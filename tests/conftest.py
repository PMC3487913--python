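import numpy as np
import pytest

from rnmf import RegularizerSpec, SolverConfig, generate


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def default_instance():
    """The standard planted instance used across solver tests."""
    return generate(60, 40, 4, alpha=1.0, planted_sparsity=0.5, noise_sd=0.05, seed=0)


@pytest.fixture(scope="session")
def noiseless_instance():
    return generate(60, 40, 4, alpha=1.0, planted_sparsity=0.5, noise_sd=0.0, seed=0)


@pytest.fixture
def small_config():
    return SolverConfig(k=4, alpha=1.0, seed=0)


def l1_reg(lam):
    return RegularizerSpec("l1", lam)
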