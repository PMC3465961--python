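import numpy as np
import pytest

from odornet import SimulationConfig, simulate_codon_pair


@pytest.fixture(scope="session")
def small_pairs():
    """A handful of simulated codon pairs reused across estimator tests."""
    return [simulate_codon_pair(SimulationConfig(
        length_codons=300, kappa=2.0, omega_true=0.2, branch_length=0.3,
        seed=seed)) for seed in range(8)]


@pytest.fixture
def rng():
    return np.random.default_rng(20120928)
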