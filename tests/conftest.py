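import numpy as np
import pytest

from evasig.datasets import PhenotypeVector
from evasig.simulate import SimulationConfig, generate_dataset


@pytest.fixture(scope="session")
def default_config() -> SimulationConfig:
    """The reference planted-signature study conditions."""
    return SimulationConfig(
        n_probes=1000,
        n_samples=300,
        frac_high_stage=5 / 6,
        n_signature_probes=20,
        frac_signature_carriers=0.4,
        signature_shift=2.0,
        baseline_mean=6.0,
        noise_sd=1.0,
        seed=1,
    )


@pytest.fixture(scope="session")
def planted(default_config):
    """One planted dataset under the reference conditions."""
    return generate_dataset(default_config)


def random_phenotype(M: int, N: int, rng: np.random.Generator) -> PhenotypeVector:
    """Phenotype with exactly N low-stage samples in random positions."""
    high = np.ones(M, dtype=bool)
    high[rng.choice(M, N, replace=False)] = False
    return PhenotypeVector([f"s{i:04d}" for i in range(M)], high)
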