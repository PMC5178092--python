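import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import bnm

settings.register_profile(
    "deterministic",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_genotypes():
    """Two small chromosomes with moderate linkage and a little missingness."""
    return bnm.simulate_genotypes(
        n_subjects=40,
        n_chromosomes=2,
        markers_per_chromosome=20,
        cm_length=40.0,
        missing_rate=0.05,
        seed=7,
    )


@pytest.fixture
def tiny_phenotype(tiny_genotypes):
    y, truth = bnm.simulate_phenotypes(tiny_genotypes, seed=8)
    return y, truth
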