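import numpy as np
import pytest

from hympred.grm import build_grm
from hympred.simdata import SimConfig, TraitArchitecture, simulate


def small_config(seed: int = 11, **overrides) -> SimConfig:
    """A fast two-generation cohort for structural tests."""
    defaults = dict(
        n_snps=300,
        n_females_sampled=(100, 100),
        hosts_per_generation=20,
        n_burnin_generations=25,
        ne=60,
        n_founder_haplotypes=60,
        traits=(TraitArchitecture("t", h2_target=0.25, host_variance_fraction=0.30),),
        seed=seed,
    )
    defaults.update(overrides)
    return SimConfig(**defaults)


@pytest.fixture(scope="session")
def small_sim():
    return simulate(small_config())


@pytest.fixture(scope="session")
def small_grm(small_sim):
    return build_grm(small_sim.genotypes)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
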