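import numpy as np
import pytest

from bchromcnv import SimConfig, run_cohort
from bchromcnv.simulate import PopulationSpec

# A scaled-down cohort shared across tests: same structure as the default
# study (three populations, GC bias on, 7x) on a 400 kb genome so the whole
# suite stays fast.
SMALL_CONFIG = SimConfig(
    seed=7,
    genome_length=400_000,
    control_fragment_length=80_000,
    n_b_fragments=10,
)


@pytest.fixture(scope="session")
def small_cohort():
    return run_cohort(SMALL_CONFIG, keep_windows=True)


@pytest.fixture(scope="session")
def diploid_config():
    """All copy numbers degenerate at 2: every genome is the plain diploid
    reference."""
    return SimConfig(
        seed=11,
        genome_length=300_000,
        control_fragment_length=60_000,
        n_b_fragments=5,
        populations=(PopulationSpec("pop", 2, (2,), (1.0,)),),
    )


def rng(seed: int = 0) -> np.random.Generator:
    return np.random.default_rng(seed)
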