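import numpy as np
import pytest

from crisprpam import (
    P42S_REPEAT,
    P42S_TERMINAL_REPEAT,
    RepeatSpec,
    SimulationConfig,
    simulate_cohort,
)

BASES = "ACGT"


def random_dna(rng: np.random.Generator, n: int, p=None) -> str:
    return "".join(rng.choice(list(BASES), size=n, p=p))


@pytest.fixture(scope="session")
def repeat_spec() -> RepeatSpec:
    return RepeatSpec(P42S_REPEAT)


@pytest.fixture(scope="session")
def terminal_repeat() -> str:
    return P42S_TERMINAL_REPEAT


@pytest.fixture(scope="session")
def small_cohort():
    """A small default-parameter cohort shared across read-only tests."""
    config = SimulationConfig(seed=7, n_bims=60, genome_length=8000)
    return config, simulate_cohort(config)


@pytest.fixture(scope="session")
def clean_cohort():
    """Mismatch-free, phage-only cohort: diffing must recover truth exactly."""
    config = SimulationConfig(
        seed=11, n_bims=60, genome_length=8000, mismatch_rate=0.0, non_phage_rate=0.0
    )
    return config, simulate_cohort(config)
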