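import numpy as np
import pytest

from ghatpy.datatypes import GenotypeMatrix
from ghatpy.sim import SimConfig, simulate_pair


def tiny_config(**overrides) -> SimConfig:
    """A miniature study used by the unit tests: 2 chromosomes, fast."""
    base = dict(n_chrom=2, chrom_length_cm=100.0, n_hist_generations=40,
                hist_n=60, n_breeding_generations=20, n=80, h2=0.5,
                n_qtl=20, n_markers=200, seed=42)
    base.update(overrides)
    return SimConfig(**base)


@pytest.fixture(scope="session")
def tiny_pair():
    """Seed-paired unselected/selected miniature populations."""
    return simulate_pair(tiny_config())


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_genotypes(rng):
    """60 samples x 30 markers with two time-point groups, no missing."""
    dos = rng.integers(0, 3, size=(60, 30)).astype(float)
    group = np.repeat(["early", "late"], 30)
    return GenotypeMatrix(samples=[f"s{i}" for i in range(60)],
                          markers=[f"m{j}" for j in range(30)],
                          dosages=dos, group=group)
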