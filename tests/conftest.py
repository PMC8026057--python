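import numpy as np
import pandas as pd
import pytest

from driftld.config import SimConfig
from driftld.simcore import simulate_expansion


def tiny_config(**kw) -> SimConfig:
    """Small, fast simulation layout shared across unit tests."""
    defaults = dict(
        n_demes=3, core_size=30, founder_size=4,
        generations_between_foundings=10, burn_in_generations=120,
        genome_length=11_002, n_genes=2, gene_length=2_000,
        intergenic_length=2_334,
        seed=0,
    )
    defaults.update(kw)
    return SimConfig(**defaults)


@pytest.fixture(scope="session")
def tiny_pop():
    return simulate_expansion(tiny_config())


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_pair_counts(rng, n_tables=1000, max_count=40) -> pd.DataFrame:
    counts = rng.integers(0, max_count, size=(n_tables, 4))
    counts[counts.sum(axis=1) == 0, 0] = 1
    return pd.DataFrame(counts, columns=["n11", "n12", "n21", "n22"]).assign(
        pop="p1", scaffold="s1",
        pos1=np.arange(n_tables) + 1,
        pos2=np.arange(n_tables) + 100,
    )
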