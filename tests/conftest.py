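import numpy as np
import pandas as pd
import pytest

from prandialreg.config import SimulationConfig
from prandialreg import simulate as sim


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    return SimulationConfig(seed=11, n_genes=600, n_dhs=800)


@pytest.fixture(scope="session")
def cohort(small_config):
    """One simulated cohort shared across tests (read-only)."""
    return sim.simulate_all(small_config, include_hormone_arms=True, include_obese=True)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def random_peak_df(rng, n, chroms=("chr1", "chr2"), span=10_000, max_len=300):
    starts = rng.integers(0, span, size=n)
    lengths = rng.integers(1, max_len, size=n)
    return pd.DataFrame({
        "chrom": rng.choice(chroms, size=n),
        "start": starts,
        "end": starts + lengths,
        "name": [f"p{i}" for i in range(n)],
        "score": 0.0,
        "strand": ".",
    })
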