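import numpy as np
import pandas as pd
import pytest

from neighbordep.config import SyntheticConfig
from neighbordep.synthetic import assign_percentiles, generate_births, generate_population


@pytest.fixture(scope="session")
def small_config() -> SyntheticConfig:
    return SyntheticConfig(seed=1, n_persons=2_000, n_mothers=300, grid_extent=25)


@pytest.fixture(scope="session")
def small_population(small_config) -> pd.DataFrame:
    pop = generate_population(small_config)
    assign_percentiles(pop)
    return pop


@pytest.fixture(scope="session")
def birth_cohort() -> pd.DataFrame:
    """Mid-size cohort for outcome and effect tests (seeded, generated once)."""
    cfg = SyntheticConfig(seed=11, n_persons=25_000, n_mothers=5_000, grid_extent=45)
    pop = generate_population(cfg)
    return generate_births(pop, cfg)


def random_person_table(rng: np.random.Generator, extent: int, n: int) -> pd.DataFrame:
    """Uniform random gridded population with arbitrary percentiles."""
    return pd.DataFrame(
        {
            "person_id": np.arange(n),
            "square_e": rng.integers(0, extent, n),
            "square_n": rng.integers(0, extent, n),
            "equiv_income": rng.lognormal(12, 0.5, n),
            "income_percentile": rng.integers(1, 101, n),
        }
    )
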