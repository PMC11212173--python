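import numpy as np
import pandas as pd
import pytest

from mcpr import coding
from mcpr.simulate import SimulationConfig, generate_population


@pytest.fixture(scope="session")
def small_population() -> pd.DataFrame:
    """A 20-district, 60-women/district synthetic population."""
    cfg = SimulationConfig(n_districts=20, women_per_district=60, seed=101)
    return generate_population(cfg)


@pytest.fixture(scope="session")
def coded_records(small_population) -> pd.DataFrame:
    analytic = coding.apply_sample_filter(small_population)
    coded = coding.code_records(analytic)
    summary = coding.aggregate_community(coded)
    return coding.attach_community(coded, summary)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(0)
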