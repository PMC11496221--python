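import numpy as np
import pandas as pd
import pytest

from epiaging import (MethylationClock, SimulationConfig, epigenetic_aging,
                      generate_cohort)


@pytest.fixture(scope="session")
def default_sim():
    """Default synthetic cohort: 539 subjects, ~1.9 waves each, 400 sites."""
    cfg = SimulationConfig(seed=7)
    cohort, meth, truth = generate_cohort(cfg)
    return cfg, cohort, meth, truth


@pytest.fixture(scope="session")
def clock_results(default_sim):
    _, cohort, meth, _ = default_sim
    return MethylationClock(meth, cohort, k=10).fit(seed=7)


@pytest.fixture(scope="session")
def aging_series(default_sim, clock_results):
    _, cohort, _, _ = default_sim
    return epigenetic_aging(cohort, clock_results.dnam_age)


def perfect_clock_dnam(cohort: pd.DataFrame, truth) -> pd.Series:
    """DNAm age of an error-free clock: chronological age plus the
    generator's latent deviation."""
    return pd.Series(cohort["age"].to_numpy() + truth.deviation,
                     index=cohort["assessment_id"].to_numpy())
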