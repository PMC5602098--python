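import numpy as np
import pytest

from rescover.config import GeneratorConfig
from rescover.survey import simulate_survey


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def default_survey():
    """The default 197-household / 314-plot synthetic survey."""
    return simulate_survey(GeneratorConfig(seed=11))


@pytest.fixture(scope="session")
def large_survey_records():
    """10,000 plots with household covariates merged (for LPM power checks)."""
    conf = GeneratorConfig(n_households=5000, n_plots=10_000,
                           n_m5=6000, n_m6=8000, seed=7)
    plots, households = simulate_survey(conf)
    return plots.merge(households.drop(columns=["ea_id"]), on="household_id")
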