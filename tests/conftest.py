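import numpy as np
import pandas as pd
import pytest

from tempodisc import CountryAnchor, PopulationConfig, sample_population, simulate_study
from tempodisc.agents import InjectionRates


@pytest.fixture
def us_anchor():
    return CountryAnchor("US", "USD", 500.0)


@pytest.fixture
def demo_anchors():
    return [
        CountryAnchor("AA", "AAD", 500.0, gini=0.30, log_gdp_pc=10.5, inflation_rate=3.0),
        CountryAnchor("BB", "BBD", 2000.0, gini=0.45, log_gdp_pc=9.0, inflation_rate=12.0),
        CountryAnchor("CC", "CCD", 800.0, gini=0.38, log_gdp_pc=9.8, inflation_rate=6.0),
    ]


@pytest.fixture
def small_study(demo_anchors):
    """A small clean simulated study: (responses, truth, anchors)."""
    config = PopulationConfig(n_per_country=80, injection=InjectionRates.none())
    rng = np.random.default_rng(42)
    population = sample_population(config, demo_anchors, rng)
    responses, truth = simulate_study(population, rng, config.injection)
    return responses, truth, demo_anchors


def anchors_frame(anchors) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "country_id": [a.country_id for a in anchors],
            "gini": [a.gini for a in anchors],
            "log_gdp_pc": [a.log_gdp_pc for a in anchors],
            "inflation_rate": [a.inflation_rate for a in anchors],
        }
    )
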