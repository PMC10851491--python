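import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from redlinex import crossover, geography, heat
from redlinex.synthetic_data import (
    SimConfig,
    gen_bg_panel,
    gen_cases,
    gen_geography,
    redlined_flags,
)

settings.register_profile(
    "default",
    max_examples=25,
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def sim_config() -> SimConfig:
    return SimConfig(seed=7, years=(2001, 2002), n_cases=3000)


@pytest.fixture(scope="session")
def city(sim_config):
    return gen_geography(sim_config)


@pytest.fixture(scope="session")
def redlined(sim_config, city) -> pd.Series:
    return redlined_flags(sim_config, city)


@pytest.fixture(scope="session")
def panel(sim_config, redlined) -> pd.DataFrame:
    return gen_bg_panel(sim_config, redlined)


@pytest.fixture(scope="session")
def heat_calendar(panel) -> pd.DataFrame:
    cal, _ = heat.build_heat_calendar(panel, 95)
    return cal


@pytest.fixture(scope="session")
def crosswalk(city) -> pd.DataFrame:
    bins = geography.bin_population(city.blocks, city.holc)
    return geography.assign_grades(bins, 0.9)


@pytest.fixture(scope="session")
def strata_set(sim_config, city, panel, heat_calendar, crosswalk, redlined):
    """Case-crossover strata from one simulated study."""
    records = gen_cases(sim_config, panel, heat_calendar, redlined)
    bg_pop = (
        city.blocks.assign(geoid12=city.blocks["geoid15"].str[:12])
        .groupby("geoid12")["population"]
        .sum()
    )
    kept, _ = crossover.apply_exclusions(
        records,
        bg_pop,
        pd.Timestamp("2001-01-05").date(),
        pd.Timestamp("2002-12-31").date(),
    )
    strata, _ = crossover.build_strata(kept, panel, heat_calendar, crosswalk)
    return strata


def make_rng(seed: int) -> np.random.Generator:
    return np.random.default_rng(seed)
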