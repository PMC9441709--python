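"""Shared fixtures: one small synthetic city reused across the suite.

Session scope keeps the geospatial work (city build, feature extraction,
minute simulation) to a single pass; tests must not mutate these objects.
"""

import numpy as np
import pandas as pd
import pytest

from noiselur import acoustics
from noiselur.features import extract_features
from noiselur.synthetic_city import (
    CityConfig,
    TruthModel,
    generate_city,
    place_sites,
    simulate_minute_levels,
    sites_frame,
)

SMALL_CITY_CONFIG = CityConfig(
    extent_m=(1500.0, 1500.0),
    n_eas=20,
    n_minor_roads=25,
    n_buildings=250,
)


@pytest.fixture(scope="session")
def small_city():
    return generate_city(SMALL_CITY_CONFIG, seed=101)


@pytest.fixture(scope="session")
def small_sites(small_city):
    return place_sites(small_city, n_rotating=40, n_fixed=4, seed=102)


@pytest.fixture(scope="session")
def small_fm(small_city, small_sites):
    return extract_features(sites_frame(small_sites), small_city).standardize()


@pytest.fixture(scope="session")
def small_minutes(small_city, small_sites, small_fm):
    return simulate_minute_levels(
        small_city,
        small_sites,
        TruthModel(),
        days_per_site={"rotating": 2, "fixed": 3},
        seed=103,
        features=small_fm.values(),
    )


@pytest.fixture(scope="session")
def small_hourly(small_minutes):
    return acoustics.hourly_levels(small_minutes)


def minute_frame(levels, start="2020-01-06 00:00", site_id="S000"):
    """Helper: long minute table from a plain level sequence."""
    ts = pd.Timestamp(start) + pd.to_timedelta(np.arange(len(levels)), unit="min")
    return pd.DataFrame(
        {"site_id": site_id, "timestamp": ts, "laeq_1min_dba": np.asarray(levels, float)}
    )
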