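import numpy as np
import pandas as pd
import pytest

from heatcase.core_io import CityDaySeries
from heatcase.exposure import panel_to_percentiles
from heatcase.synthetic_data import (
    GeneratorConfig,
    TrueExposureResponse,
    gen_city_temperatures,
    gen_deaths,
    gen_death_records,
)


def make_series(city_id="c1", n_days=30, start="2018-01-01", temps=None,
                deaths=None, **extra_cols):
    idx = pd.date_range(start, periods=n_days, freq="D", name="date")
    rng = np.random.default_rng(abs(hash(city_id)) % (2**31))
    data = pd.DataFrame(index=idx)
    data["temp_c"] = temps if temps is not None else rng.normal(20, 5, n_days)
    if deaths is not None:
        data["deaths"] = deaths
    for col, vals in extra_cols.items():
        data[col] = vals
    return CityDaySeries(city_id, data)


@pytest.fixture(scope="session")
def small_config():
    return GeneratorConfig(n_cities=3, n_days=730, seed=11)


@pytest.fixture(scope="session")
def small_panel(small_config):
    """3-city, 2-year panel with a strong planted effect."""
    truth = TrueExposureResponse(anchors=((50.0, 1.3), (99.0, 1.6)))
    cfg = GeneratorConfig(n_cities=3, n_days=730, seed=11,
                          baseline_deaths_per_day=1.5)
    panel = panel_to_percentiles(gen_city_temperatures(cfg))
    return gen_deaths(panel, truth, cfg), truth, cfg


@pytest.fixture(scope="session")
def small_records(small_panel):
    panel, truth, cfg = small_panel
    return gen_death_records(panel, cfg)
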