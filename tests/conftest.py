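import numpy as np
import pytest

import arscore


@pytest.fixture(scope="session")
def default_climate():
    return arscore.ClimateParams()


@pytest.fixture(scope="session")
def default_crop():
    return arscore.CropParams()


@pytest.fixture(scope="session")
def default_soil():
    return arscore.SoilProfile()


@pytest.fixture(scope="session")
def weather_7y(default_climate):
    """Seven synthetic years -> six autumn-sowable seasons."""
    return arscore.generate_weather(default_climate, 7, seed=42)


@pytest.fixture(scope="session")
def small_grid(weather_7y, default_crop, default_soil):
    """A 5-DOY x 6-year grid: 30 seasons, enough spread to build a pool."""
    doys = [283, 293, 303, 313, 323]
    return arscore.build_grid(weather_7y, doys, default_crop, default_soil)


@pytest.fixture(scope="session")
def small_pool(small_grid):
    return arscore.build_pool(small_grid, sgy=69.17)
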