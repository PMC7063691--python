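import numpy as np
import pytest

from wheatgap.crop import CultivarParams, Management, SoilProfile
from wheatgap.weather import WeatherSeries, WeatherSlice, generate_weather, site_preset


@pytest.fixture(scope="session")
def reference_cultivar() -> CultivarParams:
    return CultivarParams()


@pytest.fixture(scope="session")
def soil() -> SoilProfile:
    return SoilProfile()


@pytest.fixture(scope="session")
def temperate_site():
    return site_preset("temperate_CW")


@pytest.fixture(scope="session")
def temperate_series(temperate_site) -> WeatherSeries:
    """Six calendar years (five complete seasons) of temperate weather."""
    return generate_weather(temperate_site, years=6, seed=20240915)


@pytest.fixture(scope="session")
def temperate_mgmt(temperate_site) -> Management:
    return Management(sowing_doy=temperate_site.sowing_doy)


def constant_slice(tmin: float, tmax: float, precip: float, rad: float,
                   n: int = 365, latitude: float = 0.0,
                   start_day_index: int = 0) -> WeatherSlice:
    """A scripted season of constant daily forcing."""
    return WeatherSlice(
        tmin=np.full(n, float(tmin)),
        tmax=np.full(n, float(tmax)),
        precip=np.full(n, float(precip)),
        rad=np.full(n, float(rad)),
        start_day_index=start_day_index,
        latitude=latitude,
    )
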