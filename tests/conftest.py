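import numpy as np
import pytest

from allocane import Crop, SiteWeather


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_site(
    site_id: str,
    crop: Crop = Crop.NAPIERGRASS,
    rainfall: float = 21.1,
    solar: float = 22.0,
    temp: float = 23.0,
    rh: float = 72.0,
    wind: float = 14.0,
) -> SiteWeather:
    return SiteWeather(
        site_id=site_id,
        crop_id=crop,
        solar_radiation=solar,
        air_temperature=temp,
        rainfall=rainfall,
        relative_humidity=rh,
        wind_speed=wind,
    )


@pytest.fixture
def dev_site():
    return make_site("F718")
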