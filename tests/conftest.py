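import pytest

from allomax import (
    Environment,
    EnvironmentGridSpec,
    default_config,
    generate_environments,
)


@pytest.fixture(scope="session")
def calibration():
    """(AllometryConfig, TraitSet, WaterBudgetParams) from the shipped defaults."""
    return default_config()


@pytest.fixture(scope="session")
def cfg(calibration):
    return calibration[0]


@pytest.fixture(scope="session")
def traits(calibration):
    return calibration[1]


@pytest.fixture(scope="session")
def params(calibration):
    return calibration[2]


@pytest.fixture(scope="session")
def wet_cool_env():
    """Humid, cool, dim site: evaporation barely covers metabolism."""
    return Environment(
        precipitation=3.0, air_temperature=6.0, relative_humidity=0.93,
        wind_speed=2.0, solar_radiation=110.0, site_id="wet_cool",
    )


@pytest.fixture(scope="session")
def arid_hot_env():
    """Dry, hot, bright site: evaporative demand outruns the water supply."""
    return Environment(
        precipitation=0.25, air_temperature=28.0, relative_humidity=0.25,
        wind_speed=4.0, solar_radiation=330.0, site_id="arid_hot",
    )


@pytest.fixture(scope="session")
def temperate_env():
    return Environment(
        precipitation=1.2, air_temperature=15.0, relative_humidity=0.70,
        wind_speed=3.0, solar_radiation=250.0, site_id="temperate",
    )


@pytest.fixture(scope="session")
def transect8():
    """Eight-site wet/cool to arid/hot transect from the default generator."""
    return generate_environments(EnvironmentGridSpec(n_sites=8, seed=0))
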