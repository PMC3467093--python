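import numpy as np
import pytest

import ecoclim as ec
from ecoclim.synthetic import ClimateFieldSpec


@pytest.fixture(scope="session")
def final_params():
    return ec.load_fixture("s_exigua_final")


@pytest.fixture(scope="session")
def initial_params():
    return ec.load_fixture("s_exigua_initial")


@pytest.fixture(scope="session")
def transect():
    """Noise-free China-like south-to-north transect (18-40 degN)."""
    return ec.generate_china_transect(45)


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)


def random_station(rng, lat=None, lon=None):
    """One random but physically valid synthetic station."""
    spec = ClimateFieldSpec(
        t_equator=float(rng.uniform(20, 30)),
        lapse_lat=float(rng.uniform(0.1, 0.5)),
        amp0=float(rng.uniform(0, 3)),
        amp_lat=float(rng.uniform(0.1, 0.5)),
        diurnal=float(rng.uniform(2, 8)),
        rain_annual=float(rng.uniform(300, 2500)),
        rain_season_peak_month=int(rng.integers(1, 13)),
        rain_concentration=float(rng.uniform(0, 2.5)),
        noise_sd=float(rng.uniform(0, 1.5)),
        seed=int(rng.integers(0, 2**31 - 1)),
    )
    lat = float(rng.uniform(-50, 50)) if lat is None else lat
    lon = float(rng.uniform(-180, 180)) if lon is None else lon
    return ec.generate_station(lat, lon, spec)
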