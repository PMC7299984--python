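import numpy as np
import pytest
from hypothesis import settings

import thermodecay as td

settings.register_profile("deterministic", derandomize=True, database=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def cold_ambient_scene():
    """Noiseless, cloudless Aqua scene with t_ambient = 0: the ln-ratio
    estimator is exact, so recovered maps must equal the truth field."""
    return td.make_scene(shape=(12, 12), t_ambient=0.0,
                         t_peak_range=(300.0, 320.0), n_years=1,
                         composites_per_year=46, seed=11)


@pytest.fixture(scope="session")
def warm_ambient_scene():
    """Noiseless, cloudless Aqua scene with a realistic warm ambient, where
    the estimator carries the documented approximation bias."""
    return td.make_scene(shape=(8, 8), t_ambient=285.0, n_years=1,
                         composites_per_year=46, seed=12)


@pytest.fixture()
def small_grid():
    return td.GridSpec(4, 4, transform=(1.0, 0.0, 0.0, 0.0, -1.0, 4.0),
                       crs_label="EPSG:32633")


def recovered_annual_maps(scene, **kw):
    """Run the estimation pipeline on a scene; returns {year: DecayRateRaster}."""
    return td.rdk_annual_map(scene.day_stack(), scene.night_stack(),
                             delta_t=scene.schedule.delta_t, **kw)
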