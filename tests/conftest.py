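import numpy as np
import pytest
from hypothesis import settings

import thermozone as tz

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def square_region():
    """100 km x 100 km single-subregion study area on a 4-km lattice."""
    bounds = (0.0, 0.0, 100_000.0, 100_000.0)
    return tz.make_region(
        "square", bounds, tz.strip_subregions(bounds, ["all"])
    )


@pytest.fixture(scope="session")
def square_coords(square_region):
    return square_region.points[["x_m", "y_m"]].to_numpy(float)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def registry():
    return tz.load_breed_registry()
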