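import numpy as np
import pytest

from pollenscale.records import PollenRecord
from pollenscale.synthetic import (
    FOREST_PROFILE,
    OPEN_PROFILE,
    gen_surface_set,
    two_biome_world,
)


@pytest.fixture(scope="session")
def fossil_world():
    """50 two-biome fossil records with a latent 1/f driver (H_true = 0)."""
    return two_biome_world(n_records=50, H_true=0.0, seed=11)


@pytest.fixture(scope="session")
def surface_world():
    """Labelled surface samples for the forest and open-land classes."""
    return gen_surface_set(
        10,
        {"forest": FOREST_PROFILE, "open_land": OPEN_PROFILE},
        seed=12,
    )


@pytest.fixture()
def toy_record():
    """Tiny hand-checkable record: 4 samples, 3 taxa."""
    return PollenRecord(
        site_id="toy",
        lat=55.0,
        lon=10.0,
        times=np.array([2500.0, 3000.0, 3600.0, 4100.0]),
        taxa=["Pinus", "Betula", "Poaceae"],
        counts=np.array([[30, 10, 10], [20, 20, 10], [10, 30, 10], [5, 40, 5]]),
    )
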