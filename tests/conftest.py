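import numpy as np
import pytest

from sorgsim import canopy
from sorgsim.params import jigurti, meko
from sorgsim.soil import SoilLayer, SoilProfile, load_fixture


def synthetic_leaf_plants(x0_slope, y0_slope, y0_intercept, tlns, noise=0.0, seed=0):
    """Plants with bell-curve leaf areas from known generating regressions."""
    rng = np.random.default_rng(seed)
    plants = []
    for tln in tlns:
        prof = canopy.LeafSizeProfile(
            y0=y0_slope * tln + y0_intercept,
            x0=x0_slope * tln,
            a=canopy.default_a(tln),
            b=canopy.default_b(tln),
            tln=tln,
        )
        areas = {
            i: canopy.leaf_area_at(i, prof) * (1 + noise * rng.standard_normal())
            for i in range(1, tln + 1)
        }
        plants.append((float(tln), areas))
    return plants


@pytest.fixture(scope="session")
def meko_params():
    return meko()


@pytest.fixture(scope="session")
def jigurti_params():
    return jigurti()


@pytest.fixture(scope="session")
def melkassa_profile():
    return load_fixture("melkassa")


@pytest.fixture(scope="session")
def miesso_profile():
    return load_fixture("miesso")


@pytest.fixture
def two_layer_profile():
    """Small synthetic profile used by water-balance unit tests."""
    return SoilProfile(
        [
            SoilLayer(0, 15, 1.2, dul=0.30, cll=0.10, sw=0.30, kl=0.08),
            SoilLayer(15, 30, 1.2, dul=0.30, cll=0.10, sw=0.30, kl=0.08),
        ],
        "synthetic",
    )
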