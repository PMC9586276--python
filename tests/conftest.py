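import numpy as np
import pandas as pd
import pytest

from dynocc import SiteRegistry, make_fixture


@pytest.fixture(scope="session")
def tiny_fixture():
    """Small synthetic study reused across tests (30 sites, 10 years)."""
    return make_fixture("tiny", seed=11)


@pytest.fixture(scope="session")
def tiny_fit(tiny_fixture):
    """A short latent-Gibbs fit of the tiny study (shared, read-only)."""
    from dynocc import DynamicOccupancyModel, MCMCConfig

    model = DynamicOccupancyModel(tiny_fixture.data)
    res = model.fit(
        MCMCConfig(n_chains=3, n_burnin=300, n_iter=1000, thin=10, seed=5)
    )
    return model, res


def toy_sites_frame():
    """Three hand-written sites covering old/new and destruction cases."""
    return pd.DataFrame(
        {
            "site_id": ["p1", "p2", "p3"],
            "region": ["A", "A", "B"],
            "is_new": [False, True, True],
            "construction_year": [pd.NA, 2005, pd.NA],
            "destruction_year": [pd.NA, pd.NA, pd.NA],
            "destroyed": [False, False, False],
            "x_km": [0.0, 1.0, 5.0],
            "y_km": [0.0, 0.0, 0.0],
            "elevation": [400.0, 420.0, 500.0],
            "surface_area": [120.0, 300.0, 50.0],
            "water_fluctuation": [0, 1, 0],
            "forest_pct_100m": [30.0, 60.0, 10.0],
            "road_area_1km": [1000.0, 0.0, 250.0],
        }
    )


@pytest.fixture
def toy_sites():
    return SiteRegistry(toy_sites_frame())


@pytest.fixture
def toy_visits():
    rows = []
    for sid, years in (("p1", [1999, 2001]), ("p2", [2006]), ("p3", [2010])):
        for yr in years:
            for j, is_day in ((1, False), (2, False), (3, True)):
                rows.append(
                    {
                        "site_id": sid,
                        "year": yr,
                        "visit": j,
                        "is_day": is_day,
                        "observer_id": None if is_day else f"obs{j}",
                        "detected": int(sid == "p1" and j == 1),
                    }
                )
    return pd.DataFrame(rows)
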