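import numpy as np
import pandas as pd
import pytest

from forestbird.ingest import PointCountTable
from forestbird.simulate import SimulationConfig, simulate_dataset


@pytest.fixture(scope="session")
def tiny_dataset():
    """Small synthetic survey shared across fit tests (30 sites x 5 years,
    10 knots, so knot-years average 3 samples and every variance component
    is identified)."""
    cfg = SimulationConfig(n_sites=30, n_years=5, n_knots=10, seed=101)
    return cfg, simulate_dataset(cfg)


@pytest.fixture(scope="session")
def community_dataset():
    """Synthetic survey with the species-level count layer."""
    cfg = SimulationConfig(n_sites=15, n_years=3, n_knots=15, seed=202,
                           n_species=12, n_titmouse=2)
    return cfg, simulate_dataset(cfg, with_community=True)


@pytest.fixture
def toy_traits():
    return pd.DataFrame({
        "species_code": ["TIT1", "WARB", "WADER", "CROW"],
        "body_mass": [10.0, 20.0, 150.0, 500.0],
        "is_titmouse": [True, False, False, False],
        "is_excluded_guild": [False, False, True, False],
        "is_forest": [True, True, True, False],
    }).set_index("species_code")


@pytest.fixture
def toy_records():
    rec = pd.DataFrame({
        "site_id": ["A"] * 4,
        "point_id": ["p1"] * 4,
        "year": [2001] * 4,
        "period": [1] * 4,
        "species_code": ["TIT1", "WARB", "WADER", "CROW"],
        "count": [2, 3, 1, 5],
        "habitat_code": ["F"] * 4,
    })
    return PointCountTable(records=rec, country_mode="individual_counts")


@pytest.fixture
def toy_locations():
    return pd.DataFrame({
        "site_id": ["A"], "point_id": ["p1"], "x_km": [0.0], "y_km": [0.0],
    })
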