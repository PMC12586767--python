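from __future__ import annotations

import numpy as np
import pytest

import lifeburden as lb
from lifeburden.synthetic import true_hazard_matrix


@pytest.fixture(scope="session")
def default_table() -> lb.AgeCauseTable:
    """One draw from the default synthetic scenario (seed 42)."""
    return lb.default_cohort(seed=42)


@pytest.fixture(scope="session")
def large_table() -> lb.AgeCauseTable:
    """Large-sample draw: 10^7 person-years, low relative noise."""
    return lb.default_cohort(seed=7, total_person_years=1e7)


@pytest.fixture(scope="session")
def default_curves(default_table) -> dict[str, lb.RateCurve]:
    return lb.fit_all(default_table)


@pytest.fixture(scope="session")
def baseline_lifetable(default_curves) -> lb.LifeTable:
    return lb.build_life_table(default_curves[lb.ALL_CAUSE], default_curves)


@pytest.fixture(scope="session")
def true_hazards() -> dict[str, np.ndarray]:
    """Closed-form hazards of the default synthetic scenario."""
    return true_hazard_matrix(lb.default_hazards())


@pytest.fixture()
def amap() -> lb.AttributionMap:
    return lb.default_attribution()
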