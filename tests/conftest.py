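import numpy as np
import pandas as pd
import pytest

from marginshift import MonthlyTemperatureGrid, PeriodWindow


@pytest.fixture
def period1() -> PeriodWindow:
    return PeriodWindow("1984-1988", 1984, 1988)


@pytest.fixture
def period2() -> PeriodWindow:
    return PeriodWindow("2002-2006", 2002, 2006)


def make_grid(
    years,
    lats,
    lons,
    fill=15.0,
    months=(4, 5, 6),
) -> MonthlyTemperatureGrid:
    """Uniform grid helper; callers mutate ``grid.data`` for structure."""
    shape = (len(years), len(months), len(lats), len(lons))
    return MonthlyTemperatureGrid.from_arrays(
        years, months, lats, lons, np.full(shape, float(fill))
    )


def route_temps_frame(lats, temps, counts, route_ids=None, species_id="SP") -> pd.DataFrame:
    """Single-species occupied-route table for niche-metric tests."""
    n = len(lats)
    if route_ids is None:
        route_ids = [f"R{i:03d}" for i in range(n)]
    return pd.DataFrame(
        {
            "species_id": species_id,
            "route_id": route_ids,
            "latitude": np.asarray(lats, dtype=float),
            "longitude": np.zeros(n),
            "mean_T": np.asarray(temps, dtype=float),
            "total_count": np.asarray(counts, dtype=int),
        }
    )


def obs_frame(rows) -> pd.DataFrame:
    """Observation table from (route_id, lat, lon, year, species, count) tuples."""
    return pd.DataFrame(
        rows,
        columns=["route_id", "latitude", "longitude", "year", "species_id", "count"],
    )
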