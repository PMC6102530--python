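"""Survey observations, climate grids and breeding-season route temperatures.

This module owns the two raw inputs of the pipeline — a table of per-route
species counts (BBS-style: one row per route x species x year) and a stack of
gridded monthly mean temperatures — and derives from them the quantity every
downstream metric is built on: the mean breeding-season (April–June)
temperature within a 20-km buffer of a route centroid, conditioned on the
years in which a species was actually observed there.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import xarray as xr

logger = logging.getLogger(__name__)

#: Mean Earth radius in km (IUGG), used for all great-circle distances.
EARTH_RADIUS_KM = 6371.0088

#: Months whose monthly means define the breeding season.
BREEDING_MONTHS = (4, 5, 6)

#: Default buffer radius around a route centroid, km.
DEFAULT_BUFFER_KM = 20.0

OBSERVATION_COLUMNS = (
    "route_id",
    "latitude",
    "longitude",
    "year",
    "species_id",
    "count",
)


class MarginShiftError(Exception):
    """Base class for all package errors."""


class SchemaError(MarginShiftError):
    """An input table is missing required columns."""


class GridCoverageError(MarginShiftError):
    """The temperature grid lacks required (year, month) layers."""


class NoDataError(MarginShiftError):
    """A buffer or query hit no grid cell with data."""


# ---------------------------------------------------------------------------
# Period windows
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PeriodWindow:
    """An inclusive run of survey years treated as one sampling period."""

    label: str
    start_year: int
    end_year: int

    def __post_init__(self) -> None:
        if self.end_year < self.start_year:
            raise ValueError(
                f"period {self.label!r}: end_year {self.end_year} precedes "
                f"start_year {self.start_year}"
            )

    @property
    def years(self) -> tuple[int, ...]:
        return tuple(range(self.start_year, self.end_year + 1))

    @property
    def midpoint_year(self) -> float:
        return (self.start_year + self.end_year) / 2.0

    def __contains__(self, year: object) -> bool:
        return isinstance(year, (int, np.integer)) and (
            self.start_year <= int(year) <= self.end_year
        )


#: The two survey windows of the original study design.
HISTORICAL_PERIOD = PeriodWindow("1984-1988", 1984, 1988)
MODERN_PERIOD = PeriodWindow("2002-2006", 2002, 2006)


@dataclass(frozen=True)
class RouteTemperature:
    """Breeding-season temperature of a route for one species and period.

    ``mean_breeding_T`` is averaged only over the period years in which the
    species was recorded (count > 0) on the route; ``total_count`` sums the
    counts over those same years.
    """

    route_id: str
    species_id: str
    period: str
    mean_breeding_T: float
    years_used: frozenset[int]
    total_count: int
    latitude: float = float("nan")
    longitude: float = float("nan")


# ---------------------------------------------------------------------------
# Great-circle geometry
# ---------------------------------------------------------------------------


def great_circle_km(
    lat1: np.ndarray | float,
    lon1: np.ndarray | float,
    lat2: np.ndarray | float,
    lon2: np.ndarray | float,
) -> np.ndarray:
    """Haversine distance in km on a sphere of radius ``EARTH_RADIUS_KM``."""
    lat1, lon1, lat2, lon2 = (np.radians(np.asarray(a, dtype=float)) for a in (lat1, lon1, lat2, lon2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    h = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(h, 0.0, 1.0)))


# ---------------------------------------------------------------------------
# Temperature grid
# ---------------------------------------------------------------------------


class MonthlyTemperatureGrid:
    """A lattice of monthly mean temperatures indexed by (year, month, lat, lon).

    Wraps an :class:`xarray.DataArray` with dims ``("year", "month", "lat",
    "lon")`` in degrees Celsius. Cells without data are NaN and are excluded
    from buffer means; a buffer containing only NaN cells raises
    :class:`NoDataError`.
    """

    DIMS = ("year", "month", "lat", "lon")

    def __init__(self, data: xr.DataArray):
        if tuple(data.dims) != self.DIMS:
            raise ValueError(f"grid dims must be {self.DIMS}, got {tuple(data.dims)}")
        self.data = data
        self._season_cache: dict[tuple[int, tuple[int, ...]], np.ndarray] = {}

    # -- construction -------------------------------------------------------

    @classmethod
    def from_arrays(
        cls,
        years: Sequence[int],
        months: Sequence[int],
        lats: Sequence[float],
        lons: Sequence[float],
        values: np.ndarray,
    ) -> "MonthlyTemperatureGrid":
        arr = xr.DataArray(
            np.asarray(values, dtype=float),
            coords={
                "year": list(map(int, years)),
                "month": list(map(int, months)),
                "lat": np.asarray(lats, dtype=float),
                "lon": np.asarray(lons, dtype=float),
            },
            dims=cls.DIMS,
            name="temperature",
        )
        return cls(arr)

    @classmethod
    def constant(
        cls,
        value: float,
        years: Sequence[int],
        lats: Sequence[float],
        lons: Sequence[float],
        months: Sequence[int] = BREEDING_MONTHS,
    ) -> "MonthlyTemperatureGrid":
        """A spatially and temporally uniform grid — mainly for tests."""
        shape = (len(years), len(months), len(lats), len(lons))
        return cls.from_arrays(years, months, lats, lons, np.full(shape, float(value)))

    @classmethod
    def from_netcdf(cls, path: str | Path, var: str = "temperature") -> "MonthlyTemperatureGrid":
        ds = xr.open_dataset(path, engine="scipy")
        try:
            arr = ds[var].load()
        finally:
            ds.close()
        return cls(arr.transpose(*cls.DIMS))

    @classmethod
    def from_table(cls, path: str | Path) -> "MonthlyTemperatureGrid":
        """Read a long-format CSV with columns year, month, lat, lon, temperature."""
        df = pd.read_csv(path)
        required = {"year", "month", "lat", "lon", "temperature"}
        missing = required - set(df.columns)
        if missing:
            raise SchemaError(f"grid table missing columns: {sorted(missing)}")
        arr = (
            df.set_index(["year", "month", "lat", "lon"])["temperature"]
            .to_xarray()
            .transpose(*cls.DIMS)
        )
        return cls(arr.astype(float))

    # -- serialisation ------------------------------------------------------

    def to_netcdf(self, path: str | Path) -> None:
        self.data.to_dataset(name="temperature").to_netcdf(path, engine="scipy")

    def to_table(self, path: str | Path) -> None:
        self.data.rename("temperature").to_dataframe().reset_index().to_csv(path, index=False)

    # -- properties ---------------------------------------------------------

    @property
    def years(self) -> tuple[int, ...]:
        return tuple(int(y) for y in self.data.coords["year"].values)

    @property
    def months(self) -> tuple[int, ...]:
        return tuple(int(m) for m in self.data.coords["month"].values)

    @property
    def lats(self) -> np.ndarray:
        return self.data.coords["lat"].values

    @property
    def lons(self) -> np.ndarray:
        return self.data.coords["lon"].values

    # -- validation ---------------------------------------------------------

    def validate_coverage(
        self, years: Iterable[int], months: Sequence[int] = BREEDING_MONTHS
    ) -> None:
        """Raise :class:`GridCoverageError` listing every missing (year, month)."""
        have_years = set(self.years)
        have_months = set(self.months)
        missing = [
            (int(y), int(m))
            for y in years
            for m in months
            if int(y) not in have_years or int(m) not in have_months
        ]
        if missing:
            raise GridCoverageError(f"grid missing (year, month) layers: {missing}")

    # -- extraction ---------------------------------------------------------

    def season_mean(
        self, year: int, months: Sequence[int] = BREEDING_MONTHS
    ) -> np.ndarray:
        """(lat, lon) array of the mean over ``months`` for one year."""
        key = (int(year), tuple(int(m) for m in months))
        if key not in self._season_cache:
            self.validate_coverage([year], months)
            sub = self.data.sel(year=int(year), month=list(key[1]))
            self._season_cache[key] = sub.mean("month").values
        return self._season_cache[key]

    def buffer_mask(self, latitude: float, longitude: float, buffer_km: float) -> np.ndarray:
        """Boolean (lat, lon) mask of cells whose centers lie within the buffer."""
        lat_grid, lon_grid = np.meshgrid(self.lats, self.lons, indexing="ij")
        return great_circle_km(latitude, longitude, lat_grid, lon_grid) <= buffer_km

    def breeding_season_temperature(
        self,
        latitude: float,
        longitude: float,
        year: int,
        buffer_km: float = DEFAULT_BUFFER_KM,
        months: Sequence[int] = BREEDING_MONTHS,
        label: str | None = None,
    ) -> float:
        """Unweighted mean, over in-buffer cells, of the seasonal mean temperature.

        The seasonal mean of a cell is the plain average of its April, May and
        June (by default) monthly means for ``year``. Cell membership is
        center-within-radius on the sphere.
        """
        mask = self.buffer_mask(latitude, longitude, buffer_km)
        season = self.season_mean(year, months)
        vals = season[mask]
        vals = vals[np.isfinite(vals)]
        if vals.size == 0:
            who = label or f"({latitude:.4f}, {longitude:.4f})"
            raise NoDataError(
                f"no grid cell with data within {buffer_km} km of {who} in {year}"
            )
        return float(vals.mean())


def buffer_season_means(
    grid: MonthlyTemperatureGrid,
    routes: pd.DataFrame,
    years: Sequence[int],
    buffer_km: float = DEFAULT_BUFFER_KM,
    months: Sequence[int] = BREEDING_MONTHS,
) -> pd.DataFrame:
    """Bulk buffer extraction: one row per (route_id, year) with column ``T``.

    Vectorized over routes via a normalized membership matrix so the whole
    table costs one matrix product per analysis. NaN cells are excluded
    per-route; an all-NaN buffer raises :class:`NoDataError` naming the route.
    """
    years = [int(y) for y in years]
    grid.validate_coverage(years, months)
    n_cells = grid.lats.size * grid.lons.size
    weights = np.zeros((len(routes), n_cells))
    finite = np.isfinite(grid.season_mean(years[0], months)).ravel()
    for i, row in enumerate(routes.itertuples(index=False)):
        mask = grid.buffer_mask(row.latitude, row.longitude, buffer_km).ravel() & finite
        total = mask.sum()
        if total == 0:
            raise NoDataError(
                f"no grid cell with data within {buffer_km} km of route "
                f"{row.route_id!r}"
            )
        weights[i, mask] = 1.0 / total
    seasons = np.stack([grid.season_mean(y, months).ravel() for y in years])
    # NaN cells never carry weight, so zero them before the product
    temps = weights @ np.where(np.isfinite(seasons), seasons, 0.0).T
    out = pd.DataFrame(temps, columns=years)
    out.insert(0, "route_id", routes["route_id"].to_numpy())
    return out.melt(id_vars="route_id", var_name="year", value_name="T").astype(
        {"year": int}
    )


# ---------------------------------------------------------------------------
# Observation loading
# ---------------------------------------------------------------------------


def load_survey_observations(
    source: str | Path, delimiter: str | None = None
) -> pd.DataFrame:
    """Load a delimited observation table into a typed DataFrame.

    The file must carry a header naming ``route_id, latitude, longitude,
    year, species_id, count``. Rows with non-numeric or negative counts (or
    malformed coordinates/years) are rejected and logged with their file line
    numbers; duplicate (route, species, year) rows are summed with a warning.
    """
    path = Path(source)
    if delimiter is None:
        delimiter = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    raw = pd.read_csv(path, sep=delimiter, dtype=str, skipinitialspace=True)
    raw.columns = [c.strip() for c in raw.columns]
    missing = set(OBSERVATION_COLUMNS) - set(raw.columns)
    if missing:
        raise SchemaError(f"{path.name}: missing required columns {sorted(missing)}")

    df = raw.loc[:, list(OBSERVATION_COLUMNS)].copy()
    numeric = {
        "latitude": pd.to_numeric(df["latitude"], errors="coerce"),
        "longitude": pd.to_numeric(df["longitude"], errors="coerce"),
        "year": pd.to_numeric(df["year"], errors="coerce"),
        "count": pd.to_numeric(df["count"], errors="coerce"),
    }
    bad = (
        numeric["latitude"].isna()
        | numeric["longitude"].isna()
        | numeric["year"].isna()
        | numeric["count"].isna()
        | (numeric["count"] < 0)
        | (numeric["year"] % 1 != 0)
    )
    if bad.any():
        # +2: one for the header row, one for 0- vs 1-based indexing
        lines = [int(i) + 2 for i in df.index[bad]]
        logger.warning(
            "%s: rejected %d malformed row(s) at line(s) %s",
            path.name,
            len(lines),
            lines,
        )
        df = df.loc[~bad]
    for col, series in numeric.items():
        df[col] = series.loc[df.index]
    df = df.astype({"year": int, "count": int})
    df["route_id"] = df["route_id"].astype(str).str.strip()
    df["species_id"] = df["species_id"].astype(str).str.strip()

    key = ["route_id", "species_id", "year"]
    if df.duplicated(key).any():
        n_dup = int(df.duplicated(key).sum())
        logger.warning(
            "%s: %d duplicate (route, species, year) row(s) merged by summing counts",
            path.name,
            n_dup,
        )
        df = (
            df.groupby(key, as_index=False)
            .agg(
                latitude=("latitude", "first"),
                longitude=("longitude", "first"),
                count=("count", "sum"),
            )
            .loc[:, list(OBSERVATION_COLUMNS)]
        )
    return df.reset_index(drop=True)


def routes_from_observations(obs: pd.DataFrame) -> pd.DataFrame:
    """Unique routes with centroid coordinates (mean over records)."""
    return (
        obs.groupby("route_id", as_index=False)
        .agg(latitude=("latitude", "mean"), longitude=("longitude", "mean"))
        .sort_values("route_id")
        .reset_index(drop=True)
    )


# ---------------------------------------------------------------------------
# Observation-year-conditional route temperatures
# ---------------------------------------------------------------------------


def species_period_route_temperature(
    obs: pd.DataFrame,
    grid: MonthlyTemperatureGrid,
    species_id: str,
    route_id: str,
    period: PeriodWindow,
    buffer_km: float = DEFAULT_BUFFER_KM,
    months: Sequence[int] = BREEDING_MONTHS,
) -> RouteTemperature:
    """Mean breeding-season temperature on one route over the years a species
    was observed there within ``period``, plus the summed count."""
    sel = obs[
        (obs["species_id"] == species_id)
        & (obs["route_id"] == route_id)
        & obs["year"].isin(period.years)
        & (obs["count"] > 0)
    ]
    if sel.empty:
        raise MarginShiftError(
            f"species {species_id!r} has no observation years on route "
            f"{route_id!r} in period {period.label!r}"
        )
    lat = float(sel["latitude"].mean())
    lon = float(sel["longitude"].mean())
    temps = [
        grid.breeding_season_temperature(lat, lon, int(y), buffer_km, months, label=route_id)
        for y in sel["year"]
    ]
    return RouteTemperature(
        route_id=route_id,
        species_id=species_id,
        period=period.label,
        mean_breeding_T=float(np.mean(temps)),
        years_used=frozenset(int(y) for y in sel["year"]),
        total_count=int(sel["count"].sum()),
        latitude=lat,
        longitude=lon,
    )


def route_temperature_table(
    obs: pd.DataFrame,
    grid: MonthlyTemperatureGrid,
    period: PeriodWindow,
    buffer_km: float = DEFAULT_BUFFER_KM,
    months: Sequence[int] = BREEDING_MONTHS,
) -> pd.DataFrame:
    """Observation-conditional route temperatures for every (species, route).

    Returns one row per species x occupied route in ``period`` with columns
    ``species_id, route_id, latitude, longitude, mean_T, total_count,
    n_years``. This is the workhorse table every niche metric consumes.
    """
    obs_p = obs[obs["year"].isin(period.years) & (obs["count"] > 0)]
    if obs_p.empty:
        return pd.DataFrame(
            columns=[
                "species_id",
                "route_id",
                "latitude",
                "longitude",
                "mean_T",
                "total_count",
                "n_years",
            ]
        )
    routes = routes_from_observations(obs_p)
    temps = buffer_season_means(grid, routes, period.years, buffer_km, months)
    merged = obs_p.merge(temps, on=["route_id", "year"], how="left", validate="m:1")
    out = (
        merged.groupby(["species_id", "route_id"], as_index=False)
        .agg(
            latitude=("latitude", "mean"),
            longitude=("longitude", "mean"),
            mean_T=("T", "mean"),
            total_count=("count", "sum"),
            n_years=("year", "nunique"),
        )
        .sort_values(["species_id", "route_id"])
        .reset_index(drop=True)
    )
    return out
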