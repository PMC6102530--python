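"""Virtual-ecologist generator: survey-like observations with known truth.

The generator builds the simplest world in which every pipeline stage has an
analytically known answer: a rectangular latitude-longitude domain, a
temperature field that falls off linearly with latitude (a fixed lapse
rate), a uniform between-period warming, and optional cell-by-year noise.
Routes sit on a jittered regular lattice. Each species occupies exactly the
routes whose local breeding-season temperature falls inside its tolerance
window, optionally truncated poleward at a hard cap latitude — the device
that reproduces a range margin sitting warmer than the species' cool
tolerance. In the second period, sites near the warm tolerance limit can
suffer local extinction with a hazard that grows as the warm-limit
proximity shrinks.

Everything is seeded; a fixed seed yields byte-identical tables and grids.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .route_climate import (
    BREEDING_MONTHS,
    HISTORICAL_PERIOD,
    MODERN_PERIOD,
    MonthlyTemperatureGrid,
    PeriodWindow,
)
from .shift_analysis import KM_PER_DEGREE_LATITUDE, per_decade_rate


@dataclass(frozen=True)
class SpeciesTruth:
    """Ground-truth parameters of one synthetic species.

    ``poleward_cap_latitude`` imposes a non-thermal poleward range cap; when
    ``poleward_cap_latitude_p2`` is given the cap moves between periods
    (used for pure-translation scenarios where the whole range tracks the
    warming). ``extinction_sensitivity`` scales the period-2 local-extinction
    hazard at warm-limit-proximal sites (0 disables extinctions).
    """

    species_id: str
    T_opt: float
    tolerance_low: float
    tolerance_high: float
    poleward_cap_latitude: float | None = None
    poleward_cap_latitude_p2: float | None = None
    detection_prob: float = 1.0
    peak_abundance: float = 10.0
    extinction_sensitivity: float = 0.0

    def __post_init__(self) -> None:
        if not (self.tolerance_low < self.T_opt < self.tolerance_high):
            raise ValueError(
                f"{self.species_id}: need tolerance_low < T_opt < tolerance_high"
            )
        if not (0.0 < self.detection_prob <= 1.0):
            raise ValueError(f"{self.species_id}: detection_prob must be in (0, 1]")

    @property
    def abundance_width(self) -> float:
        # quarter of the tolerance window: abundance decays smoothly to
        # ~13% of peak at the window edges
        return (self.tolerance_high - self.tolerance_low) / 4.0

    def cap_for_period(self, period_index: int) -> float | None:
        if period_index == 1 and self.poleward_cap_latitude_p2 is not None:
            return self.poleward_cap_latitude_p2
        return self.poleward_cap_latitude


@dataclass(frozen=True)
class ScenarioConfig:
    """Domain geometry, climate law and sampling design of a scenario.

    The climate law is
    ``T(cell, year, month) = season_base_T + month_offset(month)
    - lapse_rate * (lat - lat_min) + a(cell) + warming * [year in period 2]
    + eps(cell, year)`` with ``eps ~ Normal(0, noise_sd^2)`` shared across
    the three months of a cell-year and ``a`` a static spatially smooth
    anomaly field (Gaussian-smoothed noise with correlation length
    ``anomaly_smoothing_deg``, amplitude ``anomaly_sd``). The static anomaly
    puts cool (and warm) pockets inside ranges — without it higher latitude
    always means cooler, and a capped poleward margin could never sit warmer
    than the coolest occupied site. Defaults mirror the study design: two five-year windows 18 years
    apart at midpoint, a +0.43 °C between-period warming, April-June
    breeding months.
    """

    lat_min: float = 30.0
    lat_max: float = 50.0
    lon_min: float = -100.0
    lon_max: float = -96.0
    cell_size_deg: float = 0.25
    route_spacing_deg: float = 0.5
    route_jitter: float = 0.1  # fraction of spacing, uniform in +/- this
    lapse_rate: float = 1.0  # °C per degree latitude, > 0
    season_base_T: float = 26.0  # breeding-season mean at lat_min, °C
    month_offsets: tuple[float, float, float] = (-2.0, 0.0, 2.0)
    warming: float = 0.43
    noise_sd: float = 0.0
    anomaly_sd: float = 0.0  # static spatial anomaly amplitude, °C
    anomaly_smoothing_deg: float = 0.75  # correlation length of the anomaly
    #: deterministic cool pockets (lat, lon, radius_deg, depth_C): conical
    #: depressions emulating highlands, so that the coolest occupied sites
    #: need not lie on the poleward margin
    cold_pockets: tuple[tuple[float, float, float, float], ...] = ()
    #: deterministic cool ridges (lon_center, half_width_deg, depth_C):
    #: north-south mountain ranges, triangular cooling in longitude and
    #: constant in latitude — cool structure whose isotherms translate
    #: exactly with a uniform warming
    cold_ridges: tuple[tuple[float, float, float], ...] = ()
    period1: PeriodWindow = HISTORICAL_PERIOD
    period2: PeriodWindow = MODERN_PERIOD
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lapse_rate <= 0:
            raise ValueError("lapse_rate must be > 0 (temperature falls poleward)")
        if set(self.period1.years) & set(self.period2.years):
            raise ValueError("periods must be disjoint")

    @property
    def years(self) -> tuple[int, ...]:
        return self.period1.years + self.period2.years

    def season_baseline(self, period_index: int) -> float:
        """Noise-free breeding-season mean at lat_min for period 0 or 1."""
        return self.season_base_T + (self.warming if period_index == 1 else 0.0)

    def temperature_at(self, latitude: float, period_index: int) -> float:
        """Noise-free breeding-season mean at a latitude for one period."""
        return self.season_baseline(period_index) - self.lapse_rate * (
            latitude - self.lat_min
        )

    def latitude_of(self, temperature: float, period_index: int) -> float:
        """Latitude of the noise-free seasonal isotherm for one period."""
        return self.lat_min + (self.season_baseline(period_index) - temperature) / (
            self.lapse_rate
        )


def _centers(lo: float, hi: float, step: float) -> np.ndarray:
    n = max(1, int(round((hi - lo) / step)))
    return lo + step * (np.arange(n) + 0.5)


def generate_climate(cfg: ScenarioConfig, seed: int | None = None) -> MonthlyTemperatureGrid:
    """Monthly temperature grid for all years of both periods."""
    base_seed = cfg.seed if seed is None else seed
    rng = np.random.default_rng(base_seed)
    lats = _centers(cfg.lat_min, cfg.lat_max, cfg.cell_size_deg)
    lons = _centers(cfg.lon_min, cfg.lon_max, cfg.cell_size_deg)
    years = cfg.years
    months = BREEDING_MONTHS
    p2_years = set(cfg.period2.years)
    if cfg.anomaly_sd > 0:
        # smoothed noise: pockets wider than a route buffer, so cool/warm
        # patches inside ranges survive the 20-km averaging
        white = np.random.default_rng([base_seed, 15485863]).normal(
            size=(lats.size, lons.size)
        )
        if cfg.anomaly_smoothing_deg > 0:
            from scipy.ndimage import gaussian_filter

            white = gaussian_filter(
                white, cfg.anomaly_smoothing_deg / cfg.cell_size_deg, mode="nearest"
            )
        anomaly = cfg.anomaly_sd * white / max(white.std(), 1e-12)
    else:
        anomaly = np.zeros((lats.size, lons.size))
    for plat, plon, radius, depth in cfg.cold_pockets:
        # conical profile: constant gradient, so the geometry of any
        # temperature level set is the same at every depth
        r = np.sqrt((lats[:, None] - plat) ** 2 + (lons[None, :] - plon) ** 2)
        anomaly = anomaly - depth * np.clip(1.0 - r / radius, 0.0, None)
    for rlon, half_width, depth in cfg.cold_ridges:
        cool = depth * np.clip(1.0 - np.abs(lons[None, :] - rlon) / half_width, 0.0, None)
        anomaly = anomaly - np.broadcast_to(cool, (lats.size, lons.size))
    values = np.empty((len(years), len(months), lats.size, lons.size))
    for yi, year in enumerate(years):
        base = cfg.season_base_T + (cfg.warming if year in p2_years else 0.0)
        eps = (
            rng.normal(0.0, cfg.noise_sd, size=(lats.size, lons.size))
            if cfg.noise_sd > 0
            else 0.0
        )
        field2d = base - cfg.lapse_rate * (lats[:, None] - cfg.lat_min) + anomaly + eps
        for mi, off in enumerate(cfg.month_offsets):
            values[yi, mi] = field2d + off
    return MonthlyTemperatureGrid.from_arrays(years, months, lats, lons, values)


def generate_routes(cfg: ScenarioConfig, seed: int | None = None) -> pd.DataFrame:
    """Survey routes on a jittered regular lattice inside the domain."""
    rng = np.random.default_rng([cfg.seed if seed is None else seed, 104729])
    lat0 = _centers(cfg.lat_min, cfg.lat_max, cfg.route_spacing_deg)
    lon0 = _centers(cfg.lon_min, cfg.lon_max, cfg.route_spacing_deg)
    lat_g, lon_g = np.meshgrid(lat0, lon0, indexing="ij")
    n = lat_g.size
    jit = cfg.route_jitter * cfg.route_spacing_deg
    lats = lat_g.ravel() + (rng.uniform(-jit, jit, n) if jit > 0 else 0.0)
    lons = lon_g.ravel() + (rng.uniform(-jit, jit, n) if jit > 0 else 0.0)
    lats = np.clip(lats, cfg.lat_min, cfg.lat_max)
    lons = np.clip(lons, cfg.lon_min, cfg.lon_max)
    return pd.DataFrame(
        {
            "route_id": [f"R{i:05d}" for i in range(n)],
            "latitude": lats,
            "longitude": lons,
        }
    )


def _nearest_cell_temps(
    grid: MonthlyTemperatureGrid, routes: pd.DataFrame, years: Sequence[int]
) -> np.ndarray:
    """(n_routes, n_years) local seasonal means taken from the nearest cell."""
    lat_idx = np.abs(
        routes["latitude"].to_numpy()[:, None] - grid.lats[None, :]
    ).argmin(axis=1)
    lon_idx = np.abs(
        routes["longitude"].to_numpy()[:, None] - grid.lons[None, :]
    ).argmin(axis=1)
    out = np.empty((len(routes), len(years)))
    for yi, year in enumerate(years):
        season = grid.season_mean(int(year))
        out[:, yi] = season[lat_idx, lon_idx]
    return out


def simulate_observations(
    cfg: ScenarioConfig,
    truths: Sequence[SpeciesTruth],
    grid: MonthlyTemperatureGrid,
    routes: pd.DataFrame | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Simulate the survey: one row per detected route x year x species.

    Occupancy at a route-year requires the local (nearest-cell) seasonal
    temperature to fall inside the tolerance window and the latitude to
    respect the poleward cap. Period-2 extinctions remove a site for the
    whole period with probability ``min(1, sensitivity * exp(-proximity))``
    where proximity is the site's period-2 distance (°C) below the warm
    tolerance limit. Given occupancy, detection is Bernoulli and the count
    is ``1 + Poisson(max(lambda - 1, 0))`` with ``lambda`` a Gaussian curve
    in temperature peaking at ``peak_abundance`` — at least one individual
    whenever the species is detected.
    """
    base_seed = cfg.seed if seed is None else seed
    if routes is None:
        routes = generate_routes(cfg, base_seed)
    years = np.asarray(cfg.years)
    local_t = _nearest_cell_temps(grid, routes, years)
    lat = routes["latitude"].to_numpy()
    p2_mask = np.isin(years, cfg.period2.years)
    p1_mask = ~p2_mask
    t_p2_site = local_t[:, p2_mask].mean(axis=1)

    frames: list[pd.DataFrame] = []
    for k, sp in enumerate(truths):
        rng = np.random.default_rng([base_seed, 2 * k + 1])
        tol = (local_t >= sp.tolerance_low) & (local_t <= sp.tolerance_high)
        occ = tol.copy()
        cap1 = sp.cap_for_period(0)
        cap2 = sp.cap_for_period(1)
        if cap1 is not None:
            occ[:, p1_mask] &= (lat <= cap1)[:, None]
        if cap2 is not None:
            occ[:, p2_mask] &= (lat <= cap2)[:, None]

        if sp.extinction_sensitivity > 0:
            occupied_p1 = occ[:, p1_mask].any(axis=1)
            proximity = np.maximum(sp.tolerance_high - t_p2_site, 0.0)
            p_ext = np.clip(
                sp.extinction_sensitivity * np.exp(-proximity), 0.0, 1.0
            )
            extinct = occupied_p1 & (rng.random(len(routes)) < p_ext)
            occ[np.ix_(extinct, p2_mask)] = False

        detected = occ & (
            rng.random(occ.shape) < sp.detection_prob
            if sp.detection_prob < 1.0
            else True
        )
        lam = sp.peak_abundance * np.exp(
            -0.5 * ((local_t - sp.T_opt) / sp.abundance_width) ** 2
        )
        counts = 1 + rng.poisson(np.maximum(lam - 1.0, 0.0))
        ri, yi = np.nonzero(detected)
        if ri.size == 0:
            continue
        frames.append(
            pd.DataFrame(
                {
                    "route_id": routes["route_id"].to_numpy()[ri],
                    "latitude": lat[ri],
                    "longitude": routes["longitude"].to_numpy()[ri],
                    "year": years[yi],
                    "species_id": sp.species_id,
                    "count": counts[ri, yi],
                }
            )
        )
    if not frames:
        return pd.DataFrame(
            columns=["route_id", "latitude", "longitude", "year", "species_id", "count"]
        )
    out = pd.concat(frames, ignore_index=True)
    return out.sort_values(["species_id", "route_id", "year"], kind="mergesort").reset_index(
        drop=True
    )


def true_values(
    cfg: ScenarioConfig,
    truths: Sequence[SpeciesTruth],
    expectations: bool = False,
) -> pd.DataFrame:
    """Analytic ground truth per species: margin latitudes, limit temperatures
    and displacement rates under the noise-free climate law.

    Refuses stochastic scenarios (noise, static anomalies or imperfect
    detection) unless ``expectations=True``, in which case the same formulas
    are returned as expectations of the pure-gradient field. In the pure
    gradient the coolest occupied sites are exactly the poleward margin
    sites, so both environmental distances are identically zero whether or
    not a cap binds; positive poleward gaps need the static anomaly field
    and are checked against the pipeline, not against this table.
    """
    if not expectations:
        if cfg.noise_sd > 0 or cfg.anomaly_sd > 0:
            raise ValueError("scenario is stochastic; truth undefined")
        if any(sp.detection_prob < 1.0 for sp in truths):
            raise ValueError("detection_prob < 1; truth undefined")
    rows = []
    for sp in truths:
        rec: dict[str, float | str] = {"species_id": sp.species_id}
        margins: dict[tuple[int, str], float] = {}
        for pi, plabel in ((0, "period1"), (1, "period2")):
            lat_warm_iso = cfg.latitude_of(sp.tolerance_high, pi)
            lat_cool_iso = cfg.latitude_of(sp.tolerance_low, pi)
            equa = float(np.clip(lat_warm_iso, cfg.lat_min, cfg.lat_max))
            pole = float(np.clip(lat_cool_iso, cfg.lat_min, cfg.lat_max))
            cap = sp.cap_for_period(pi)
            if cap is not None:
                pole = min(pole, cap)
            margins[(pi, "poleward")] = pole
            margins[(pi, "equatorward")] = equa
            rec[f"{plabel}_poleward_margin_lat"] = pole
            rec[f"{plabel}_equatorward_margin_lat"] = equa
            rec[f"{plabel}_warm_limit_T"] = cfg.temperature_at(equa, pi)
            rec[f"{plabel}_cool_limit_T"] = cfg.temperature_at(pole, pi)
            rec[f"{plabel}_env_distance_poleward"] = 0.0
            rec[f"{plabel}_env_distance_equatorward"] = 0.0
        for side in ("poleward", "equatorward"):
            disp = (margins[(1, side)] - margins[(0, side)]) * KM_PER_DEGREE_LATITUDE
            rec[f"displacement_{side}_km"] = disp
            rec[f"rate_{side}_km_per_decade"] = per_decade_rate(
                disp, cfg.period1, cfg.period2
            )
        rows.append(rec)
    return pd.DataFrame(rows)


def sample_species_truths(
    cfg: ScenarioConfig,
    n_species: int,
    seed: int,
    cap_fraction: float = 0.0,
    cap_offset_deg: float = 2.0,
    detection_prob: float = 1.0,
    extinction_sensitivity: float = 0.0,
    tracking_caps: bool = False,
) -> list[SpeciesTruth]:
    """Draw a community of species whose niches fit inside the domain.

    Tolerance windows are placed so both thermal edges fall strictly inside
    the domain's temperature range in both periods. A ``cap_fraction`` of
    species get a poleward cap ``cap_offset_deg`` degrees south of their
    cool-tolerance isocline (a non-thermal margin); with ``tracking_caps``
    the cap moves with the warming so the whole range translates.
    """
    rng = np.random.default_rng([seed, 7919])
    t_cold = cfg.temperature_at(cfg.lat_max, 0)
    t_hot = cfg.temperature_at(cfg.lat_min, 0)
    span = t_hot - t_cold
    out = []
    for i in range(n_species):
        breadth = rng.uniform(0.25, 0.45) * span
        low = rng.uniform(t_cold + 0.15 * span, t_hot - breadth - 0.15 * span)
        t_opt = low + breadth / 2.0
        capped = rng.random() < cap_fraction
        cap = cap2 = None
        if capped:
            cap = cfg.latitude_of(low, 0) - cap_offset_deg
            if tracking_caps:
                cap2 = cfg.latitude_of(low, 1) - cap_offset_deg
        out.append(
            SpeciesTruth(
                species_id=f"SP{i:03d}",
                T_opt=float(t_opt),
                tolerance_low=float(low),
                tolerance_high=float(low + breadth),
                poleward_cap_latitude=cap,
                poleward_cap_latitude_p2=cap2,
                detection_prob=detection_prob,
                peak_abundance=float(rng.uniform(5.0, 20.0)),
                extinction_sensitivity=extinction_sensitivity,
            )
        )
    return out
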