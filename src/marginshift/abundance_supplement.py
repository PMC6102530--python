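"""Fixed-site abundance-change analyses at margins and thermal limits.

Holding the historical (period-1) margin and thermal-limit route sets
constant, these analyses ask whether abundance changed where the climate
did. A site occupied in period 1 but empty in period 2 counts as a local
population extinction; every summary is computed both with those sites
included (extinction = loss of the whole period-1 abundance) and with them
excluded (guarding against non-detection masquerading as extinction).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .niche_metrics import MarginSet, ThermalLimitSet
from .route_climate import (
    BREEDING_MONTHS,
    DEFAULT_BUFFER_KM,
    MarginShiftError,
    MonthlyTemperatureGrid,
    PeriodWindow,
    buffer_season_means,
)
from .shift_analysis import FitResult, margin_limit_regression

SITE_CLASSES = (
    "poleward_margin",
    "equatorward_margin",
    "cool_limit",
    "warm_limit",
)


@dataclass(frozen=True)
class FixedSiteChange:
    """Mean abundance and temperature change over one species' fixed sites."""

    species_id: str
    site_class: str
    mean_delta_abundance: float
    mean_delta_T: float
    n_sites: int
    n_extinct_sites: int
    include_extinct: bool


def site_class_of(site_set: MarginSet | ThermalLimitSet) -> str:
    if isinstance(site_set, MarginSet):
        return f"{site_set.side}_margin"
    return f"{site_set.direction}_limit"


def fixed_site_changes(
    obs: pd.DataFrame,
    grid: MonthlyTemperatureGrid,
    site_set: MarginSet | ThermalLimitSet,
    routes: pd.DataFrame,
    period1: PeriodWindow,
    period2: PeriodWindow,
    include_extinct: bool = True,
    buffer_km: float = DEFAULT_BUFFER_KM,
    months: Sequence[int] = BREEDING_MONTHS,
) -> FixedSiteChange:
    """Per-species mean abundance and temperature change at fixed sites.

    Site abundance in a period is the species' summed count over the
    period's years (zero in period 2 marks the site extinct). The site
    temperature change is the all-years between-period difference in mean
    breeding-season temperature, never conditioned on observation.
    """
    species = site_set.species_id
    sel_routes = routes[routes["route_id"].isin(site_set.route_ids)]
    missing = set(site_set.route_ids) - set(sel_routes["route_id"])
    if missing:
        raise MarginShiftError(f"no coordinates for sites: {sorted(missing)}")

    sp_obs = obs[(obs["species_id"] == species) & (obs["count"] > 0)]

    def period_abundance(period: PeriodWindow) -> pd.Series:
        sub = sp_obs[sp_obs["year"].isin(period.years)]
        totals = sub.groupby("route_id")["count"].sum()
        return totals.reindex(list(site_set.route_ids), fill_value=0)

    a1 = period_abundance(period1)
    a2 = period_abundance(period2)
    never = a1[a1 == 0].index.tolist()
    if never:
        raise MarginShiftError(
            f"site(s) never occupied by {species!r} in {period1.label}: {never}"
        )

    t1 = (
        buffer_season_means(grid, sel_routes, period1.years, buffer_km, months)
        .groupby("route_id")["T"]
        .mean()
    )
    t2 = (
        buffer_season_means(grid, sel_routes, period2.years, buffer_km, months)
        .groupby("route_id")["T"]
        .mean()
    )
    delta_t = (t2 - t1).reindex(list(site_set.route_ids))
    delta_a = a2 - a1
    extinct = a2 == 0

    if include_extinct:
        keep = pd.Series(True, index=delta_a.index)
    else:
        keep = ~extinct
    if keep.sum() == 0:
        # every site lost: with extinct sites excluded there is nothing to
        # average, so report NaN rather than fabricating a change
        mean_da, mean_dt = float("nan"), float("nan")
    else:
        mean_da = float(delta_a[keep].mean())
        mean_dt = float(delta_t[keep].mean())
    return FixedSiteChange(
        species_id=species,
        site_class=site_class_of(site_set),
        mean_delta_abundance=mean_da,
        mean_delta_T=mean_dt,
        n_sites=int(len(site_set.route_ids)),
        n_extinct_sites=int(extinct.sum()),
        include_extinct=include_extinct,
    )


def abundance_temperature_regression(
    changes: Sequence[FixedSiteChange],
) -> FitResult:
    """OLS of per-species mean abundance change on mean temperature change."""
    rows = [c for c in changes if np.isfinite(c.mean_delta_abundance)]
    if len(rows) < 3:
        raise ValueError("need >= 3 species with defined changes")
    x = [c.mean_delta_T for c in rows]
    y = [c.mean_delta_abundance for c in rows]
    return margin_limit_regression(x, y)


def supplement_table(changes: Sequence[FixedSiteChange]) -> pd.DataFrame:
    """Long-form export of fixed-site changes (site class x extinction handling)."""
    return pd.DataFrame(
        [
            {
                "species_id": c.species_id,
                "site_class": c.site_class,
                "include_extinct": c.include_extinct,
                "mean_delta_abundance": c.mean_delta_abundance,
                "mean_delta_T": c.mean_delta_T,
                "n_sites": c.n_sites,
                "n_extinct_sites": c.n_extinct_sites,
            }
            for c in changes
        ]
    )
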