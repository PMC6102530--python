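"""Species and study-region selection filters with an audit trail.

The screening mirrors the selection rules of continental survey studies:
clip the study region at a maximum latitude (low sampling density further
poleward), then retain only species that are abundant enough (total
individuals per period), widespread enough (unique occupied routes per
period), have their historical poleward margin far enough from the study
edge to leave room for detectable expansion, and are not on a manual
exclusion list (disjunct / coastal / non-native species, which no formula
can identify from counts alone).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .route_climate import PeriodWindow

logger = logging.getLogger(__name__)

#: Criterion order used for the "first_failed" column of the report.
CRITERIA_ORDER = (
    "min_individuals_per_period",
    "min_routes_per_period",
    "max_historical_poleward_margin",
    "manual_exclusion",
)


@dataclass(frozen=True)
class ScreeningCriteria:
    """Thresholds for the study-region clip and the species filters.

    Defaults are the original study design: routes south of 52°N only;
    >=100 individuals and >=30 unique occupied routes in each period;
    historical poleward margin at or below 49°N (leaving ~3° of sampled
    climate space for poleward expansion to be detectable).
    """

    max_study_latitude: float = 52.0
    max_historical_poleward_margin: float = 49.0
    min_individuals_per_period: int = 100
    min_routes_per_period: int = 30
    manual_exclusions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if min(
            self.max_study_latitude,
            self.max_historical_poleward_margin,
            self.min_individuals_per_period,
            self.min_routes_per_period,
        ) <= 0:
            raise ValueError("all screening thresholds must be positive")
        for sp, reason in self.manual_exclusions.items():
            if not str(reason).strip():
                raise ValueError(f"manual exclusion for {sp!r} must give a reason")


def clip_study_region(obs: pd.DataFrame, criteria: ScreeningCriteria) -> pd.DataFrame:
    """Drop observations on routes at or above the maximum study latitude.

    The clip is strict: a route at exactly the boundary latitude is removed.
    """
    keep = obs["latitude"] < criteria.max_study_latitude
    removed_routes = obs.loc[~keep, "route_id"].nunique()
    if removed_routes:
        logger.info(
            "study-region clip at %.1f°N removed %d route(s)",
            criteria.max_study_latitude,
            removed_routes,
        )
    return obs.loc[keep].reset_index(drop=True)


def filter_species(
    obs: pd.DataFrame,
    criteria: ScreeningCriteria,
    period1: PeriodWindow,
    period2: PeriodWindow,
) -> tuple[list[str], pd.DataFrame]:
    """Apply the species filters; return (retained ids, per-species report).

    A species is retained iff all of the following hold:

    * summed individuals >= ``min_individuals_per_period`` in EACH period;
    * unique occupied routes >= ``min_routes_per_period`` in EACH period;
    * maximum occupied-route latitude in the historical (first) period
      <= ``max_historical_poleward_margin`` (inclusive boundary);
    * not on the manual exclusion list.

    The report has one row per species with a boolean column per criterion,
    the retained flag, and the first failing criterion (in the fixed order
    abundance, routes, margin, manual) — empty when retained.
    """
    present = obs[obs["count"] > 0]
    species = sorted(present["species_id"].unique())

    def per_period(period: PeriodWindow) -> pd.DataFrame:
        sub = present[present["year"].isin(period.years)]
        return sub.groupby("species_id").agg(
            individuals=("count", "sum"),
            routes=("route_id", "nunique"),
            max_latitude=("latitude", "max"),
        )

    p1 = per_period(period1)
    p2 = per_period(period2)

    rows = []
    for sp in species:
        ind1 = int(p1["individuals"].get(sp, 0))
        ind2 = int(p2["individuals"].get(sp, 0))
        r1 = int(p1["routes"].get(sp, 0))
        r2 = int(p2["routes"].get(sp, 0))
        hist_max_lat = float(p1["max_latitude"].get(sp, float("nan")))
        checks = {
            "min_individuals_per_period": min(ind1, ind2)
            >= criteria.min_individuals_per_period,
            "min_routes_per_period": min(r1, r2) >= criteria.min_routes_per_period,
            # absent from the historical period -> margin undefined -> fail
            "max_historical_poleward_margin": (
                hist_max_lat == hist_max_lat
                and hist_max_lat <= criteria.max_historical_poleward_margin
            ),
            "manual_exclusion": sp not in criteria.manual_exclusions,
        }
        retained = all(checks.values())
        first_failed = next((c for c in CRITERIA_ORDER if not checks[c]), "")
        rows.append(
            {
                "species_id": sp,
                "individuals_period1": ind1,
                "individuals_period2": ind2,
                "routes_period1": r1,
                "routes_period2": r2,
                "historical_max_latitude": hist_max_lat,
                **checks,
                "retained": retained,
                "first_failed": first_failed,
                "exclusion_reason": criteria.manual_exclusions.get(sp, ""),
            }
        )
    report = pd.DataFrame(rows)
    retained_ids = report.loc[report["retained"], "species_id"].tolist() if rows else []
    if not retained_ids:
        logger.warning("species screen retained no species")
    return retained_ids, report
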