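"""Range-margin sets, realized thermal-limit sets and niche summaries.

A species' range margin on one side is operationalized as its k (default 10)
latitude-extreme occupied routes in a period; its realized thermal-niche
limit in a direction as the k thermally extreme occupied routes. Both carry
an abundance-weighted mean breeding-season temperature: routes where more
individuals were counted pull the mean harder. The environmental distance is
the temperature gap between a margin and the matching thermal limit — zero
when the margin sits exactly at the species' realized thermal extreme, and
positive when the margin is held short of it by something other than
temperature.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .route_climate import MarginShiftError

#: Routes per margin / thermal-limit set.
DEFAULT_SET_SIZE = 10

Side = Literal["poleward", "equatorward"]
Direction = Literal["warm", "cool"]


@dataclass(frozen=True)
class MarginSet:
    """The k latitude-extreme occupied routes of a species on one side."""

    species_id: str
    period: str
    side: Side
    route_ids: tuple[str, ...]
    mean_latitude: float
    weighted_T: float
    small_set: bool = False  # fewer occupied routes than k: all were used


@dataclass(frozen=True)
class ThermalLimitSet:
    """The k thermally extreme occupied routes of a species in one direction."""

    species_id: str
    period: str
    direction: Direction
    route_ids: tuple[str, ...]
    weighted_T: float
    small_set: bool = False


@dataclass(frozen=True)
class NicheSummary:
    species_id: str
    period: str
    centroid_T: float
    env_distance_poleward: float
    env_distance_equatorward: float


def abundance_weighted_mean_temperature(
    temperatures: Sequence[float], counts: Sequence[float]
) -> float:
    """Sum(T_i * c_i) / Sum(c_i) over member routes.

    Each route's observation-conditional mean temperature is weighted by the
    total abundance recorded there over the years of observation.
    """
    t = np.asarray(temperatures, dtype=float)
    c = np.asarray(counts, dtype=float)
    if t.shape != c.shape or t.size == 0:
        raise ValueError("temperatures and counts must be equal-length and non-empty")
    total = c.sum()
    if total <= 0:
        raise MarginShiftError("total abundance is zero; weighted mean undefined")
    return float((t * c).sum() / total)


def _take_extreme(
    route_temps: pd.DataFrame, by: str, ascending: bool, k: int
) -> tuple[pd.DataFrame, bool]:
    """Top-k rows of the route table ordered by ``by``; ties by route_id."""
    if route_temps.empty:
        raise MarginShiftError("empty occupied-route set")
    if k < 1:
        raise ValueError("k must be >= 1")
    ordered = route_temps.sort_values(
        [by, "route_id"], ascending=[ascending, True], kind="mergesort"
    )
    small = len(ordered) < k
    return ordered.head(k), small


def margin_route_set(
    route_temps: pd.DataFrame,
    side: Side,
    k: int = DEFAULT_SET_SIZE,
    species_id: str = "",
    period: str = "",
) -> MarginSet:
    """The k most poleward (or equatorward) occupied routes for one species.

    ``route_temps`` is the single-species slice of the per-route temperature
    table (columns ``route_id, latitude, mean_T, total_count``). Sorting is
    by latitude — descending for the poleward side, ascending for the
    equatorward side — with ties broken by ascending route_id. If fewer than
    k routes are occupied, all of them are used and ``small_set`` is set.
    """
    if side not in ("poleward", "equatorward"):
        raise ValueError(f"unknown side {side!r}")
    members, small = _take_extreme(route_temps, "latitude", side == "equatorward", k)
    return MarginSet(
        species_id=species_id or _only(route_temps, "species_id"),
        period=period,
        side=side,
        route_ids=tuple(members["route_id"]),
        mean_latitude=float(members["latitude"].mean()),
        weighted_T=abundance_weighted_mean_temperature(
            members["mean_T"], members["total_count"]
        ),
        small_set=small,
    )


def thermal_limit_route_set(
    route_temps: pd.DataFrame,
    direction: Direction,
    k: int = DEFAULT_SET_SIZE,
    species_id: str = "",
    period: str = "",
) -> ThermalLimitSet:
    """The k warmest (or coolest) occupied routes for one species."""
    if direction not in ("warm", "cool"):
        raise ValueError(f"unknown direction {direction!r}")
    members, small = _take_extreme(route_temps, "mean_T", direction == "cool", k)
    return ThermalLimitSet(
        species_id=species_id or _only(route_temps, "species_id"),
        period=period,
        direction=direction,
        route_ids=tuple(members["route_id"]),
        weighted_T=abundance_weighted_mean_temperature(
            members["mean_T"], members["total_count"]
        ),
        small_set=small,
    )


def _only(df: pd.DataFrame, col: str) -> str:
    if col in df.columns and df[col].nunique() == 1:
        return str(df[col].iloc[0])
    return ""


def niche_centroid(route_temps: pd.DataFrame) -> float:
    """Abundance-weighted mean breeding-season temperature over ALL occupied routes."""
    if route_temps.empty:
        raise MarginShiftError("empty occupied-route set")
    return abundance_weighted_mean_temperature(
        route_temps["mean_T"], route_temps["total_count"]
    )


def breadth_adjusted_temperature(
    T: float,
    centroid_T: float,
    mode: Literal["deviation", "ratio"] = "deviation",
    breadth: float | None = None,
) -> float:
    """Temperature corrected for the species' thermal-niche breadth.

    The default (and primary) form is the signed deviation ``T - centroid``.
    The alternative ``ratio`` form divides that deviation by the species'
    total realized breadth (warm-limit minus cool-limit temperature), for
    sensitivity runs.
    """
    if not (np.isfinite(T) and np.isfinite(centroid_T)):
        raise ValueError("temperature and centroid must be finite")
    dev = float(T - centroid_T)
    if mode == "deviation":
        return dev
    if mode == "ratio":
        if breadth is None or breadth <= 0:
            raise ValueError("ratio mode needs a positive total niche breadth")
        return dev / float(breadth)
    raise ValueError(f"unknown breadth-correction mode {mode!r}")


def environmental_distance(margin: MarginSet, limit: ThermalLimitSet) -> float:
    """Temperature gap (°C) between a range margin and its thermal limit.

    Poleward margins pair with the cool limit (gap = margin T - limit T);
    equatorward margins with the warm limit (gap = limit T - margin T). Both
    are >= 0 when margin and limit come from the same occupied-route pool.
    """
    pairing = {"poleward": "cool", "equatorward": "warm"}
    if limit.direction != pairing[margin.side]:
        raise MarginShiftError(
            f"{margin.side} margin must pair with {pairing[margin.side]} limit, "
            f"got {limit.direction}"
        )
    if margin.species_id and limit.species_id and margin.species_id != limit.species_id:
        raise MarginShiftError(
            f"species mismatch: {margin.species_id!r} vs {limit.species_id!r}"
        )
    if margin.side == "poleward":
        return float(margin.weighted_T - limit.weighted_T)
    return float(limit.weighted_T - margin.weighted_T)


def niche_summary(
    route_temps: pd.DataFrame,
    species_id: str = "",
    period: str = "",
    k: int = DEFAULT_SET_SIZE,
) -> NicheSummary:
    """Centroid and both environmental distances for one species x period."""
    pole = margin_route_set(route_temps, "poleward", k, species_id, period)
    equa = margin_route_set(route_temps, "equatorward", k, species_id, period)
    cool = thermal_limit_route_set(route_temps, "cool", k, species_id, period)
    warm = thermal_limit_route_set(route_temps, "warm", k, species_id, period)
    return NicheSummary(
        species_id=species_id or _only(route_temps, "species_id"),
        period=period,
        centroid_T=niche_centroid(route_temps),
        env_distance_poleward=environmental_distance(pole, cool),
        env_distance_equatorward=environmental_distance(equa, warm),
    )


def species_metrics_table(
    route_temps: pd.DataFrame, period_label: str, k: int = DEFAULT_SET_SIZE
) -> pd.DataFrame:
    """Per-species metrics for one period, in export-ready long form.

    ``route_temps`` holds all species (column ``species_id``). One row per
    species x set (two margin sides + two thermal directions) with member
    route ids semicolon-joined, plus the centroid and both environmental
    distances repeated for convenience.
    """
    rows = []
    for sp, sub in route_temps.groupby("species_id"):
        summary = niche_summary(sub, str(sp), period_label, k)
        sets: list[tuple[str, MarginSet | ThermalLimitSet]] = [
            ("margin_poleward", margin_route_set(sub, "poleward", k, str(sp), period_label)),
            ("margin_equatorward", margin_route_set(sub, "equatorward", k, str(sp), period_label)),
            ("limit_cool", thermal_limit_route_set(sub, "cool", k, str(sp), period_label)),
            ("limit_warm", thermal_limit_route_set(sub, "warm", k, str(sp), period_label)),
        ]
        for name, s in sets:
            rows.append(
                {
                    "species_id": sp,
                    "period": period_label,
                    "set": name,
                    "routes": ";".join(s.route_ids),
                    "weighted_T": s.weighted_T,
                    "mean_latitude": getattr(s, "mean_latitude", float("nan")),
                    "small_set": s.small_set,
                    "centroid_T": summary.centroid_T,
                    "env_distance_poleward": summary.env_distance_poleward,
                    "env_distance_equatorward": summary.env_distance_equatorward,
                }
            )
    return pd.DataFrame(rows)
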