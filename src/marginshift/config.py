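"""YAML-backed run configuration for the analysis and simulation CLIs."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import yaml

from .route_climate import (
    BREEDING_MONTHS,
    DEFAULT_BUFFER_KM,
    HISTORICAL_PERIOD,
    MODERN_PERIOD,
    PeriodWindow,
)
from .species_screen import ScreeningCriteria
from .synthetic_data import ScenarioConfig


def _period(raw: dict | Sequence | None, default: PeriodWindow) -> PeriodWindow:
    if raw is None:
        return default
    if isinstance(raw, dict):
        return PeriodWindow(
            str(raw.get("label", f"{raw['start_year']}-{raw['end_year']}")),
            int(raw["start_year"]),
            int(raw["end_year"]),
        )
    start, end = int(raw[0]), int(raw[1])
    return PeriodWindow(f"{start}-{end}", start, end)


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one analysis run.

    ``climate_format`` is "netcdf" or "csv" (long-format table); species
    labels, if given, point at a CSV with columns ``species_id,label`` used
    by ``--subset`` reruns.
    """

    observations: Path
    climate: Path
    climate_format: str = "netcdf"
    period1: PeriodWindow = HISTORICAL_PERIOD
    period2: PeriodWindow = MODERN_PERIOD
    months: tuple[int, ...] = BREEDING_MONTHS
    buffer_km: float = DEFAULT_BUFFER_KM
    set_size: int = 10
    breadth_mode: str = "deviation"
    criteria: ScreeningCriteria = field(default_factory=ScreeningCriteria)
    species_labels: Path | None = None
    output_dir: Path = Path("marginshift_output")


def load_run_config(path: str | Path) -> RunConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    crit = raw.get("criteria", {})
    criteria = ScreeningCriteria(
        max_study_latitude=float(crit.get("max_study_latitude", 52.0)),
        max_historical_poleward_margin=float(
            crit.get("max_historical_poleward_margin", 49.0)
        ),
        min_individuals_per_period=int(crit.get("min_individuals_per_period", 100)),
        min_routes_per_period=int(crit.get("min_routes_per_period", 30)),
        manual_exclusions=dict(crit.get("manual_exclusions", {})),
    )
    base = Path(path).parent
    periods = raw.get("periods", {})
    return RunConfig(
        observations=base / raw["observations"],
        climate=base / raw["climate"],
        climate_format=str(raw.get("climate_format", "netcdf")),
        period1=_period(periods.get("period1"), HISTORICAL_PERIOD),
        period2=_period(periods.get("period2"), MODERN_PERIOD),
        months=tuple(int(m) for m in raw.get("months", BREEDING_MONTHS)),
        buffer_km=float(raw.get("buffer_km", DEFAULT_BUFFER_KM)),
        set_size=int(raw.get("set_size", 10)),
        breadth_mode=str(raw.get("breadth_mode", "deviation")),
        criteria=criteria,
        species_labels=(base / raw["species_labels"]) if raw.get("species_labels") else None,
        output_dir=base / raw.get("output_dir", "marginshift_output"),
    )


def load_scenario_config(path: str | Path) -> ScenarioConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    periods = raw.pop("periods", {})
    kwargs = dict(raw)
    if "period1" in periods or "period2" in periods:
        kwargs["period1"] = _period(periods.get("period1"), HISTORICAL_PERIOD)
        kwargs["period2"] = _period(periods.get("period2"), MODERN_PERIOD)
    if "month_offsets" in kwargs:
        kwargs["month_offsets"] = tuple(float(x) for x in kwargs["month_offsets"])
    return ScenarioConfig(**kwargs)
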