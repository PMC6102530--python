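"""End-to-end orchestration: observations + climate -> metrics, shifts, fits.

The stages run in the order the method is defined: clip the study region,
screen species, build observation-conditional route temperatures for each
period, extract margin and thermal-limit sets, summarize niches, compute
between-period displacements with direction coding, then run the
statistical battery (margin-vs-limit OLS and paired t per side, temporal
gap regression per side, logistic shift-probability model per side, mean
shift rates and net extent change) and the fixed-site abundance supplement.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import abundance_supplement as supp
from . import niche_metrics as nm
from . import shift_analysis as sa
from .route_climate import (
    BREEDING_MONTHS,
    DEFAULT_BUFFER_KM,
    MonthlyTemperatureGrid,
    PeriodWindow,
    route_temperature_table,
    routes_from_observations,
)
from .species_screen import ScreeningCriteria, clip_study_region, filter_species

logger = logging.getLogger(__name__)

SIDES = ("poleward", "equatorward")
PAIRED_LIMIT = {"poleward": "cool", "equatorward": "warm"}


@dataclass
class AnalysisResult:
    """Everything the pipeline produces, ready for export."""

    retained_species: list[str]
    screening_report: pd.DataFrame
    metrics: pd.DataFrame  # per species x period x set
    shifts: pd.DataFrame  # per species x side displacement/coding
    fits: dict[str, sa.FitResult]
    summary: dict[str, float]
    supplement: pd.DataFrame = field(default_factory=pd.DataFrame)
    supplement_fits: dict[str, sa.FitResult] = field(default_factory=dict)

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.screening_report.to_csv(outdir / "screening_report.csv", index=False)
        self.metrics.to_csv(outdir / "metrics.csv", index=False)
        self.shifts.to_csv(outdir / "shifts.csv", index=False)
        if not self.supplement.empty:
            self.supplement.to_csv(outdir / "supplement.csv", index=False)
        fits = {name: f.to_dict() for name, f in self.fits.items()}
        fits.update({name: f.to_dict() for name, f in self.supplement_fits.items()})
        report = {"summary": self.summary, "fits": fits}
        (outdir / "fits.json").write_text(json.dumps(report, indent=2, default=float))
        flat = [
            {"fit": name, **{f"param_{k}": v for k, v in f.params.items()},
             **{f"p_{k}": v for k, v in f.pvalues.items()},
             "r_squared": f.r_squared, "loglik": f.loglik, "n": f.n}
            for name, f in {**self.fits, **self.supplement_fits}.items()
        ]
        pd.DataFrame(flat).to_csv(outdir / "fits.csv", index=False)


def species_sets(
    rt: pd.DataFrame, period_label: str, k: int
) -> dict[str, dict[str, object]]:
    """Per-species margin/limit sets and niche summary for one period."""
    out: dict[str, dict[str, object]] = {}
    for sp, sub in rt.groupby("species_id"):
        sp = str(sp)
        out[sp] = {
            "margin_poleward": nm.margin_route_set(sub, "poleward", k, sp, period_label),
            "margin_equatorward": nm.margin_route_set(
                sub, "equatorward", k, sp, period_label
            ),
            "limit_cool": nm.thermal_limit_route_set(sub, "cool", k, sp, period_label),
            "limit_warm": nm.thermal_limit_route_set(sub, "warm", k, sp, period_label),
            "summary": nm.niche_summary(sub, sp, period_label, k),
            "centroid": nm.niche_centroid(sub),
        }
    return out


def run_analysis(
    obs: pd.DataFrame,
    grid: MonthlyTemperatureGrid,
    period1: PeriodWindow,
    period2: PeriodWindow,
    criteria: ScreeningCriteria | None = None,
    buffer_km: float = DEFAULT_BUFFER_KM,
    months: Sequence[int] = BREEDING_MONTHS,
    k: int = nm.DEFAULT_SET_SIZE,
    breadth_mode: str = "deviation",
    with_supplement: bool = True,
    species_subset: Sequence[str] | None = None,
) -> AnalysisResult:
    """Run the full analysis; see the module docstring for stage order.

    ``species_subset`` restricts the retained species (after screening) to a
    labeled subgroup, for the migrant-guild / coastal-boundary reruns.
    """
    criteria = criteria or ScreeningCriteria()
    obs = clip_study_region(obs, criteria)
    retained, report = filter_species(obs, criteria, period1, period2)
    if species_subset is not None:
        retained = [s for s in retained if s in set(species_subset)]
    obs_r = obs[obs["species_id"].isin(retained)]
    routes = routes_from_observations(obs)

    rt1 = route_temperature_table(obs_r, grid, period1, buffer_km, months)
    rt2 = route_temperature_table(obs_r, grid, period2, buffer_km, months)
    sets1 = species_sets(rt1, period1.label, k)
    sets2 = species_sets(rt2, period2.label, k)
    both = [sp for sp in retained if sp in sets1 and sp in sets2]
    if len(both) < len(retained):
        logger.warning(
            "%d retained species lack occupied routes in one period and are "
            "dropped from shift analyses",
            len(retained) - len(both),
        )

    metrics = pd.concat(
        [
            nm.species_metrics_table(rt1, period1.label, k),
            nm.species_metrics_table(rt2, period2.label, k),
        ],
        ignore_index=True,
    )

    # --- displacement and direction coding -------------------------------
    shift_rows = []
    for sp in both:
        for side in SIDES:
            m1 = sets1[sp][f"margin_{side}"]
            m2 = sets2[sp][f"margin_{side}"]
            delta_t = sa.local_margin_temperature_change(
                m1, grid, routes, period1, period2, buffer_km, months
            )
            rec = sa.build_shift_record(sp, side, m1, m2, delta_t, period1, period2)
            limit1 = sets1[sp][f"limit_{PAIRED_LIMIT[side]}"]
            shift_rows.append(
                {
                    "species_id": sp,
                    "side": side,
                    "displacement_km": rec.displacement_km,
                    "rate_km_per_decade": rec.rate_km_per_decade,
                    "delta_T_margin": rec.delta_T_margin,
                    "expected_direction": rec.expected_direction,
                    "outcome": rec.outcome,
                    "zero_delta_T": rec.zero_delta_T,
                    "env_distance_t1": nm.environmental_distance(m1, limit1),
                }
            )
    shifts = pd.DataFrame(shift_rows)

    # --- statistical battery ----------------------------------------------
    fits: dict[str, sa.FitResult] = {}
    summary: dict[str, float] = {"n_species": float(len(both))}

    def adj(sp: str, sets: dict, key: str) -> float:
        s = sets[sp][key]
        centroid = sets[sp]["centroid"]
        breadth = (
            sets[sp]["limit_warm"].weighted_T - sets[sp]["limit_cool"].weighted_T
        )
        return nm.breadth_adjusted_temperature(
            s.weighted_T, centroid, breadth_mode, breadth or None
        )

    if len(both) >= 3:
        for side in SIDES:
            limit_key = f"limit_{PAIRED_LIMIT[side]}"
            x = [adj(sp, sets1, limit_key) for sp in both]
            y = [adj(sp, sets1, f"margin_{side}") for sp in both]
            try:
                fits[f"margin_limit_ols_{side}"] = sa.margin_limit_regression(x, y)
            except Exception as exc:  # zero variance in degenerate scenarios
                logger.warning("margin-limit OLS (%s) skipped: %s", side, exc)
            margin_T = [sets1[sp][f"margin_{side}"].weighted_T for sp in both]
            limit_T = [sets1[sp][limit_key].weighted_T for sp in both]
            fits[f"margin_limit_paired_t_{side}"] = sa.paired_mean_difference_test(
                margin_T, limit_T
            )
            gaps1 = [sets1[sp]["summary"].__getattribute__(f"env_distance_{side}") for sp in both]
            gaps2 = [sets2[sp]["summary"].__getattribute__(f"env_distance_{side}") for sp in both]
            try:
                fits[f"temporal_gap_{side}"] = sa.temporal_gap_regression(gaps1, gaps2)
            except Exception as exc:
                logger.warning("temporal gap regression (%s) skipped: %s", side, exc)

    for side in SIDES:
        sub = shifts[shifts["side"] == side] if not shifts.empty else pd.DataFrame()
        if len(sub) >= 10 and sub["outcome"].nunique() == 2:
            fits[f"shift_probability_{side}"] = sa.shift_probability_model(
                sub["env_distance_t1"], sub["outcome"]
            )
        if not sub.empty:
            summary[f"mean_rate_{side}_km_per_decade"] = float(
                sub["rate_km_per_decade"].mean()
            )
            summary[f"se_rate_{side}_km_per_decade"] = float(
                sub["rate_km_per_decade"].std(ddof=1) / np.sqrt(len(sub))
            ) if len(sub) > 1 else float("nan")
    if (
        "mean_rate_poleward_km_per_decade" in summary
        and "mean_rate_equatorward_km_per_decade" in summary
    ):
        summary["extent_change_km_per_decade"] = sa.extent_change_rate(
            summary["mean_rate_poleward_km_per_decade"],
            summary["mean_rate_equatorward_km_per_decade"],
        )

    result = AnalysisResult(
        retained_species=list(both),
        screening_report=report,
        metrics=metrics,
        shifts=shifts,
        fits=fits,
        summary=summary,
    )

    # --- fixed-site abundance supplement ----------------------------------
    if with_supplement and both:
        changes: list[supp.FixedSiteChange] = []
        for sp in both:
            for key in ("margin_poleward", "margin_equatorward", "limit_cool", "limit_warm"):
                for include in (True, False):
                    changes.append(
                        supp.fixed_site_changes(
                            obs_r,
                            grid,
                            sets1[sp][key],
                            routes,
                            period1,
                            period2,
                            include_extinct=include,
                            buffer_km=buffer_km,
                            months=months,
                        )
                    )
        result.supplement = supp.supplement_table(changes)
        for site_class in supp.SITE_CLASSES:
            for include in (True, False):
                group = [
                    c
                    for c in changes
                    if c.site_class == site_class and c.include_extinct == include
                ]
                tag = "with_extinct" if include else "without_extinct"
                try:
                    result.supplement_fits[f"abundance_{site_class}_{tag}"] = (
                        supp.abundance_temperature_regression(group)
                    )
                except Exception as exc:
                    logger.warning(
                        "abundance regression (%s, %s) skipped: %s",
                        site_class,
                        tag,
                        exc,
                    )
    return result
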