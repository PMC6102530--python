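"""Between-period margin displacement and the statistical battery.

Displacement is the change in a margin set's mean latitude converted to
kilometers (positive poleward), scaled to km/decade over the gap between
period midpoints. Each species' shift is coded 1 when it went in the
direction expected from the local temperature change at its historical
margin routes (warming -> poleward expected, cooling -> equatorward), and 0
otherwise. The fits are ordinary least squares for margin-vs-limit and
temporal-gap relationships, paired t-tests for mean temperature gaps, and a
maximum-likelihood logistic regression of the shift outcome on thermal
proximity with a likelihood-ratio significance test.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .niche_metrics import MarginSet
from .route_climate import (
    BREEDING_MONTHS,
    DEFAULT_BUFFER_KM,
    MarginShiftError,
    MonthlyTemperatureGrid,
    PeriodWindow,
    buffer_season_means,
)

logger = logging.getLogger(__name__)

#: Meridian arc length of one degree of latitude on a spherical Earth, km.
KM_PER_DEGREE_LATITUDE = 111.195


@dataclass(frozen=True)
class ShiftRecord:
    """Per-species, per-side displacement and its direction coding."""

    species_id: str
    side: str
    displacement_km: float
    rate_km_per_decade: float
    delta_T_margin: float
    expected_direction: str
    outcome: int
    zero_delta_T: bool = False  # ΔT was exactly 0; poleward expected by convention


@dataclass(frozen=True)
class FitResult:
    """Uniform container for regression / test output.

    ``params``, ``statistics`` and ``pvalues`` are keyed by term name
    (e.g. ``slope``, ``proximity``, ``lr``); ``flags`` records degenerate
    conditions (separation, zero-variance, ...).
    """

    method: str
    n: int
    df: float
    params: dict[str, float] = field(default_factory=dict)
    statistics: dict[str, float] = field(default_factory=dict)
    pvalues: dict[str, float] = field(default_factory=dict)
    r_squared: float | None = None
    loglik: float | None = None
    flags: tuple[str, ...] = ()

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "n": self.n,
            "df": self.df,
            "params": self.params,
            "statistics": self.statistics,
            "pvalues": self.pvalues,
            "r_squared": self.r_squared,
            "loglik": self.loglik,
            "flags": list(self.flags),
        }


# ---------------------------------------------------------------------------
# Displacement arithmetic
# ---------------------------------------------------------------------------


def margin_displacement_km(margin_t1: MarginSet, margin_t2: MarginSet) -> float:
    """Signed poleward displacement (km) of a margin between two periods."""
    if margin_t1.species_id != margin_t2.species_id or margin_t1.side != margin_t2.side:
        raise MarginShiftError(
            "displacement requires the same species and side in both periods"
        )
    if margin_t1.period == margin_t2.period:
        raise MarginShiftError("displacement requires two distinct periods")
    return float(
        (margin_t2.mean_latitude - margin_t1.mean_latitude) * KM_PER_DEGREE_LATITUDE
    )


def per_decade_rate(
    displacement_km: float, period1: PeriodWindow, period2: PeriodWindow
) -> float:
    """Displacement scaled to km/decade over the period-midpoint gap."""
    elapsed = period2.midpoint_year - period1.midpoint_year
    if elapsed == 0:
        raise MarginShiftError("periods have identical midpoints; rate undefined")
    return float(displacement_km * 10.0 / elapsed)


def extent_change_rate(poleward_rate: float, equatorward_rate: float) -> float:
    """Net change in latitudinal range extent, km/decade (negative = contraction).

    Both inputs are poleward-positive margin shift rates; the extent grows
    when the poleward margin outruns the equatorward one.
    """
    return float(poleward_rate - equatorward_rate)


def local_margin_temperature_change(
    margin_t1: MarginSet,
    grid: MonthlyTemperatureGrid,
    routes: pd.DataFrame,
    period1: PeriodWindow,
    period2: PeriodWindow,
    buffer_km: float = DEFAULT_BUFFER_KM,
    months: Sequence[int] = BREEDING_MONTHS,
) -> float:
    """Mean between-period breeding-season temperature change (°C) over the
    historical margin routes.

    Uses ALL years of each period, not observation-conditional years: the
    species may be absent from these routes in the later period, and local
    extinction is the outcome whose predictor this feeds.
    """
    sel = routes[routes["route_id"].isin(margin_t1.route_ids)]
    missing = set(margin_t1.route_ids) - set(sel["route_id"])
    if missing:
        raise MarginShiftError(f"no coordinates for margin routes: {sorted(missing)}")
    t1 = buffer_season_means(grid, sel, period1.years, buffer_km, months)
    t2 = buffer_season_means(grid, sel, period2.years, buffer_km, months)
    m1 = t1.groupby("route_id")["T"].mean()
    m2 = t2.groupby("route_id")["T"].mean()
    return float((m2 - m1).mean())


def code_shift_outcome(
    displacement_km: float, delta_T_margin: float
) -> tuple[str, int, bool]:
    """(expected_direction, outcome, zero_delta_T_flag) for one species-side.

    Warming at the historical margin makes a poleward shift the expected
    response on both sides; cooling makes equatorward expected. A zero
    temperature change is coded as expecting poleward by convention and
    flagged. The outcome is 1 only when the displacement is nonzero and its
    sign matches the expectation.
    """
    if not np.isfinite(delta_T_margin):
        raise ValueError("delta_T_margin must be finite")
    zero = delta_T_margin == 0.0
    expected = "poleward" if delta_T_margin >= 0 else "equatorward"
    if displacement_km > 0:
        moved = "poleward"
    elif displacement_km < 0:
        moved = "equatorward"
    else:
        moved = "none"
    return expected, int(moved == expected), zero


def build_shift_record(
    species_id: str,
    side: str,
    margin_t1: MarginSet,
    margin_t2: MarginSet,
    delta_T_margin: float,
    period1: PeriodWindow,
    period2: PeriodWindow,
) -> ShiftRecord:
    disp = margin_displacement_km(margin_t1, margin_t2)
    rate = per_decade_rate(disp, period1, period2)
    expected, outcome, zero = code_shift_outcome(disp, delta_T_margin)
    return ShiftRecord(
        species_id=species_id,
        side=side,
        displacement_km=disp,
        rate_km_per_decade=rate,
        delta_T_margin=delta_T_margin,
        expected_direction=expected,
        outcome=outcome,
        zero_delta_T=zero,
    )


# ---------------------------------------------------------------------------
# Regressions and tests
# ---------------------------------------------------------------------------


def margin_limit_regression(x: Sequence[float], y: Sequence[float]) -> FitResult:
    """OLS of margin temperature on thermal-limit temperature across species.

    Both inputs are typically breadth-adjusted (deviation from the niche
    centroid). Besides the usual slope test against 0, the departure of the
    slope from the 1:1 reference line is reported under ``slope_vs_1``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need >= 3 paired species values")
    if np.ptp(x) == 0:
        raise MarginShiftError("zero variance in x; regression undefined")
    model = sm.OLS(y, sm.add_constant(x)).fit()
    # constant response: no variance to explain, R^2 is 0 by convention
    r_squared = 0.0 if np.ptp(y) == 0 else float(model.rsquared)
    slope, intercept = float(model.params[1]), float(model.params[0])
    se_slope = float(model.bse[1])
    t_vs_1 = (slope - 1.0) / se_slope
    p_vs_1 = 2.0 * stats.t.sf(abs(t_vs_1), model.df_resid)
    return FitResult(
        method="ols",
        n=int(x.size),
        df=float(model.df_resid),
        params={"intercept": intercept, "slope": slope},
        statistics={
            "t_slope": float(model.tvalues[1]),
            "t_intercept": float(model.tvalues[0]),
            "slope_vs_1": float(t_vs_1),
            "se_slope": se_slope,
        },
        pvalues={
            "slope": float(model.pvalues[1]),
            "intercept": float(model.pvalues[0]),
            "slope_vs_1": float(p_vs_1),
        },
        r_squared=r_squared,
        loglik=float(model.llf),
    )


def paired_mean_difference_test(a: Sequence[float], b: Sequence[float]) -> FitResult:
    """Two-sided paired t-test on per-species differences a - b (df = n - 1)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size != b.size or a.size < 2:
        raise ValueError("need >= 2 paired values")
    diff = a - b
    flags: tuple[str, ...] = ()
    if np.ptp(diff) == 0:
        # constant difference: t is 0 (all-equal) or infinite (nonzero const)
        if diff[0] == 0:
            t_stat, p = 0.0, 1.0
        else:
            t_stat, p = float(np.sign(diff[0]) * np.inf), 0.0
            flags = ("infinite_t",)
    else:
        res = stats.ttest_rel(a, b)
        t_stat, p = float(res.statistic), float(res.pvalue)
    return FitResult(
        method="paired_t",
        n=int(a.size),
        df=float(a.size - 1),
        params={"mean_difference": float(diff.mean())},
        statistics={"t": t_stat},
        pvalues={"t": p},
        flags=flags,
    )


def temporal_gap_regression(
    gap_t1: Sequence[float], gap_t2: Sequence[float]
) -> FitResult:
    """Regression of later-period environmental distances on historical ones,
    plus a paired test of the mean gap change.

    A slope near 1 with a non-significant paired t means the margin tracked
    its thermal limit (the gap neither widened nor narrowed).
    """
    fit = margin_limit_regression(gap_t1, gap_t2)
    paired = paired_mean_difference_test(gap_t2, gap_t1)
    return FitResult(
        method="temporal_gap",
        n=fit.n,
        df=fit.df,
        params={**fit.params, "mean_gap_change": paired.params["mean_difference"]},
        statistics={**fit.statistics, "paired_t": paired.statistics["t"]},
        pvalues={**fit.pvalues, "paired_t": paired.pvalues["t"]},
        r_squared=fit.r_squared,
        loglik=fit.loglik,
        flags=paired.flags,
    )


def _penalized_logistic(x: np.ndarray, outcome: np.ndarray) -> tuple[float, float, float]:
    """L2-penalized fallback fit; returns (intercept, coef, loglik)."""
    from sklearn.linear_model import LogisticRegression

    clf = LogisticRegression(C=1.0, solver="lbfgs").fit(x.reshape(-1, 1), outcome)
    intercept = float(clf.intercept_[0])
    coef = float(clf.coef_[0][0])
    eta = intercept + coef * x
    p = 1.0 / (1.0 + np.exp(-eta))
    eps = 1e-12
    llf = float(np.sum(outcome * np.log(p + eps) + (1 - outcome) * np.log(1 - p + eps)))
    return intercept, coef, llf


def shift_probability_model(
    proximity: Sequence[float], outcome: Sequence[int], min_n: int = 10
) -> FitResult:
    """Logistic regression of the binary shift outcome on thermal proximity.

    ``proximity`` is each species' historical environmental distance (°C)
    between margin and thermal limit; small values mean the margin sits close
    to the realized niche edge. Significance is a likelihood-ratio test
    against the intercept-only model. Complete separation is flagged and the
    model refit with an L2 penalty (the LR p is then approximate).
    """
    x = np.asarray(proximity, dtype=float)
    y = np.asarray(outcome, dtype=int)
    if x.size != y.size or x.size < min_n:
        raise ValueError(f"need >= {min_n} paired values")
    if set(np.unique(y)) - {0, 1}:
        raise ValueError("outcome must be binary 0/1")
    if len(np.unique(y)) < 2:
        raise MarginShiftError("both outcome classes must be present")

    n = int(x.size)
    p_null = y.mean()
    ll_null = float(n * (p_null * np.log(p_null) + (1 - p_null) * np.log(1 - p_null)))

    if np.ptp(x) == 0:
        # constant predictor: the model collapses to the intercept-only fit
        return FitResult(
            method="logistic",
            n=n,
            df=float(n - 2),
            params={"intercept": float(np.log(p_null / (1 - p_null))), "proximity": 0.0},
            statistics={"lr": 0.0},
            pvalues={"lr": 1.0, "proximity": 1.0},
            loglik=ll_null,
            flags=("constant_predictor",),
        )

    flags: list[str] = []
    design = sm.add_constant(x)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", category=RuntimeWarning)
            warnings.filterwarnings(
                "error", message=".*[Ss]eparation.*", category=UserWarning
            )
            model = sm.Logit(y, design).fit(disp=0, maxiter=200)
        converged = bool(model.mle_retvals.get("converged", True))
        separated = (not converged) or np.abs(model.params).max() > 50
    except Exception:
        separated = True
        model = None

    if separated or model is None:
        flags.append("separation")
        intercept, coef, llf = _penalized_logistic(x, y)
        z = float("nan")
        p_coef = float("nan")
    else:
        intercept, coef = float(model.params[0]), float(model.params[1])
        llf = float(model.llf)
        z = float(model.tvalues[1])
        p_coef = float(model.pvalues[1])

    lr_stat = max(0.0, 2.0 * (llf - ll_null))
    lr_p = float(stats.chi2.sf(lr_stat, df=1))
    if "separation" in flags:
        flags.append("lr_p_approximate")
    return FitResult(
        method="logistic",
        n=n,
        df=float(n - 2),
        params={"intercept": intercept, "proximity": coef},
        statistics={"lr": lr_stat, "z_proximity": z},
        pvalues={"lr": lr_p, "proximity": p_coef},
        loglik=llf,
        flags=tuple(flags),
    )
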