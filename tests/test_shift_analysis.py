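"""Displacement arithmetic, direction coding and the statistical battery."""

import json
import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from marginshift import (
    MarginSet,
    MarginShiftError,
    PeriodWindow,
    code_shift_outcome,
    extent_change_rate,
    local_margin_temperature_change,
    margin_displacement_km,
    margin_limit_regression,
    paired_mean_difference_test,
    per_decade_rate,
    shift_probability_model,
    temporal_gap_regression,
)
from conftest import make_grid


def mk_margin(mean_lat, period="p1", side="poleward", species="SP", routes=("A",)):
    return MarginSet(
        species_id=species,
        period=period,
        side=side,
        route_ids=tuple(routes),
        mean_latitude=float(mean_lat),
        weighted_T=10.0,
    )


# ---------------------------------------------------------------------------
# Displacement and rates
# ---------------------------------------------------------------------------


def test_identical_latitudes_give_zero_displacement():
    assert margin_displacement_km(mk_margin(40.0), mk_margin(40.0, "p2")) == 0.0


def test_one_degree_poleward_is_the_meridian_arc():
    assert margin_displacement_km(mk_margin(40.0), mk_margin(41.0, "p2")) == pytest.approx(111.195)


def test_small_equatorward_shift_hand_value():
    d = margin_displacement_km(mk_margin(40.0), mk_margin(39.95, "p2"))
    assert d == pytest.approx(-5.56, abs=0.005)


def test_mismatched_species_or_side_rejected():
    with pytest.raises(MarginShiftError):
        margin_displacement_km(mk_margin(40.0), mk_margin(41.0, "p2", species="OTHER"))
    with pytest.raises(MarginShiftError):
        margin_displacement_km(mk_margin(40.0), mk_margin(41.0, "p2", side="equatorward"))


def test_per_decade_rate_uses_midpoint_gap(period1, period2):
    # 1986 -> 2004 midpoints: 18 years
    assert per_decade_rate(9.0, period1, period2) == pytest.approx(5.0)
    assert per_decade_rate(0.0, period1, period2) == 0.0
    assert per_decade_rate(-8.64, period1, period2) == pytest.approx(-4.8)


def test_identical_period_midpoints_rejected():
    p = PeriodWindow("a", 1984, 1988)
    with pytest.raises(MarginShiftError):
        per_decade_rate(1.0, p, PeriodWindow("b", 1984, 1988))


def test_extent_change_examples():
    assert extent_change_rate(0.65, 5.45) == pytest.approx(-4.80)
    assert extent_change_rate(3.2, 3.2) == 0.0
    assert extent_change_rate(2.0, -1.0) == pytest.approx(3.0)


@settings(max_examples=50, derandomize=True)
@given(st.floats(-50, 50), st.floats(-50, 50))
def test_extent_change_antisymmetric_under_margin_swap(a, b):
    assert extent_change_rate(a, b) == pytest.approx(-extent_change_rate(b, a))


# ---------------------------------------------------------------------------
# Local margin temperature change
# ---------------------------------------------------------------------------


def _two_period_grid(period1, period2, warm_by_lon=None):
    years = list(period1.years) + list(period2.years)
    grid = make_grid(years, [40.0], [-95.3, -94.7], fill=12.0)
    if warm_by_lon:
        for lon, dT in warm_by_lon.items():
            grid.data.loc[{"year": list(period2.years), "lon": lon}] += dT
    return grid


def test_stationary_climate_gives_zero_change(period1, period2):
    grid = _two_period_grid(period1, period2)
    routes = pd.DataFrame(
        {"route_id": ["A"], "latitude": [40.0], "longitude": [-95.3]}
    )
    m = mk_margin(40.0, routes=("A",))
    assert local_margin_temperature_change(m, grid, routes, period1, period2) == pytest.approx(0.0)


def test_uniform_imposed_warming_is_recovered(period1, period2):
    grid = _two_period_grid(period1, period2, {-95.3: 0.43, -94.7: 0.43})
    routes = pd.DataFrame(
        {"route_id": ["A", "B"], "latitude": [40.0, 40.0], "longitude": [-95.3, -94.7]}
    )
    m = mk_margin(40.0, routes=("A", "B"))
    assert local_margin_temperature_change(m, grid, routes, period1, period2) == pytest.approx(0.43)


def test_route_changes_are_averaged(period1, period2):
    grid = _two_period_grid(period1, period2, {-95.3: 0.2, -94.7: 0.6})
    routes = pd.DataFrame(
        {"route_id": ["A", "B"], "latitude": [40.0, 40.0], "longitude": [-95.3, -94.7]}
    )
    m = mk_margin(40.0, routes=("A", "B"))
    assert local_margin_temperature_change(m, grid, routes, period1, period2) == pytest.approx(0.4)


def test_missing_route_coordinates_named(period1, period2):
    grid = _two_period_grid(period1, period2)
    routes = pd.DataFrame({"route_id": ["A"], "latitude": [40.0], "longitude": [-95.3]})
    m = mk_margin(40.0, routes=("A", "GHOST"))
    with pytest.raises(MarginShiftError, match="GHOST"):
        local_margin_temperature_change(m, grid, routes, period1, period2)


# ---------------------------------------------------------------------------
# Outcome coding
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "dT,disp,expected,outcome,zero_flag",
    [
        (0.5, 12.0, "poleward", 1, False),
        (0.5, -12.0, "poleward", 0, False),
        (-0.3, -12.0, "equatorward", 1, False),
        (-0.3, 12.0, "equatorward", 0, False),
        (0.5, 0.0, "poleward", 0, False),
        (0.0, 12.0, "poleward", 1, True),
        (0.0, -12.0, "poleward", 0, True),
    ],
)
def test_outcome_coding_rule_table(dT, disp, expected, outcome, zero_flag):
    assert code_shift_outcome(disp, dT) == (expected, outcome, zero_flag)


@settings(max_examples=100, derandomize=True)
@given(
    st.floats(0.001, 100),
    st.floats(0.001, 1000),
    st.sampled_from([-1, 1]),
    st.sampled_from([-1, 1]),
)
def test_outcome_coding_depends_only_on_signs(dT_mag, disp_mag, s1, s2):
    assert code_shift_outcome(s2 * disp_mag, s1 * dT_mag) == code_shift_outcome(
        s2 * 1.0, s1 * 1.0
    )


# ---------------------------------------------------------------------------
# OLS margin-limit regression
# ---------------------------------------------------------------------------


def test_perfect_identity_line():
    x = np.linspace(-5, 5, 20)
    fit = margin_limit_regression(x, x)
    assert fit.params["slope"] == pytest.approx(1.0)
    assert fit.r_squared == pytest.approx(1.0)
    assert fit.statistics["slope_vs_1"] == pytest.approx(0.0, abs=1e-8)


def test_constant_offset_keeps_unit_slope():
    x = np.linspace(-5, 5, 20)
    fit = margin_limit_regression(x, x + 2.5)
    assert fit.params["slope"] == pytest.approx(1.0)
    assert fit.params["intercept"] == pytest.approx(2.5)
    assert fit.r_squared == pytest.approx(1.0)


def test_zero_variance_predictor_rejected():
    with pytest.raises(MarginShiftError):
        margin_limit_regression([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


def test_known_slope_recovered_within_ci_in_most_replicates():
    rng = np.random.default_rng(314)
    hits = 0
    for _ in range(100):
        x = rng.normal(0, 2, 100)
        y = 0.7 * x + rng.normal(0, 0.5, 100)
        fit = margin_limit_regression(x, y)
        half = 1.984 * fit.statistics["se_slope"]  # t_{0.975, df=98}
        hits += abs(fit.params["slope"] - 0.7) <= half
    assert hits >= 93


# ---------------------------------------------------------------------------
# Paired t and temporal gap
# ---------------------------------------------------------------------------


def test_equal_samples_give_t_zero_p_one():
    a = np.array([1.0, 2.0, 3.0, 4.0])
    fit = paired_mean_difference_test(a, a)
    assert fit.statistics["t"] == 0.0
    assert fit.pvalues["t"] == 1.0


def test_paired_t_hand_formula():
    fit = paired_mean_difference_test([2.0, 4.0, 6.0], [1.0, 2.0, 3.0])
    assert fit.statistics["t"] == pytest.approx(2 * np.sqrt(3))
    assert fit.df == 2


def test_unchanged_gaps_give_unit_slope_and_zero_t():
    gaps = np.array([0.5, 1.0, 1.5, 2.0, 3.0])
    fit = temporal_gap_regression(gaps, gaps)
    assert fit.params["slope"] == pytest.approx(1.0)
    assert fit.statistics["paired_t"] == 0.0


def test_constant_gap_widening_flags_degenerate_infinite_t():
    gaps = np.array([0.5, 1.0, 1.5, 2.0, 3.0])
    fit = temporal_gap_regression(gaps, gaps + 1.0)
    assert fit.params["slope"] == pytest.approx(1.0)
    assert fit.params["intercept"] == pytest.approx(1.0)
    assert "infinite_t" in fit.flags
    assert fit.pvalues["paired_t"] == 0.0


# ---------------------------------------------------------------------------
# Logistic shift-probability model
# ---------------------------------------------------------------------------


def test_constant_proximity_collapses_to_null_model():
    y = np.array([0, 1] * 10)
    fit = shift_probability_model(np.full(20, 2.0), y)
    assert fit.params["proximity"] == 0.0
    assert fit.pvalues["lr"] == 1.0
    assert "constant_predictor" in fit.flags


def test_perfect_separation_is_flagged():
    x = np.concatenate([np.zeros(10), np.ones(10) * 5])
    y = np.concatenate([np.ones(10, int), np.zeros(10, int)])
    fit = shift_probability_model(x, y)
    assert "separation" in fit.flags


def test_single_outcome_class_rejected():
    with pytest.raises(MarginShiftError):
        shift_probability_model(np.arange(12.0), np.ones(12, int))


def test_generating_coefficient_sign_recovered():
    rng = np.random.default_rng(2718)
    neg = 0
    for _ in range(100):
        d = rng.uniform(0, 2.5, 34)
        p = 1 / (1 + np.exp(-(2.0 - 1.5 * d)))
        y = (rng.random(34) < p).astype(int)
        if len(np.unique(y)) < 2:
            continue
        fit = shift_probability_model(d, y)
        neg += fit.params["proximity"] < 0
    assert neg >= 95


# ---------------------------------------------------------------------------
# Agreement with an independent reference implementation (R lm/glm)
# ---------------------------------------------------------------------------

R_SCRIPT = """
args <- commandArgs(trailingOnly = TRUE)
d <- read.csv(args[1])
out <- NULL
for (i in unique(d$instance)) {
  s <- d[d$instance == i, ]
  ols <- lm(y ~ x, data = s)
  log <- glm(z ~ x, data = s, family = binomial())
  out <- rbind(out, data.frame(
    instance = i,
    ols_intercept = coef(ols)[1], ols_slope = coef(ols)[2],
    ols_r2 = summary(ols)$r.squared,
    glm_intercept = coef(log)[1], glm_slope = coef(log)[2],
    glm_loglik = as.numeric(logLik(log))))
}
write.csv(format(out, digits = 17), args[2], row.names = FALSE)
"""


@pytest.mark.skipif(shutil.which("Rscript") is None, reason="Rscript not available")
def test_fits_agree_with_r_reference_to_six_significant_figures(tmp_path):
    rng = np.random.default_rng(1729)
    frames = []
    for i in range(20):
        n = 60
        x = rng.normal(0, 1.5, n)
        y = 0.8 * x - 0.3 + rng.normal(0, 1.0, n)
        p = 1 / (1 + np.exp(-(0.4 - 0.9 * x)))
        z = (rng.random(n) < p).astype(int)
        if len(np.unique(z)) < 2:
            z[0], z[1] = 0, 1
        frames.append(pd.DataFrame({"instance": i, "x": x, "y": y, "z": z}))
    data = pd.concat(frames, ignore_index=True)
    csv_in = tmp_path / "instances.csv"
    csv_out = tmp_path / "reference.csv"
    data.to_csv(csv_in, index=False)
    script = tmp_path / "ref.R"
    script.write_text(R_SCRIPT)
    subprocess.run(
        ["Rscript", "--vanilla", str(script), str(csv_in), str(csv_out)],
        check=True,
        capture_output=True,
    )
    ref = pd.read_csv(csv_out).set_index("instance")
    for i, sub in data.groupby("instance"):
        ols = margin_limit_regression(sub["x"], sub["y"])
        logi = shift_probability_model(sub["x"], sub["z"])
        assert "separation" not in logi.flags
        r = ref.loc[i]
        assert ols.params["intercept"] == pytest.approx(r["ols_intercept"], rel=1e-6)
        assert ols.params["slope"] == pytest.approx(r["ols_slope"], rel=1e-6)
        assert ols.r_squared == pytest.approx(r["ols_r2"], rel=1e-6)
        assert logi.params["intercept"] == pytest.approx(r["glm_intercept"], rel=1e-6)
        assert logi.params["proximity"] == pytest.approx(r["glm_slope"], rel=1e-6)
        assert logi.loglik == pytest.approx(r["glm_loglik"], rel=1e-6)
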