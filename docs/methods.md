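# Methods

## The analysis model

The pipeline treats a species' breeding distribution as the set of survey
routes on which it was recorded (count > 0) within a five-year period. Two
such periods, 18 years apart at midpoint by default (1984–1988 and
2002–2006), are compared. All thermal quantities derive from one primitive:
the breeding-season temperature of a route-year, defined as the unweighted
mean, over grid cells whose centers lie within `buffer_km` (default 20 km)
of the route centroid, of the April–June mean of the cell's monthly means.
Great-circle distances use a spherical Earth of radius 6371.0088 km.

Species-level temperatures are conditioned on observation: a route's
temperature for a species is averaged only over the period years in which
the species was recorded there. The rationale is that the presence record
is the evidence that the conditions of those particular years were
tolerated. The one deliberate exception is the temperature *change* at
historical margin routes (the predictor of the shift outcome) and at fixed
supplement sites, which uses all years of each period: local extinction is
the outcome under study, so its predictor cannot be conditioned on
continued presence.

Margins and realized thermal limits are k-extreme route sets (k = 10,
configurable): by latitude for margins, by observation-conditional mean
temperature for limits, ties broken by ascending route id so runs are
reproducible across platforms. When fewer than k routes are occupied, all
are used and the set is flagged rather than rejected, so degenerate
synthetic cases still run. Set temperatures are abundance-weighted
(Σ Tᵢcᵢ / Σ cᵢ over member routes); the niche centroid applies the same
weighting over all occupied routes.

Breadth adjustment is the signed deviation T − centroid. A normalized
variant (deviation divided by the realized breadth, warm-limit minus
cool-limit temperature) is available via `breadth_mode="ratio"` for
sensitivity runs; the deviation form is the default because the quantity
being compared across species is a temperature gap in °C, not a
proportion.

Displacement converts the change in a margin set's mean latitude to
kilometers with the spherical meridian arc, 111.195 km/degree; geodesic
refinements differ by < 0.5% and are not modeled. Rates divide by the
period-midpoint gap (18 years for the default windows) and are reported
per decade. Net extent change is the poleward-margin rate minus the
equatorward-margin rate, so negative values mean latitudinal contraction.

Direction coding: warming at the historical margin makes a poleward shift
the expected response at both margins; cooling, equatorward. A zero
temperature change is coded as expecting poleward and flagged
(`zero_delta_T`); zero displacement is coded as outcome 0 — no shift is
not a shift in the expected direction. Both conventions are choices where
no rule is forced by the data; they are applied uniformly and surfaced in
the shift table.

## Statistics

Ordinary least squares (statsmodels) is used for the margin-vs-limit and
temporal-gap regressions; besides the usual slope test against 0, the
departure of the slope from the 1:1 line is reported (`slope_vs_1`),
because perfect margin–limit correspondence predicts unit slope. The
paired comparison of margin and limit temperatures is a two-sided paired
t-test (df = n − 1). A constant nonzero paired difference has zero
variance; it is reported as an infinite-t flag rather than an error, since
it arises in exact synthetic scenarios. A constant response in OLS is
reported with R² = 0.

The shift-probability model is a maximum-likelihood logistic regression of
the binary outcome on the historical environmental distance, with
significance from a likelihood-ratio test against the intercept-only model
(the quantity mirrored in reported log-likelihoods). Complete separation
is detected (non-convergence or runaway coefficients) and the model refit
with an L2 penalty (C = 1); the result is flagged `separation` and its LR
p-value marked approximate. A constant predictor returns a zero
coefficient with LR p = 1 rather than failing on a singular design. OLS
and logistic fits are cross-checked against R's `lm`/`glm` to six
significant figures in the test suite.

## The synthetic-data generator

The generator builds the simplest world in which each estimator has a
known answer. Climate: T(cell, year, month) = season base − lapse·(lat −
lat_min) + month offset + static anomaly + warming·[year ∈ period 2] +
ε(cell, year). Defaults: lapse 1 °C/degree, season base 26 °C at the
southern domain edge, month offsets (−2, 0, +2) °C for April–June,
+0.43 °C between-period warming (the observed continental figure for the
default windows), ε iid Normal with sd `noise_sd` shared across the three
months of a cell-year. The static anomaly can be smoothed random noise
(`anomaly_sd`, correlation length `anomaly_smoothing_deg`), conical cool
pockets (highland emulation), or north–south cool ridges (triangular in
longitude, constant in latitude). The pockets and ridges exist because a
purely latitudinal field makes the coolest occupied sites identical to the
poleward margin sites, which forces every poleward environmental distance
to zero; real landscapes hold cool interiors, and the ridge variant has
the additional property that all of its isotherms translate exactly under
uniform warming, which is what a pure-translation experiment needs.

Species: occupancy at a route-year requires the local (nearest-cell)
seasonal temperature to lie inside [tolerance_low, tolerance_high] and the
latitude to respect an optional poleward cap (the non-thermal margin
device; a second-period cap lets the cap track warming). Counts are
1 + Poisson(max(λ − 1, 0)) with λ a Gaussian curve in temperature peaking
at `peak_abundance` (width a quarter of the tolerance window) — at least
one individual whenever the species is detected, mean ≈ λ elsewhere.
Detection is Bernoulli per route-year. Period-2 site extinction occurs
with probability min(1, sensitivity·exp(−proximity)), proximity being the
site's distance below the warm tolerance limit, so extinction concentrates
where thermal headroom is smallest. All randomness flows from one seed
with fixed per-species substreams; identical seeds give byte-identical
outputs.

`true_values` returns analytic margin latitudes, limit temperatures and
displacement rates for the pure-gradient case (isocline algebra), and
refuses stochastic scenarios unless expectations are requested. In the
pure gradient both environmental distances are exactly zero — positive
poleward gaps require the anomaly structures and are validated against the
pipeline itself, not the analytic table.

What the generator does not emulate: coastlines and real continental
geometry, observer effects and detection heterogeneity beyond a constant
detection probability, spatially varying warming, elevation as a separate
covariate, and route-level habitat. Passing tests therefore demonstrate
estimator correctness under the stated model, not robustness to those
real-data complications.

## Numerical and design notes

- Buffer membership is cell-center-within-radius with an unweighted mean;
  no area weighting. A buffer with no data cell raises an error naming the
  route (this occurs when grid resolution is coarser than ~0.25° against a
  20-km buffer; tests with coarse grids pass a larger buffer).
- Duplicate (route, species, year) rows are summed with a warning;
  malformed rows are rejected with file line numbers; a missing column is
  fatal.
- The 100-individual and 30-route screening rules are evaluated per period
  (both periods must pass); the 49°N historical-margin rule is inclusive
  (max occupied latitude ≤ 49 retains) and uses the first period only.
  Qualitative exclusions (disjunct, coastal, non-native) are a manual list
  in configuration, never inferred.
- Environmental distances are not clamped at zero. With abundance
  weighting they can be marginally negative (order 0.05 °C): the extreme
  sets maximize member temperatures, not abundance-weighted means, so when
  counts correlate with temperature a margin set can weight slightly
  warmer than the warm-limit set. Unweighted distances are nonnegative by
  the sort-dominance argument.
- The per-decade scaling divides by the midpoint-year gap; with the
  default windows the divisor is 18 years.
- Simulation scales in the test suite and acceptance script (domain sizes,
  route spacings, replicate counts, community sizes) were chosen as the
  smallest designs whose Monte-Carlo error is comfortably inside the
  assertion bands; the gap-constancy experiment uses 20-species
  communities on a 0.25° lattice with warming equal to two lattice
  spacings, so the translation is exact on the route grid and the only
  variability left is interannual noise.

## Known limitations

- Route centroids stand in for the full 39.5-km transect geometry.
- The logistic separation fallback is a ridge-penalized fit, not a Firth
  correction; flagged results should be treated as directional only.
- The fixed-site abundance supplement sums counts over a period's
  observation years; per-year averaging would differ when sampling effort
  varies between periods.
- With all extinct sites excluded and no survivors, the supplement reports
  NaN for that species rather than inventing a change.
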