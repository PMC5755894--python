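# Methods

## Model

The population model is a five-compartment ODE system for eggs, larvae,
pupae, adults and cumulative trapped adults, forced by daily mean
temperature.  Its assumptions:

- Density dependence acts only on oviposition, through the egg carrying
  capacity `K` (eggs): laying is proportional to `A (1 − E/K)`.  `K` is the
  single free parameter; it aggregates breeding-site availability and is
  the quantity the calibration estimates.
- Development rates respond to temperature through the Sharpe–Schoolfield
  enzyme-kinetics form: Arrhenius acceleration relative to 298 K divided by
  a high-temperature inactivation term.  Mortalities are
  temperature-independent.
- Trapping removes adults at rate `c = α Tₙ/Hₙ` per day: a trap competes
  with ordinary attraction within its household, so the per-adult rate
  scales with traps per household.  `α` and `K` are confounded — the
  equilibrium relation `K = Φ_E A* R₀/(R₀ − 1)` is linear in adult
  abundance with a slope that depends on `c` — so `α` is fixed (0.2/day)
  and `K` is interpreted as conditional on it.
- Temperature is the only source of temporal variation; rainfall,
  humidity, spatial coupling between areas and demographic stochasticity
  are out of scope.

Default parameters (per day unless noted): `σ₀ = 1.0`; mortalities
`μ₁ = 1/100` (egg), `μ₂ = 1/3` (larva), `μ₃ = 1/70` (pupa), `μ₄ = 1/17.5`
(adult); Schoolfield constants per stage in
`src/aedes_capacity/data/thermal_params.yaml` (`ρ` per day, `a`, `b` in
cal/mol, `τ` in Kelvin).  Users may override the YAML file; `R = 1.987`
cal K⁻¹ mol⁻¹ is fixed.  Celsius→Kelvin conversion uses the 273.15 offset
throughout.

## Equilibrium

At constant temperature the stage equations give abundance ratios per
adult, `Φ_P = (μ₄+c)/σ₃`, `Φ_L = Φ_P (σ₃+μ₃)/σ₂`, `Φ_E = Φ_L (σ₂+μ₂)/σ₁`,
and the egg equation fixes the scale,
`A* = K (1 − (σ₁+μ₁)Φ_E/σ₀)/Φ_E`.  The offspring number
`R₀ = σ₀/((σ₁+μ₁)Φ_E)` — expected lifetime egg output per adult weighted
by stage survival — decides persistence: the positive equilibrium exists
iff `R₀ > 1`, otherwise extinction is the only non-negative steady state.
The closed form is verified against 3000-day brute-force integration over
a grid of temperature, capture rate and `K` (agreement < 0.1% where the
positive equilibrium exists).

## Numerical integration

`simulate()` realises "solve to steady state under the forcing" by tiling
the forcing series periodically: repeated passes over the full series,
each starting from the previous end state, until the weekly index pattern
of consecutive passes changes by less than 1e-4 (cap 10 passes).  The
final pass, calendar-aligned and with the trapped counter restarted at
zero, is returned.  Default initial condition `E = K/2, L = P = A = 10`;
the burn-in makes results insensitive to it (transients decay on the
~2–3 week timescale of the fastest stages and the ~17-day adult
lifespan).

Stage rates are evaluated at the daily forcing temperatures and
interpolated linearly in time between days, so the integrated ODE is
identical for both solver paths:

- default `solver="rk4"`: classical fixed-step Runge–Kutta, 4 steps/day.
  The system is non-stiff — every per-day rate is ≤ ~0.5 — so the local
  error at a quarter-day step is orders of magnitude below the
  observation noise, and the pure-float loop makes multi-replicate
  simulation experiments cheap.
- `solver="lsoda"`: adaptive stiff-capable integration (rtol 1e-8,
  atol 1e-10) as a cross-check; the two agree to < 1e-6 on weekly IMFA in
  the tests.

Exponentials in the thermal formula are clipped at ±700 so extreme
temperatures degrade smoothly to zero rate instead of overflowing.

## Calibration

The observed weekly index is smoothed with a degree-2 local polynomial
regression (loess-style): for each week, the `span × n` nearest weeks
(default span 0.08) are fitted by tricube-weighted least squares and
evaluated at that week; windows below `degree + 2` points are widened with
a warning; negative fitted values are clipped to zero; missing weeks are
excluded as predictors and left missing.  Fitting to the smoothed series
is the default (`smooth=False` switches to raw).

Every term of the model is jointly homogeneous of degree 1 in the state
and `K`, so the steady-state weekly index is exactly proportional to `K`.
The MSE against any target series is therefore an exact quadratic in `K`,
and the default fit (`method="scaling"`) simulates once at a reference
`K` (the geometric mid of the search bounds, default [10, 1e5] eggs) and
takes the closed-form bounded minimiser — deterministic to the bit and
the exact argmin of the same objective the generic search would scan.
`method="brent"` performs bounded scalar minimisation with a fresh
simulation per candidate and agrees with the default to < 0.1% in tests;
it is retained for when model changes break the homogeneity.  An optimum
on a search bound is flagged non-converged.  Missing surveillance weeks
are excluded from the cost pairwise, never imputed.  Batch fitting
records per-area failures in the output table without aborting.

## Surveillance metrics

Fit quality is classified per batch: "poor" iff an area's MSE exceeds the
mean MSE (ties are good).  The ROC sweeps every distinct observed trap
count as a threshold with orientation "predicted good iff count ≥
threshold", selects the maximum of Youden's J (sensitivity + specificity
− 1), and resolves ties to the smallest threshold; AUC comes from
scikit-learn.  The descriptor screen fits univariate OLS regressions of
`K̂` and of the average index (aIMFA) on each census descriptor,
log-transforming population counts; p-values are deliberately unadjusted
(each descriptor is reported as its own univariate hypothesis, the
convention of the screening table this mirrors), with `***` for p < 0.05
and `**` for p < 0.1.

## Synthetic data

The generator emulates a humid-tropical surveillance study:

- temperature: annual sinusoid (default mean 26 °C, amplitude 4 °C,
  peaking at the turn of the year) plus stationary AR(1) noise
  (lag-one correlation 0.8, marginal sd 1 °C) mimicking weather
  persistence;
- observations: weekly total captures Poisson-distributed with mean
  `Tₙ · imfa_model(w)` — counts summed over identical traps — so index
  variance shrinks as 1/Tₙ, which is what produces the sampling-effort
  effect the ROC quantifies;
- cities: per-area `K_true` uniform on [1300, 4200] eggs (the realistic
  neighbourhood range), trap counts log-normal (median ≈ 13) clipped to
  [2, 149], households log-normal around 8000 — chosen so typical weekly
  indices fall in the observed 0.2–1 range — four years of weeks, and
  census descriptors with optional planted linear effects of `K_true`
  (in descriptor units per 1000 eggs).

What the generator does *not* emulate: trap interference, spatial
correlation between neighbouring areas, missing surveillance weeks,
reporting errors, or rainfall-driven variation.  Passing recovery tests
therefore demonstrate internal consistency of the method under its own
assumptions, not field validity.

Recovery experiments in the test suite use 4-year series at
`K_true = 2500` with 50 replicates per trap level (2/16/64 traps) and a
20-area city at 30 traps per area — sizes chosen to make each experiment
a few seconds while keeping the Monte-Carlo comparisons stable.

## Data formats

CSV throughout (spreadsheets accepted read-only via
`convert-supplementary`): IMFA tables as `area_id, week_start_date, imfa,
n_traps, n_households`; temperature as `date, area_id, tmean_C` (or
`tmax_C` plus the mean-from-max regression in
`aedes_capacity.temperature`); descriptors as `area_id` plus the nine
census columns.  Junction merges (areas pooled because trap locations
could not be separated) sum captures and traps before the index is formed
— a ratio of sums, not a mean of ratios — and sum households.  Weeks are
7-day blocks from the first day of the analysis period, identified by
their start date.

## Known limitations

- `K` estimates are conditional on trap attractiveness and density and
  are not comparable across different trapping configurations; only the
  equilibrium relation allows re-expression under a different `α`.
- The forcing tiling assumes the temperature series is approximately
  periodic; a strong trend across the tiled seam would bleed into the
  burn-in.
- The smoother's tricube weighting is one concrete choice of local
  polynomial regression; other loess variants will move fitted `K` by a
  fraction of a percent.
- Temperature-independent mortalities and the absence of rainfall mean
  the model can misattribute moisture-driven seasonality to temperature.
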