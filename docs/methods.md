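# Methods

This note documents the models, numerical choices and known limitations of
`fluxpheno`. Day-of-year (DOY) is the universal time axis: a fixed 365-day
calendar (leap days are merged into DOY 59 on ingest). NEE follows the
micrometeorological sign convention — negative is net uptake.

## Carbon-flux phenology retrieval

The start/end of carbon uptake are retrieved in three steps: a centered
15-day moving average of daily NEE; a search for a 10-day window whose first
five smoothed values and last five straddle zero (positive→negative for
spring, negative→positive for autumn, strict inequalities — zeros fail the
pattern); and an OLS fit of smoothed NEE on DOY within the window, with the
date reported at the zero intersection −β₀/β₁. The slope must be negative in
spring and positive in autumn; a root falling more than 5 days outside the
window is flagged as extrapolated.

Choices the procedure leaves open, fixed here:

* **Window choice under multiple candidates.** Spring takes the *first*
  qualifying window in DOY 1–200, autumn the *last* in DOY 150–365, so a
  mid-season sign flicker cannot truncate the uptake period. Both ranges are
  configurable.
* **Edges and gaps.** Edge windows truncate to the available days; missing
  days are excluded from each window mean, and a day whose window retains
  fewer than half the nominal width of valid values becomes missing itself.
  Windows containing missing smoothed days are skipped during the search.
* **Smoothing bias.** A centered moving average of width *w* shifts a curved
  zero crossing by ≈ −(w²−1)/24 · f″/f′. For the double-logistic NEE family
  used in validation this bias is ≈ (w²−1)/24 · (1−2·R₀/A)/s days (R₀
  respiration baseline, A uptake amplitude, s the transition time constant):
  zero when the crossing sits at the uptake inflection (R₀/A = ½), up to
  ≈ 2 days for steep, strongly uptake-dominated curves (s = 5 d, R₀/A ≈ 0.06).
  This is a property of the method, not of the implementation; the
  noise-free validation grid spans temperate-realistic shapes
  (R₀/A ∈ [0.2, 0.5], s ∈ [8, 14] d) where the retrieval stays within 1 day
  of the bisection truth. Under daily NEE noise of 0.5 g C m⁻² d⁻¹ the mean
  absolute retrieval error is ≈ 1.2 days.

## Vegetation-index filtering and growing-season retrieval

Composite VI series (nominal 16-day MOD13Q1-style periods, labelled by their
start day; mid-period labelling is available as an option) are cleaned with
an iterative upper-envelope Savitzky–Golay filter: fit a local polynomial
(7 composites, degree 4), lift every original composite lying below the fit
onto it, refit. Because VI contamination (cloud, aerosol, snow) is
negatively biased, the clean signal is the upper envelope. Iterating to
convergence over-lifts — each refit of the lifted series rises, ratcheting
the envelope above the clean curve — so the retained iterate is the one
minimising a weighted fitting-effect index (departures from the original
series, down-weighted for points far below the initial trend); the loop also
exits when the mean absolute change between iterations falls below 10⁻⁴.
With symmetric noise σ = 0.03 plus 15% multiplicative cloud dropouts the
filtered daily curve beats raw linear interpolation (MSE against the
noise-free curve) in ≈ 97–99 of 100 replicates.

The filtered composites are linearly interpolated to a daily curve (edge
values held constant) so threshold crossings can be reported as fractional
DOY — finer than the 16-day sampling. Six retrieval methods operate on that
curve (the function-fitting ones may also consume the raw composites):

* **global_threshold** — first upward / last downward crossing of a fixed VI
  value shared by all site-years;
* **local_midpoint** — crossing of (annual min + annual max)/2, per
  site-year; the extrema are estimated as the means of the lowest and
  highest 10% of daily values, which is robust to residual spikes;
* **local_fraction** — crossing of min + f·(max−min); f = 0.5 reproduces the
  midpoint method exactly (same code path);
* **delayed_moving_average** — crossing of the curve over its trailing mean
  of the previous 5 composite-equivalent (16-day) lags; fires earlier than
  the midpoint method on a rising limb by construction;
* **fit_midpoint / fit_curvature** — nonlinear least squares of a
  single-season double logistic (background, amplitude, two inflections, two
  time constants; 4 deterministic starts, bounded trust-region solver),
  returning either the inflection parameters directly or the extrema of the
  curvature-change rate of each limb (the earlier green-up onset / later
  dormancy onset of the curvature convention).

An evaluation harness scores any method's SOS/EOS against reference SCU/ECU
(R², RMSE, bias = mean(LSP−CFP), pooled and per biome) and ranks methods by
R², ties broken by RMSE.

**Sampling resolution limit.** Linear interpolation of 16-day composites of
a logistic limb with time constant s mis-places the midpoint crossing by up
to ≈ 0.6 day at s = 7 (worst composite phase, from chord asymmetry alone),
falling to ≈ 0.3 day at s ≥ 10. Sub-half-day accuracy claims therefore apply
to limbs the composite sampling resolves (s ≥ ~9 d); steeper limbs carry
proportionally larger uncertainty. A single growing season per year is
assumed throughout; double-cropping is out of scope.

## Climate drivers

Impact windows are day-offset pairs relative to the (rounded) SOS or EOS:
starts {−60 … −10 step 10} × ends {0, +10, +20}, 18 windows, both endpoints
inclusive (window (−20, 0) spans 21 days). Two drivers: cumulative daily air
temperature above 0 °C (degree-days, base 0 — negative days are clipped, not
dropped) and total precipitation (summed as-is). For each biome, metric and
driver, the CFP date is regressed on the accumulated driver for every
window; the window with the highest R² is retained and marked *selected*
only if its regression F-test (equivalently the slope t-test) has p < 0.05.
Site-years whose window leaves the calendar year or covers missing daily
data are dropped from that candidate only. Exact R² ties (within 10⁻¹²)
break toward the shorter window, then the later start.

Because the selection is an argmax over 18 strongly overlapping
accumulations, neighbouring windows tie within sampling noise whenever the
driver explains only a modest share of the date variance; with ~30
site-years the designed window is reliably identified only when the driver
is the dominant signal. The designed validation experiments respect this
(see below). The same multiple-comparison effect inflates the apparent
significance of the best window under the null; the significance gate is
applied as specified, per window, without correction.

## Cohort assembly

Per metric, three exclusion rules in order: (1) per-biome mean dates are
computed once over all site-years; any *site* whose site-mean deviates by
more than 60 days is excluded entirely (single pass, no re-averaging);
(2) site-years whose metric is unretrievable are excluded; (3) biome cells
with fewer than 10 site-years are dropped. Spring and autumn cohorts are
filtered independently, so their sizes differ. Every input site-year lands
exactly once — included or in the exclusion ledger with its rule.

## Estimation and validation

Final models are OLS fits of the observed CFP date on the LSP date plus the
selected (significant) drivers, per biome and metric; with no selected
driver the model is LSP-only and flagged. Reported: coefficients with
standard errors, R² (stored as a fraction, printed as a percent), RMSE with
divisor n, bias = mean(fitted−observed), and the overall F-test.
Leave-one-out cross-validation refits each fold explicitly; for linear
models this equals the PRESS/hat-matrix closed form e᷈ᵢ = eᵢ/(1−hᵢᵢ), which
the test suite uses as an independent check. The LOOCV R² is the squared
correlation between observed dates and held-out predictions; the 1−SSE/SST
variant is reported alongside. Listwise deletion (with logging) handles
missing predictors; rank-deficient designs raise a collinearity error.

Impact windows may be **pinned** via configuration
(`fixed_driver_windows={"scu:temperature": (-20, 0)}`), skipping the grid
search — the regime in which windows established on one site network are
reapplied when extrapolating to new sites.

## Synthetic data

The generator produces the study conditions for all validation:

* **NEE**: NEE(d) = R₀ − A·L↑(d)·L↓(d) with logistic ramps
  L(d) = 1/(1+exp(∓(d−t)/s)), plus iid Gaussian noise (default σ = 0.5
  g C m⁻² d⁻¹). True SCU/ECU are the noise-free roots, bracketed and solved
  by bisection to 10⁻⁶ day. Defaults: R₀ = 1, A = 4, s = 7 d.
* **VI**: double logistic between winter background 0.2 and summer plateau
  0.8, sampled at the 23 composite start days, noise σ = 0.02, and
  cloud dropouts that multiply a composite by U(0.3, 0.7) with probability
  0.1 (depressed, not missing, matching the negative bias the envelope
  filter assumes; dropout positions are recorded on a separate flag). True
  SOS/EOS are the logistic inflections.
* **Climate**: air temperature = annual sinusoid (mean 8 °C, half-range
  14 °C, coldest DOY 15) plus iid noise (σ = 1.5 °C by default; the
  driver-identification experiment uses 4 °C, the synoptic scale);
  precipitation = Bernoulli(0.3) wet days × exponential depths (mean 5 mm).
* **Cohorts**: per-site-year true SOS/EOS are drawn (defaults N(120, 12²)
  and N(280, 12²)), the site-year's annual temperature gets an offset
  (default σ = 4 °C), and the designed links SCU = a + b·SOS + c·GDD(window)
  (and analogously ECU) define target dates; the NEE curve midpoints are
  then back-solved by alternating 1-D root finding so the noise-free zero
  crossings equal the targets (to ≪ 0.1 day). Substreams derive from
  (cohort seed, site index), so cohorts are bit-reproducible and site-years
  uncoupled.

What the generator does **not** emulate: temporal autocorrelation of weather
and NEE residuals, snow/freeze VI artefacts beyond multiplicative dropouts,
double seasons, site-specific phenology–climate feedback, and spatial
correlation among sites. Passing tests therefore demonstrate algorithmic
correctness under the stated curve families, not performance on real tower
archives.

## Designed validation experiments

Two packaged experiments (`fluxpheno.experiments`) validate the pipeline end
to end, both on cohorts of n = 30 with the balanced NEE curve (R₀/A = ½, so
retrieval bias does not confound the regression design):

* **Driver-window identification**: SCU = 100 + 0.1·GDD(−20, 0) + ε(0.5 d),
  with synoptic daily temperature noise (σ = 4 °C) supplying the signal that
  distinguishes the designed window from its overlapping neighbours. The
  pipeline must select (−20, 0) out of the 18 candidates with p < 0.05.
* **Coefficient recovery**: SCU = 10 + 1.0·SOS + 0.1·GDD(−20, 0) + ε(0.1 d),
  with the designed window pinned and function-fit phenology retrieval
  (exact on noise-free double-logistic VI), isolating the estimation stage.
  Fitted coefficients come back within a few tenths of a percent of design.

The two claims are validated separately because they are jointly
unidentifiable at this sample size: once the date depends strongly on SOS
itself, the argmax over overlapping windows is decided by sampling noise
(see the climate-drivers section), while shrinking the SOS variance to fix
selection destroys the intercept's recoverability (its standard error grows
with the 120-day extrapolation lever arm). The link noise of 0.1 day in the
recovery design likewise keeps the intercept tolerance meaningful: at
σ ≈ 1 day the intercept's sampling error alone exceeds 5% of its 10-day
design value.

## Defaults worth knowing

| Parameter | Default | Meaning |
|---|---|---|
| `smooth_width` | 15 d | NEE moving-average width (odd) |
| `window_width` | 10 d | transition window, split half/half |
| `spring_range` / `autumn_range` | 1–200 / 150–365 | DOY search intervals |
| `sg_window_points` / `sg_degree` | 7 / 4 | Savitzky–Golay setup (composites) |
| `min_valid_composites` | 15 | below this a VI series is rejected |
| `amplitude_floor` | 0.05 | minimum annual VI amplitude for thresholds |
| `window_starts` / `window_ends` | −60…−10 / 0…+20 | impact-window grid |
| `min_site_years_per_window` | 5 | per-candidate completeness floor |
| `max_site_deviation` | 60 d | site exclusion rule |
| `min_site_years_per_biome` | 10 | biome-cell floor |
| `significance_level` | 0.05 | driver screening and model F-tests |

The CLI (`fluxpheno simulate / retrieve-cfp / retrieve-lsp / build-cohort /
select-drivers / run-all`) is a thin layer over these functions and writes
only CSV/JSON; plots are deliberately not produced — the scatter data for an
observed-vs-estimated figure is written as CSV instead.
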