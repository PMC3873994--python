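# fluxpheno

Estimate **carbon flux phenology** — the spring and autumn dates at which an
ecosystem's net CO₂ exchange changes sign — from satellite-derived land
surface phenology and climate drivers.

Eddy covariance towers measure daily net ecosystem exchange (NEE, g C m⁻² d⁻¹,
negative = net uptake) and yield the **start and end of carbon uptake**
(SCU/ECU): the days the smoothed NEE crosses zero downward in spring and
upward in autumn. Towers are sparse, however, while satellites observe
everywhere. This package implements a methodology to bridge the two:

1. **CFP retrieval** — smooth daily NEE with a 15-day moving average, find a
   10-day transition window whose first five values and last five values
   straddle zero, and regress NEE on day-of-year within it; SCU/ECU is the
   zero intersection `−β₀/β₁`.
2. **LSP retrieval** — clean 16-day composite vegetation-index series
   (NDVI/EVI) with an iterative upper-envelope Savitzky–Golay filter, then
   retrieve the start and end of growing season (SOS/EOS) by six methods from
   the three classic families (global/local thresholds, delayed moving
   average, double-logistic function fitting), ranked against the flux dates.
3. **Climate drivers** — accumulate growing degree-days (base 0 °C) and total
   precipitation over 18 candidate impact windows spanning 60 days before to
   20 days after SOS/EOS, and keep, per biome and metric, the window with the
   highest R² that passes an F-test at α = 0.05.
4. **Estimation** — fit per-biome least-squares models
   `CFP = β₀ + β₁·LSP + Σ βⱼ·driverⱼ`, reported with R², RMSE, bias, the
   overall F-test and leave-one-out cross-validation.

Because real tower/satellite archives are not required, a **synthetic
site-year generator** produces coupled daily NEE, climate and composite VI
series with analytically known transition dates (double-logistic curves whose
zero crossings are found by bisection to 10⁻⁶ day), so every stage — and the
end-to-end regression — is validated against ground truth.

## Worked example

```python
import fluxpheno as fp

# a designed cohort: SCU = 10 + 1.0*SOS + 0.1*GDD(-20, 0) + noise
from fluxpheno import experiments
res = experiments.run_coefficient_recovery(seed=11)
print(res.coefficients)   # {'intercept': 10.195, 'sos': 0.99861, 'gdd': 0.09985}
print(round(res.r_squared, 4), round(res.loocv_rmse, 3))  # 1.0 0.092

ident = experiments.run_driver_identification(seed=11)
print(ident.window, ident.selected)  # (-20, 0) True
```

The recovery run fits the designed cohort end to end — NEE → SCU, VI → SOS,
degree-days over the designed window, OLS — and returns the design
coefficients to within fractions of a percent; the identification run
rediscovers the designed impact window out of the 18 candidates. (Numbers
above are the actual output for seed 11; other seeds vary in the last
digits.)

From a shell, the same pipeline runs over CSV files:

```bash
fluxpheno simulate --n 30 --seed 1 --out data/
fluxpheno run-all data/ --out results/
```

`results/models.csv` then holds one row per biome and metric with the fitted
coefficients, R² (%), RMSE (days) and their cross-validated counterparts, and
`results/observed_vs_estimated.csv` the per-site-year scatter.

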