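# democlim

Plant populations track the weather: in a wet year a desert herb recruits,
in a hot year an alpine cushion plant loses adults. `democlim` is a tested,
reusable pipeline for quantifying those responses from long-term structured
demographic data. It links yearly asymptotic population growth rates (λ)
computed from matrix population models (MPMs) or integral projection models
(IPMs) to standardized precipitation and temperature anomalies, and then
asks which sites and which species respond most strongly.

It is written for population ecologists working with collections of annual
projection matrices (e.g. COMPADRE-style data) plus monthly site climate.
A first-class synthetic-data module generates whole studies with known
ground-truth coefficients, so every stage of the pipeline is verifiable by
parameter recovery.

## The model

For each population, yearly log growth rates are regressed on census-
aligned climate anomalies with an autoregressive error term:

```
log(λ)_y = α + β_p P_y + β_t T_y + ε_y
ε_y      = ρ ε_{y−1} + η_y
```

where `P_y` and `T_y` are z-scores of total annual precipitation and mean
annual temperature over the 12 months preceding the census of year `y`,
standardized against a 40-year site baseline. Up to six candidate models —
the baseline, three quadratic variants (only for series longer than 14
years), and two covariate-interaction variants — are compared by AICc; the
selected model's coefficients are combined into one effect size per
climate variable (e.g. β = β_p + β_p2 for a quadratic fit), with SEs
combined by literal addition.

Three follow-up analyses use the per-population effect sizes:

- a pooled linear mixed model `log(λ) = α + βP + ηT + θP×T` with random
  population intercepts and slopes (overall climate effect);
- simulation-based **meta-regressions** of effect sizes on site water
  availability (WAI = MAP − PET) and mean annual temperature (linear), and
  of absolute effect sizes on log generation time `T` (gamma, log link).
  Uncertainty is propagated by simulating 1000 datasets with each effect
  perturbed by its SE, fitting a 1/SE-weighted regression to each, then
  drawing 1000 values per fitted slope — 10⁶ pooled values give the 95% CI
  and a one-tailed test (significant when >95% of draws fall below zero);
- ANOVA + Tukey HSD across plant types (graminoid, herbaceous, fern,
  woody, succulent), with hypothesis re-runs excluding divergent types.

Generation time is computed from each population's mean matrix as
`T = log(R0)/log(λ)` with `R0` the dominant eigenvalue of `F(I−U)⁻¹`.

## Worked example

Generate a 12-population synthetic study whose absolute climate effects
decline with generation time (planted slope −0.5 on the log scale), then
run the full pipeline:

```
$ democlim simulate --n-populations 12 --seed 7 --out demo/study
$ democlim run-all --study demo/study --out demo/results --seed 7
effects: 24 rows -> demo/results/effects.csv
overall: beta=-0.0985 eta=-0.0058 theta=0.0070
H2_precip_vs_WAI: beta_meta=-0.0002413 frac_below_zero=0.927 significant=False
H3_temp_vs_MAT: beta_meta=-0.00732 frac_below_zero=0.762 significant=False
H4_precip_vs_logT: beta_meta=-0.4192 frac_below_zero=0.997 significant=True
H4_temp_vs_logT: beta_meta=-0.4694 frac_below_zero=0.998 significant=True
```

Reading the output: each of the 12 populations yields one precipitation
and one temperature effect size (24 rows). The aridity (H2) and mean-
temperature (H3) meta-regressions are not significant — fewer than 95% of
the pooled simulated slopes fall below zero — while both generation-time
meta-regressions (H4) are: populations of longer-lived species respond
less strongly to climate anomalies, and the fitted gamma slopes (−0.42,
−0.47) recover the planted −0.5 within the uncertainty of a 12-population
study. The `overall:` line reports the pooled mixed-model fixed effects,
which here reflect the mix of planted positive and negative responses.

Library use mirrors the CLI:

```python
from democlim import synthetic_data as syn
from democlim.pipeline import RunConfig, run_pipeline

config = syn.make_ensemble(12, seed=7, meta_slope_logT=-0.5)
paths = syn.generate_study(config, seed=7, out_dir="demo/study")
result = run_pipeline(RunConfig(
    matrices_path=str(paths["matrices"]), climate_path=str(paths["climate"]),
    sites_path=str(paths["sites"]), populations_path=str(paths["populations"]),
    output_dir="demo/results", seed=7,
))
print(result.meta["H4_precip_vs_logT"].beta_meta_point)
```

## Data formats

- **matrices CSV** (long format): `pop_id, year, stage_from, stage_to,
  U_value, F_value` — one row per matrix cell, 1-based stage indices.
- **climate CSV**: `site_id, year, month, precip_mm, tmin_c, tmax_c`.
- **sites CSV**: `site_id, census_month, map_mm, pet_mm, mat_c`.
- **populations CSV**: `pop_id, site_id, plant_type, covariate_kind`.
- optional **covariates CSV**: `pop_id, census_year, covariate`.

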