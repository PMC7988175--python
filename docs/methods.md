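# Methods

This note documents the statistical model the package implements, the
numerical and design choices behind it, what the synthetic-data generator
does and does not emulate, and the known limitations.

## Demographic quantities

A population-year is a projection matrix `A = U + F`: `U` holds per-capita
survival/growth transition probabilities (each column sum ≤ 1 — an
individual survives at most once per year), `F` per-capita recruit
production. The asymptotic growth rate λ is the dominant eigenvalue
modulus of `A`; for an irreducible nonnegative matrix this is the Perron
root. Reducible matrices — common in real databases, where some stages
feed nothing back into the life cycle — are accepted with a warning.

Generation time is `T = log(R0)/log(λ)`, with `R0` the dominant eigenvalue
of `F(I−U)⁻¹`, the standard choice for stage-structured plant models and
computable directly from the matrices. When `|log λ| < 1e−8` the ratio
degenerates; the fallback is the R0-weighted mean age of reproduction of a
newborn cohort, obtained by summing the age-from-stage expansion in closed
form: `T = 1'F(I−U)⁻²c / 1'F(I−U)⁻¹c`, with `c` the stage distribution of
newborns (stable-stage-weighted column mix of `F`). Both quantities need
`(I−U)` invertible: a `U` with spectral radius ≥ 1 (immortal stages) or an
`F` with `R0 = 0` is rejected. A population observed over several years is
summarized by the element-wise mean of its yearly `U` and `F` when a single
generation time is needed for the meta-regression; this represents the
average life cycle rather than any single year's.

IPM kernels are discretized by the midpoint rule (default 100 mesh points;
entry `(i,j) = kernel(z_i, z_j)·h`), with survival/growth and fecundity
components kept separate so the same demographic quantities apply.
Convergence should be checked by doubling the mesh (the test suite does
this for a smooth Gaussian-growth kernel; λ moves by < 1e−3).

## Climate anomalies

Annual climate is aggregated over the 12 months preceding each census:
a census in month `m` of year `y` uses months `m..12` of `y−1` and
`1..m−1` of `y` — the census month itself is excluded, reading "the 12
months preceding" literally. Precipitation is summed; temperature is the
mean of `(tmin+tmax)/2`. Anomalies are z-scores against a 40-year baseline
(configurable, minimum 30 — the conventional floor for climate normals)
ending at the population's last census year. The baseline SD uses the
`n−1` denominator by default with a config switch for `n`; the convention
is not universally fixed and the switch makes the choice auditable. A
fixed (rather than per-census-year sliding) baseline keeps anomalies of
one population mutually comparable.

Sample skewness (adjusted Fisher–Pearson) of the baseline annual values is
reported with a flag at `|skew| > 1`; the flag never drops data — strongly
skewed distributions merely weaken the recurrence-interval interpretation
of z-scores, under which anomalies beyond 1 and 2 SD recur every 6 and 44
years (`round(1/Φ̄(z))`).

The water availability index is `WAI = MAP − PET` (mm/yr), a coarse but
widely comparable aridity proxy; PET is an input, not computed.

## Per-population regression

The response is the series of yearly `log λ`. The error model is a
stationary AR(1); estimation is exact Gaussian maximum likelihood: for a
candidate ρ the Prais–Winsten transform whitens the series (first
observation scaled by `√(1−ρ²)`), regression coefficients and innovation
variance are concentrated out, and the resulting 1-D likelihood is
optimized over ρ ∈ (−0.999, 0.999) by bounded scalar minimization. With
spatial replicates, one ρ per replicate is estimated (L-BFGS-B over the ρ
vector) while coefficients are shared; on optimizer failure an iterated
feasible-GLS (Cochrane–Orcutt-style) loop is the documented fallback.
The implementation agrees with `statsmodels` ARIMA(1,0,0)+exog maximum
likelihood to ~1e−4 in coefficients and ~1e−11 in log-likelihood (test
suite), and collapses exactly to OLS when ρ is fixed at 0.

Standard errors use the GLS covariance at the ML ρ with the residual
variance df-corrected (`n − p`), matching common GLS conventions; the
log-likelihood itself uses the ML variance (`n`). The AICc parameter count
is `k = p + 2`: coefficients, ρ, and the innovation variance — penalizing
the correlation parameter keeps candidate comparisons internally
consistent.

Candidates: the baseline (intercept, P, T) always; quadratic variants
(`+P²`, `+T²`, both) only for series strictly longer than 14 years, where
model selection between linear and quadratic forms becomes reliable;
interaction variants (covariate main effect + covariate × P, or × T — one
interaction per model, never both) only when a non-climatic covariate
exists and varies within the population. Selection is minimum AICc, with
near-ties (ΔAICc < 1e−9) resolved toward fewer parameters, then the
baseline.

Effect-size combination for a selected non-baseline model: quadratic →
`β = β_lin + β_quad`; continuous-covariate interaction → `β = β_lin +
β_int·E(C)`; categorical interaction → `β = β_lin + β_int·0.5` (the mean
effect across the two categories). The combined SE is the literal
arithmetic sum of the two terms' SEs — deliberately conservative — with a
quadrature switch for users who prefer the root-sum-of-squares.

## Pooled mixed model

All population-years enter `log λ = α + βP + ηT + θP×T` with random
population effects on intercept and both slopes, fit by REML via
`statsmodels` MixedLM. No quadratic terms: individual series rarely carry
enough years to identify them in the pooled fit. A singular random-effects
fit triggers a documented fallback to a random intercept only, with a
warning.

## Simulation meta-regression

Inputs are per-population effect sizes with SEs plus a predictor (WAI, MAT
or log T). For each of `n_datasets = 1000` simulated datasets each effect
is drawn from `N(β, SE)`; a weighted regression is fit with weights `1/SE`
(as stated: inversely proportional to the SE, not the variance; `1/SE²`
available by config); from each fitted slope `β_meta` with standard error
`σ_meta`, `n_draws = 1000` values are drawn from `N(β_meta, σ_meta)`. The
pooled 10⁶ values give the empirical 2.5/97.5-percentile CI and the
one-tailed test: significant iff strictly more than 95% of draws fall
below zero.

Signed effects regress linearly on WAI or MAT; absolute effects `|β|`
regress on log T with a gamma GLM (log link), respecting the positive
support. Perturbed `|β|` draws that land at exactly zero are truncated at
machine epsilon, preserving the draw count. The linear family is solved in
closed form for all datasets at once (one matrix product); equality with a
per-dataset `statsmodels` WLS fit is asserted in the test suite to 1e−10.
The point estimate is the weighted fit to the unperturbed effects.

The propagation is deliberately conservative: perturbing effects by their
SE inflates residual variance in each simulated fit, so under a zero-slope
null the one-tailed test rejects well below its nominal 5% (≈ 2% in the
calibration runs here).

## Plant types

One-way ANOVA and Tukey HSD compare raw (unweighted) effect sizes across
graminoids, herbaceous perennials, ferns, woody species (shrubs and trees
merged) and succulents — succulents kept as their own type. Flagged types
can be excluded and the affected hypotheses re-run; excluding a type
holding more than 78% of effects emits a warning, since the remainder no
longer supports meaningful inference.

## Synthetic-data generator

The generator emulates the statistical structure the analysis assumes, at
the study conditions the pipeline is designed for:

- **Climate**: monthly values drawn independently per calendar month from
  site-specific normals (precipitation truncated at 0 by redraw;
  temperature untruncated; tmin/tmax placed ±2 °C around the drawn monthly
  mean). Sites carry ≥ 46 years so a 40-year baseline plus at least six
  transitions fit.
- **Populations**: two-stage juvenile/adult ladders by default. Ensembles
  draw adult survival in [0.05, 0.97] and tie fecundity to adult mortality
  (`fec ∝ 1 − s_adult`), which keeps baseline λ near 1 and spreads
  generation time over more than an order of magnitude (≈ 2–50 yr) — the
  realistic pattern that long-lived plants recruit rarely.
- **Responses**: yearly target `log λ` is the linear predictor (known
  β_p, β_t, optional quadratic/interaction terms) plus stationary AR(1)
  noise (initial draw at variance `σ²/(1−ρ²)`). The yearly matrix scales
  baseline fecundities — and survivals only while column sums stay ≤ 1 —
  by a common factor found by Brent root-finding so the dominant
  eigenvalue hits the target exactly (to ~1e−12): matrices stay
  biologically valid while `log λ` is exactly controllable.
- **Planted meta-slope**: ensemble effect magnitudes follow
  `|β| = exp(−1 − 0.5·log T)` with random sign (β within ±0.3 over the
  generated T range), so the gamma meta-regression has a known true slope.
  Ensemble noise levels are `noise_sd ~ U(0.05, 0.2)`,
  `ρ ~ U(0, 0.6)`, series lengths 15–40 transitions.
- **Seeding**: one master seed; per-population streams derive from a
  stable SHA-256 hash of the pop_id, so the population set is
  order-independent and fixtures are byte-identical across reruns.

What it does **not** emulate: spatial climate gradients within a site,
density dependence, observation error on the matrices themselves,
seed banks, correlated monthly weather, or trait–climate confounding.
Passing recovery tests therefore demonstrates that the estimation chain is
correct under its own assumptions — not that those assumptions hold in any
particular field dataset.

## Problem sizes and numerical choices

Recovery experiments use a 200-population ensemble (CI coverage of the
planted β_p between 90% and 98% with t-based intervals; gamma meta-slope
CI covering the planted −0.5). Null calibration uses 200 replicates of a
30-effect study at 200×200 draws per replicate — the reduced draw count
estimates the rejection rate with ample precision while single analyses
keep the full 1000×1000 default. Root-finding tolerances: `brentq` at
xtol 1e−13 for λ targeting; ρ optimization at xatol 1e−10. Degenerate
inputs rejected with named errors: zero baseline SD, constant vectors for
skewness, all-zero matrices, collinear designs, series shorter than the
parameter count + 2.

## Limitations

- The generation-time definition is one of several in use; analyses mixing
  `T` sources should confirm the convention matches. Recovery tests use
  the package's own `T` consistently.
- SEs of combined effects (literal sum) overstate uncertainty relative to
  quadrature when the two estimates are near-independent.
- The AR(1) ML estimate of ρ is biased downward in short series (n < 15);
  coefficient SEs remain approximately calibrated (the coverage test
  brackets this).
- The pooled mixed model assumes Gaussian random effects and homoscedastic
  residuals across populations; populations with very different noise
  levels are not reweighted.
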