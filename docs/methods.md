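# Methods

This note records the modelling and numerical choices behind `bhpm`, in the
spirit of a model-documentation page: what is assumed, what is tunable, and
what the synthetic experiments do and do not establish.

## Data model and geometry

The unit of analysis is a PM2.5 mass-monitoring location with a monthly
record of deaths `Y_ij`, population at risk `N_ij` and previous-1-year
average exposure `x_ij`.  Distances are great-circle miles (haversine,
sphere radius 3958.8 mi; sub-0.5% error at the 6-mile scales that matter
here); a `planar` flag treats coordinates as miles for hand-checkable test
geometry.  Two linkage conventions are fixed package-wide: "within 6 miles"
is a *strict* inequality everywhere, and equidistant source monitors
tie-break to the lexicographically smallest id.  A centroid point lying in
two monitors' buffers contributes to both by default (`aggregate_all`
offers assign-to-nearest).

Exposure windows: the previous-year average at a month start is the mean of
daily values over the 365 calendar days ending the day before.  A month is
emitted only when at least `min_coverage` (default 0.5) of the window has
observations; this is what makes per-site record counts vary.  Covariate
standardization uses the n−1 SD, so second-level coefficients are per-1-SD
effects.

## Two-stage estimation

Stage 1 maximizes the per-location Poisson likelihood by safeguarded Newton
iteration (line search with a tolerance relative to |log L|, so float noise
cannot stall it); the inverse observed information is the 2×2 sampling
covariance `V_i`.  Degenerate locations — all-zero deaths, no exposure
variation, or fewer than `min_months` (default 6) records — are flagged and
excluded from stage 2.

Stage 2 treats `(α̂_i0, α̂_i1) ~ N((X0β)_i, (X1γ)_i; V_i + C)` with the
equation errors independent (`C = diag(σ0², σ1²)` per site) or spatially
correlated (`σ²e^{−φd} + τ²I` per equation; the intercept and slope error
processes are independent of each other, as the model writes separate
errors with no cross-covariance).  The sampler integrates the latent site
effects out analytically and alternates

* a joint conjugate Gaussian draw of (β, γ) given the variance parameters —
  the sampling covariance `V_i` correlates the two equations, so the draw
  is joint rather than per-equation;
* adaptive random-walk Metropolis on the log of each equation's variance
  parameters (step tuned toward 25–40% acceptance during burn-in, frozen
  after).

Marginalization is not cosmetic: slope estimates carry sampling noise an
order of magnitude larger than the slope equation's error SD, and a
centered latent-variable Gibbs scheme mixes very slowly in exactly that
regime (we observed R̂ ≈ 1.2 on the slope intercept where the marginal
sampler gives R̂ ≈ 1.00).  Latent site effects are reported through their
conditional means averaged over draws.

Priors (configurable via `Priors`): N(0, 10²) on all regression
coefficients; half-normal(0, 1) on the error SDs σ and τ; uniform on log φ
over the range implying a 40-mile correlation between 0.01 and 0.99.  The
half-normal SD prior is deliberately kept even though it forfeits
conjugacy — the 1-D Metropolis update it requires is cheap.  Defaults are
3 chains × 10,000 iterations with 5,000 burn-in; convergence is monitored
by split-R̂ (arviz), with a result flagged (never suppressed) above 1.1.

## DIC and model selection

Eight candidate structures cross {no covariates, constituents only,
confounders only, both} with {independent, spatial} errors; the same block
choice applies to both equations, and x̄ enters the intercept design
whenever any covariates do (excluded in the no-covariate structure).
DIC = D̄ + pD uses the marginal (latent-integrated) likelihood of the
stage-1 estimates and the plug-in posterior mean θ̄.  One numerical choice
matters: positive variance/decay parameters are averaged **on the log
scale** for θ̄.  Their posteriors are strongly right-skewed (the decay in
particular), the natural-scale mean is then an unrepresentative plug-in,
and because DIC = 2D̄ − D(θ̄) an inflated D(θ̄) systematically *deflates*
DIC for the spatial models — enough, in our replicates, to make the
saturated spatial structure win on data generated without spatial
correlation.  With the log-scale plug-in the generating structure is
recovered reliably and negative-pD pathologies (still warned about)
largely disappear.

## Spatial GP imputation

Each constituent surface is a constant-mean GP with exponential covariance
plus nugget, fitted on observed monitors by Metropolis-within-Gibbs
(conjugate mean; log-scale random walks on sill, nugget, decay).  Priors:
inverse-gamma(2, sample variance) on sill and nugget, uniform log-decay as
above, near-flat normal on the mean.  Imputation is the kriging conditional
mean averaged over thinned hyperparameter draws — single-value imputation,
mirroring the common field practice; predictive SDs are returned for users
who want multiple imputation, but the default deliberately does not
propagate imputation uncertainty into stage 2 (a known limitation of the
procedure it reproduces).  Cross-validation uses k = 5 folds by default.

A caution for interpreting the GP fits themselves: from a single field
realization in a bounded domain, sill and decay are not separately
consistently estimable for the exponential family (only microergodic
functionals such as their product are).  The recovery tests therefore check
sill·decay, the nugget, the mean and the implied 40-mile correlation, not
the raw sill.

## Synthetic-data generator

The generator runs the two-level model forward with known truth and is
calibrated, once, to the summary scale of a large eastern-US elderly-cohort
monitoring panel:

* 518 locations by default, 33–70 monthly records each; population at risk
  lognormal (mean ≈ 14,500/month), constant within site.
* Monitor locations uniform in a lon/lat box.  The default box
  (≈ 31,500 sq mi, mid-Atlantic) is sized so that a uniform draw reproduces
  the *effective density* of the real networks — about half of 518 mass
  monitors fall within 6 miles of one of 174 speciation monitors — rather
  than their full geographic extent, since real monitors cluster in cities.
* Constituent surfaces: independent GPs per constituent with means/SDs
  (EC 0.68 ± 0.24, OCM 4.05 ± 0.90, SO4 4.14 ± 0.80, Si 0.09 ± 0.03,
  NO3 1.68 ± 0.85, Na 0.17 ± 0.07 μg/m³), nugget fraction 0.05, and decay
  solved so the 40-mile correlations are (0.05, 0.20, 0.21, 0.19, 0.21,
  0.20) — the values estimated for these constituents on real networks.
* Confounders: multivariate normal at survey scales with the three reported
  large correlations (income↔high-school 0.62, high-school↔white 0.50,
  white↔black −0.84), remaining pairs 0, projected to the nearest positive
  definite correlation matrix.
* Exposure: site means N(13.7, 2.13²) μg/m³; month-to-month deviations
  AR(1) with ρ = 0.9 and stationary SD 1.0 μg/m³ — previous-year averages
  of adjacent months share 11/12 of their window, so high autocorrelation
  is structural, and the AR(1) is a declared stand-in, not an estimate.
* Default truth: β_0 = log(0.0045) (≈ 4.5 deaths/month/1,000), constituent
  main effects +1.3%, +1.4%, +1.2% per 1 SD on EC, Si, NO3, modest
  confounder effects, σ_ε0 = 0.05; γ_0 = 0.008, modifiers on SO4 (+0.4%)
  and Na (+0.3%) per 1 SD, σ_ε1 = 0.004.  The implied site ranges
  (baseline rates ≈ 3.4–5.7 per 1,000; slopes ≈ −1% to +3% per μg/m³)
  match what such panels report.

What the generator does **not** emulate: cross-constituent correlation
(surfaces are independent per constituent, matching the per-constituent
imputation model), correlation between constituents and confounders or
exposure, seasonality in mortality, within-site population drift, and
cause-specific deaths.  Passing tests therefore demonstrate internal
consistency of the estimation chain under the stated generative model —
not robustness to confounding structures the generator does not contain.

## Validation experiments and problem sizes

`bhpm.experiments` (used by both the test suite and
`scripts/acceptance.py`) runs: (1) stage-1 MLEs vs a brute-force 2-D
likelihood grid (step 10⁻³) on 10 sites × 40 months; (2) closed-form
degenerate cases; (3) 50 replicate studies at 241 sites × 60 months with
3 × 2,000-iteration chains, checking that every coefficient's posterior
mean falls within 3 posterior SDs of truth and that pooled 95%-interval
coverage is nominal; (4) DIC selection over 25 strong-effect and 25 null
replicates at 80 sites with 800-iteration chains; (5) imputation at 518
sites with 53% masked; (6) byte-identical outputs across two identical
pipeline runs.  Replicate counts and chain lengths are chosen so the whole
battery runs on a single CPU in minutes; they are validation studies, not
power analyses.

## Known limitations

Stage 1 is pure Poisson (no overdispersion term) and has no time-varying
confounders, by design of the target model.  The two-stage scheme
conditions on `V_i` as known; a fully joint sampler over both levels could
be swapped in behind the same interfaces.  Single-value imputation
understates uncertainty at imputed sites.  Age-group analyses are supported
only by pre-filtering the input panel, since the model itself is identical
across strata.
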