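# Methods

## The model

`harpseal_ipm` implements an integrated population model (IPM) for the
Northwest Atlantic harp seal (*Pagophilus groenlandicus*): an age-structured,
annual-time-step matrix model whose vital rates are driven by density,
climate, sea-ice conditions and four sources of human removals, fit jointly
to four observed data streams in one Bayesian posterior.

### Competing hazards

All mortality is expressed as additive instantaneous hazards, so annual
survival is the joint probability of escaping every cause:

    S0(t)    = exp(−[h0(t) + hIC(t) + Σ_j hH0,j(t)])        (young of the year)
    SA(i,t)  = exp(−[hA(i,t) + Σ_j hHA,j(t)])               (ages i = 1..36)

and the expected share of deaths from cause *j* is the hazard ratio
`h_j / Σ h` — independent of the within-year ordering of risks. The test
suite checks this partition against a Monte-Carlo simulation of independent
exponential competing risks.

Natural log hazards follow a Siler-type age quadratic
`γA(i) = α1 − α2(i−1) + α3(i−1)²` with a young-of-the-year (YOY) increment
`γ0 = γA(1) + υ`. Density and climate act multiplicatively on the hazard
scale through `γD0 = φ_S · Ñ(t) · exp(δ·NLCI(t) + ε_S(t))`, where `Ñ` is
abundance in millions (the `density_scale` configuration entry) so that
`φ_S` is O(0.1–1). Adults feel an attenuated version of the same effect:
`exp(γDA) = (exp(γD0) − 1)·ζ + 1`, with `ζ ∈ [0,1]` interpreted as the
adult fraction of the per-capita YOY effect.

Ice hazards for YOY are a saturating logistic in the standardized ice
anomaly, `hIC(a,t) = logit⁻¹(−ψ0 − ψ_a·IC(a,t))`, weighted across the three
whelping areas by the proportion of pups born in each (`P(a,t)`). We use
the logistic output directly as the area-level hazard: it is bounded in
(0, 1), vanishes in good-ice years, and saturates as anomalies become
strongly negative, matching the threshold behaviour the index is meant to
capture. `P(a,t)` is observed in survey years and drawn from a Dirichlet
distribution otherwise, with concentrations fit by maximum likelihood
(Minka fixed-point iteration, convergence 1e-8 on the log-likelihood;
zeros floored at 1e-4 before fitting because the Dirichlet excludes the
simplex boundary).

Human-removal hazards are hierarchical: per source *j* (Canadian
commercial, Arctic hunt, Greenland hunt, bycatch) the year-specific log
hazards are Normal(γ̄_j, σ_H,j) around estimable hyper-means.

Fecundity is the complement of the hazard of not becoming pregnant:
zero below age 3, `exp(−exp(β1 + β2(8−i)² + φ_F·Ñ(t−1)·∇))` through age 8
and asymptotic beyond, with `∇ = exp(δ·NLCI(t−1) + ε_F(t))` giving a
one-year-lagged climate effect. The young-adult branch is extended down to
age 3, where the `(8−i)²` penalty naturally produces a near-zero rate.

### Projection and predicted observables

Vital rates populate a 36 × 36 Leslie matrix (first row
`R(i,t) = 0.5·F(i,t)·S0(t)`, subdiagonal survival, pooled terminal class).
The initial vector is `N0 ×` the stationary age distribution (SAD) of the
first year's schedule, with density evaluated at `N0`; the SAD is obtained
by repeated projection with renormalization (L1 tolerance 1e-10, cap
10,000 iterations). Abundance counts both sexes with identical survival;
the 0.5 factor in reproduction and pup predictions encodes the 50:50 sex
ratio. Demographic stochasticity is ignored — at multi-million abundance
it is negligible against environmental variation.

Predicted observables: pups countable at the survey
`YOY = 0.5 Σ n F · S0^π` (the annual parameter `π ∈ (0,1)` is the fraction
of first-year mortality falling before the survey); the adult age
distribution over ages 5–36; and reported removals per source, obtained by
multiplying total deaths by the hazard-ratio cause fraction and by the
reporting fraction `Q = 1 −` struck-and-loss (Canadian YOY 1% before
1983 / 5% after; Arctic and Greenland YOY 50%; adults 50% in all hunts;
bycatch fully reported). Adult removals are spread across ages in
proportion to the standing age structure.

### Data model

| dataset | distribution | dispersion |
|---|---|---|
| pup-production surveys | gamma(mean = prediction, SD = design SE) | fixed by survey SE |
| pregnancy by age × year | beta-binomial(NF, ηF, η(1−F)) | estimable η |
| age composition (ages ≥ 5) | Dirichlet-multinomial(ΣNC, τ·Agedist) | estimable τ |
| reported removals | negative binomial, variance = (CV·mean)² | assigned CV |
| YOY share of removals | beta-binomial(total, κ·ratio, κ(1−ratio)) | assigned κ |

The negative-binomial size is `ξ = μ²/((CV·μ)² − μ)`; when the assigned CV
would imply variance at or below the mean the term falls back to Poisson
with a warning (variance floor). All kernels are written in gamma-function
form so they accept non-integer predictions, and each is cross-checked
against the corresponding `scipy.stats` distribution in the tests. Years
with missing datasets contribute nothing; no imputation.

### Priors and inference

Cauchy(0, 1) on the climate effect δ; Cauchy(0, 2.5) on the signed
log-hazard parameters (α, β, γ̄) — we place the prior on the signed
parameter directly rather than on a positive offset version, which is the
same family up to a location shift; half-Cauchy(2.5) on φ_S, φ_F and all
σ; half-Cauchy on N0 (scale 5 million), η and τ (scale 50); and moderately
informative priors on the remaining bounded parameters: ψ0 ~ Normal(2,1)
truncated positive, ψ_a ~ half-Normal(2), ζ ~ Beta(2,2),
υ ~ Normal(0.7, 0.5), π ~ Beta(2,18) (mean 0.1). All are configurable per
parameter and recorded in every fit's metadata.

The posterior is sampled with an affine-invariant ensemble sampler (emcee,
differential-evolution moves), run as several independent ensembles so
that split R-hat applies across them. Positive parameters sample on the
log scale and unit-interval parameters on the logit scale, with Jacobian
corrections. Chains initialize from a small ball around a posterior-mode
estimate (Nelder-Mead from prior medians, shrunk toward the base
configuration if the medians give a degenerate trajectory).

At desk scale the fit estimates the structural parameters (N0, α1, β1,
φ_S, δ and the eight harvest hyper-means by default) with year effects
held at their hierarchical means; the full latent-year-effect treatment is
reachable through the same machinery but is far beyond a laptop-scale
budget, and the reduced design is what the recovery tests validate. A
parameter vector whose trajectory collapses below one pup is assigned zero
posterior mass — the survey gamma shape diverges there.

Diagnostics follow standard practice for hierarchical ecological models:
split R-hat (< 1.1) and effective sample size per parameter; posterior
predictive checks per dataset using the summed squared Pearson residual
(chi-square discrepancy) with Bayesian p in (0.05, 0.95) taken as
adequate; PSIS-LOO on the pointwise log-likelihood (one term per survey
point, pregnancy row, age-composition year, removal total and age split)
with observations flagged at Pareto-k > 1; and out-of-sample hindcasts
that re-project from N0 with parameters drawn from the joint posterior,
survival/fecundity random effects redrawn from their fitted SDs, and
harvest year-hazards held at their hyper-means — an adequate fit keeps the
best-fit trajectory inside the hindcast envelope.

### Life-stage simulation analysis

For each posterior draw and period (1951–1982, 1983–1999, 2000–2019, and
the full span; near-equal tertiles for shorter synthetic spans) we average
each hazard over the period's years, rebuild the projection matrix, and
take its dominant eigenvalue λ by power iteration (tolerance 1e-10;
verified against direct eigen decomposition). Sensitivities multiply one
hazard at a time by 1.10 — fecundity perturbed on the −log scale, i.e. as
the hazard of not becoming pregnant — and report (λ' − λ)/0.10.

Variance contributions pool draw × year samples within a period, compute
the annual asymptotic λ of each year-specific matrix, and regress λ on
each standardized hazard separately; the contribution of a hazard is the
R² of its single-rate regression, normalized across hazards to sum to one
(the normalization is recorded in output metadata; raw R² is also
reported). Age-structured rates (adult natural hazard, fecundity hazard)
are collapsed to abundance-weighted scalars for the regression. Hazards
with zero variance get share zero by convention. λ_sim distributions are
compared to realized annual growth λ_obs = N(t+1)/N(t) per period via a
histogram overlap coefficient and a two-sample KS summary.

## Synthetic data

The generator produces complete studies from the model's own generative
structure: NLCI and per-area ice anomalies as stationary AR(1) series
(coefficient 0.5, marginal SD 1 — both indices are standardized
anomalies), whelping proportions from a Dirichlet, year effects from their
hierarchical distributions, the latent trajectory by projection, and
observations from the four data-model distributions after Q-thinning.

The default full-span scenario (1951–2019, 36 ages) includes step changes
in the harvest hyper-means (a large Canadian YOY reduction in 1983,
resumption in 1996, reduction in 2009; increased Greenland pressure after
1996) and a declining ice trend after 2000, so the synthetic population
traverses the qualitative regimes that make the analysis interesting —
decline under heavy harvest, recovery after harvest reduction, renewed
pressure from density, ice and harvest. The true parameter values are
scenario settings chosen for that qualitative behaviour; they are not
estimates of the real population.

The reduced scenario used by the recovery tests and the acceptance script
(30 years, 12 age classes, annual surveys with 10% CV, 30 females
sampled per age and year, 300 aged animals per year, deterministic year
effects, no harvest eras) deliberately produces a growth-to-saturation
trajectory: without contrast in abundance the density and climate effects
are weakly identified, which is a property of the design, not of the
estimator. What passing recovery tests demonstrate is that the estimator
is consistent under the model's own assumptions at these sample sizes;
they do not establish robustness to the mis-specification real data would
bring (spatial structure, observer effects, non-AR(1) climate spectra,
age-reading error).

## Numerical choices

- Problem sizes: recovery uses 10 replicate studies, 4 chains × ~2,100
  saved draws each (300 burn-in sweeps, 150 saved sweeps thinned by 2,
  28 walkers per chain); the diagnostics subsample ≤ 400 draws for LOO and
  150 for the posterior predictive check. The projection recursion runs in
  a compiled (numba) kernel whose algebra is asserted equal to the
  module-level operations.
- Dirichlet ML: Minka fixed-point with Newton inverse-digamma, tolerance
  1e-8, cap 2,000 iterations.
- Power iterations: SAD tolerance 1e-10 (cap 10,000), λ tolerance 1e-10.
- Fecundity hazard −log F is capped at 700 where F = 0 to keep period
  means finite; immature classes stay exactly zero.
- Ties/degenerate inputs: an all-zero age-count vector contributes zero
  log-likelihood with a warning; a projection matrix that annihilates the
  population raises; `σ_{a,p} = 0` in the ice reference window raises a
  dedicated error.

## Known limitations

- Year effects are fixed at hierarchical means in desk-scale fits; σ_S,
  σ_F, σ_H are therefore inputs, not estimates, at that scale.
- The ensemble sampler mixes slowly in the correlated (N0, α1, β1, φ_S)
  ridge; short chains give usable posterior means and SDs but R-hat can
  remain above 1.1 at desk-scale settings. Longer runs (production-scale
  settings of 10 chains × 20,000 saved draws) are a configuration change,
  not a code change.
- One shared climate coefficient δ serves both survival and fecundity by
  construction.
- The model is not sex- or space-structured; within-year hazard sequencing
  is intentionally not modelled.
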