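# Methods

## The surplus-production family

Aggregate surplus production treats the multispecies reef-fish assemblage as a single
stock.  Annual production at standing biomass B (t/km²) is

* Gompertz-Fox: `P = log(B0) · r · B · (1 − log B / log B0)` — peak at `B_MMSY = B0/e`,
  `MMSY = r·B0/e`;
* Pella-Tomlinson with exponent n > 1: `P = r/(n−1) · B · (1 − (B/B0)^(n−1))` — peak
  at `B0·n^(1/(1−n))`; n = 2 is Graham-Schaefer (peak at B0/2), and the n → 1 limit
  reproduces the Gompertz-Fox curve exactly.  This parameterization was chosen for
  that limit property; all logarithms are natural, biomass is t/km², catch t/km²/y.

P is defined (and negative) for B > B0 so that assessment of observations above
carrying capacity cannot fail.  The recovery trajectory dB/dt = P(B) from B_min has
closed forms in the whole family: Gompertz for fox
(`B(t) = B0·exp(log(Bmin/B0)·e^(−rt))`) and, via the substitution u = (B/B0)^(n−1)
which satisfies a logistic equation, `B(t) = B0·u(t)^(1/(n−1))` for Pella-Tomlinson.
An adaptive ODE integrator (rtol 1e−8) provides an independent numerical route,
cross-checked in the tests.  The PGMY window solves P(B) = f·MMSY by bracketed
root-finding (xtol 1e−10) on each side of B_MMSY; because P factorizes as
r·B0·g(B/B0), every reference point is proportional to B0 at fixed (r, family), which
the propagation code exploits.

## The joint hierarchical model

Three lognormal sub-likelihoods share parameters.  With standardized covariates x:

* reserves (i): `log B_i ~ N(μ_i, σ_i)` where
  `B0_i = exp(log B0 + β1·x_oceanprod + β2·x_sst + β3·x_atoll + β4·x_coral)` and μ_i
  is the log recovery trajectory from the common B_min at reserve age t_i toward
  B0_i, plus sampling effects (depth, crest, lagoon/backreef, flat, point-count,
  sampling area), a reserve-size effect and the gravity effect.  Reserves share one
  B_min and one r (space-for-time substitution; per-reserve trajectories are not
  identifiable from single visits).
* remote reefs (j): `log B_j ~ N(log B0_j + sampling effects, σ_j)` with the same
  environmental construction of B0_j — remote reefs sit at their local unfished
  biomass and anchor the baseline.
* fished reefs (z): `log B_z ~ N(γ + sampling effects + β13·gravity + u_c, σ_z)`
  with jurisdiction random intercepts `u_c ~ N(0, σ_u)`.  This sub-model calibrates
  the sampling corrections used to marginalize observed biomass.

Note the structural asymmetries: the reserve mean carries the point-count dummy but
not distance sampling, the remote mean carries distance sampling but not flat habitat
or point counts, and the fished mean carries all sampling dummies.  The synthetic
generator assigns census methods and habitats so the same structure holds in the
data.

Priors: `log B0 ~ N(log 120, 1)`, `log r ~ N(−2, 1)`, `log Bmin ~ N(log 10, 1)`,
`β ~ N(0, 2)`, `γ ~ N(5, 5)`, and half-Cauchy(0,1) on all scales (implemented as a
Cauchy truncated at zero; sampled as log σ with the Jacobian term).  B0, r, Bmin and
the σ's are sampled on the log scale, making the posterior smooth and unconstrained.

**Covariate standardization.** Continuous environmental and methodological
covariates and reserve size are centered and divided by **two** standard deviations,
so their effects are comparable with the 0/1 dummies; categorical covariates are
dummy-coded against slope habitat and belt transects.  Gravity is deliberately left
unstandardized and uncentered: the intercepts then describe a reef with *zero* human
pressure, which is what makes the recovered B0 an unfished baseline rather than an
average-pressure one.  Missing coral cover is imputed at the covariate mean
(standardized value 0).  When a reserve has several survey years, one is chosen at
random (seeded) so reserves are equally represented.

## Sampling

The posterior is explored with Hamiltonian Monte Carlo implemented in numpy:

* analytic gradients of the joint log posterior (the trajectory term enters through
  g(m, w) = log B(t)/B0 with closed-form ∂g/∂m and ∂g/∂w per family); the test suite
  checks every coordinate against central finite differences at 1e−5 relative
  tolerance;
* dual-averaging step-size adaptation toward 0.95 acceptance;
* a **dense** mass matrix re-estimated from the warmup draws at three checkpoints
  (shrinkage-regularized covariance).  A dense metric matters because the fished
  intercept γ and the jurisdiction effects u_c are strongly correlated a posteriori;
  with a diagonal metric the effective sample size per iteration is several times
  smaller;
* trajectory length ε·L ≈ 1.5 in metric units, jittered ±30%; energy errors beyond
  1000 count as divergences and any post-warmup divergence fails the fit loudly.

Defaults are 4 chains × (1000 warmup + 1000 draws), seeded per chain; identical
seeds give identical draws.  On the desk-preset data (150 sites, ~29 parameters)
this takes on the order of a minute and yields bulk ESS of several hundred to a
thousand for the slowest parameter (typically the fished intercept or a
jurisdiction effect).  An affine-invariant ensemble sampler (emcee) run on the same log
posterior serves as an independent cross-check of the posterior means in the test
suite.

## Diagnostics

Split R-hat and bulk ESS come from ArviZ.  Posterior contraction is
`1 − Var_posterior/Var_prior` per parameter **on the sampling scale**: prior
variances are analytic for the normal priors (1 for the log-scale biomass
parameters, 4 for β, 25 for γ) and π²/4 for log of a half-Cauchy(0,1) (exact, by the
σ → 1/σ symmetry of |Cauchy|).  Jurisdiction random effects are excluded from the
contraction summary: their marginal prior variance (E[σ_u²] under a half-Cauchy) is
infinite, so the statistic is undefined for them.  Model families are compared by
PSIS-LOO expected log predictive density (ArviZ) using stored pointwise
log-likelihoods.

## Reference points, status and classification

For any site s, each posterior draw gives
`B0_s = exp(log B0 + β·x_env,s)`, `B_MMSY,s` and `MMSY_s` through the family's shape
constants, and the PGMY window.  Observed biomass is corrected to reference sampling
conditions — slope habitat, belt transects, average depth and sampling area — by
subtracting the sampling effects on the log scale (`B_marg`).  Status ratios
B_marg/B_MMSY and C/MMSY, the surplus at the current biomass, and the relative catch
potential P/MMSY are computed per draw and summarized by the median and the central
90% interval (5th–95th percentile; the interval convention is central because no
other construction is implied by a bare "90%").

Classification uses posterior medians (strict inequalities; a ratio exactly 1 counts
as *not below*): good condition (B > B_MMSY, C < MMSY), warning (B > B_MMSY,
C > MMSY), recovering (B < B_MMSY, C ≤ surplus), unsustainable (B < B_MMSY,
C > surplus).  Conservation concern is the complement of good condition; collapse is
B_marg ≤ 0.1·B0_s.  Draw-wise classification of every unit yields the uncertainty
intervals on the headline percentages.  Jurisdiction reference points are draw-wise
arithmetic means over member sites (exactly equivalent to averaging B0_s, by
proportionality); jurisdiction biomass is the mean marginalized fished biomass,
optionally MPA-weighted: `B_w = mean(B_marg)·(1−p_mpa) + mean(B0_s)·p_mpa`, an
optimistic convention that treats protected waters as unfished.  Sites or
jurisdictions missing catch get biomass-only status (category undefined); those
missing biomass get fishing-only status.

## Synthetic data

The generator emulates the three-subset structure at two scales: the full design
(70 reserves / 80 remote / 1903 fished in ~30 jurisdictions) and a desk preset
(30/20/100, 8 jurisdictions) for fast runs.  Covariate distributions are plausible
tropical-reef values — SST ~ N(28, 1.2) °C, ocean productivity lognormal around
600 mg C m⁻² d⁻¹, coral cover Beta(2,3), depth U(2, 18) m, sampling area lognormal
around 500 m², reserve ages U(0.5, 40) y, gravity lognormal around 5 (zero on remote
reefs), 25% atolls — identical across subsets so the space-for-time substitution has
covariate overlap (tested by KS distance).  Defaults for the generating parameters
are the prior centers (B0 = 120 t/km², r = 0.135 1/y, Bmin = 10 t/km²) with modest
effect sizes.  Remote labelling uses the 20-hour travel-time threshold plus an
uninhabited flag.

Catches are scaffolding for the assessment stage (the biomass model says nothing
about catch generation): `C = surplus(B_latent) · f · lognormal(0, 0.3)` with the
exploitation factor f drawn from a four-point mixture (0.3/0.8/1.3/2.5 with weights
0.35/0.25/0.20/0.20) chosen so all four fishery categories occur; surplus is floored
at 2% of the site MMSY so depleted sites still record small catches.  10% of fished
sites lose their coral-cover value to exercise the imputation path.

What passing tests on these data do **not** show: robustness to covariate
measurement error, spatial autocorrelation, non-lognormal residuals, catch
misreporting, or model misspecification of the recovery functional form — none of
which the generator produces.

## Ecosystem metrics

Total richness at a site is estimated by fitting a zero-truncated Poisson-lognormal
to the observed species-abundance counts (maximum likelihood; the Poisson-lognormal
integral is evaluated by 60-node Gauss–Hermite quadrature), giving a veil probability
p0 and the correction `S_obs/(1 − p0)`; fit quality is a chi-square test on pooled
abundance octaves at α = 0.05, and degenerate inputs fall back to observed richness
with a flag.  Scraping potential is Σ density × feeding rate × bite area over
parrotfish species-size classes; the bundled rate table is **synthetic** (plausible
magnitudes, marked in the filename) and meant to be replaced by measured rates.

Metric regressions use the sampling + environmental + gravity covariates with
jurisdiction random intercepts: gaussian on the log scale for length and richness
(REML mixed models), a variational-Bayes Bernoulli-logit for top-predator presence,
and a hurdle-lognormal for scraping whose zero part and positive part are estimated
independently (the likelihood factorizes; tested by perturbation).  Point estimates
are used rather than full posteriors — adequate for curve estimation and orders of
magnitude faster.

Trade-off curves smooth the marginalized metric against marginalized biomass with
penalized cubic B-splines (basis size 10, penalty chosen by the smoother's built-in
criterion, binomial link for presence/absence), and report percent changes of the
curve at B_MMSY and the PGMY bounds relative to its value at B0.  Presence/absence
observations cannot be marginalized on the response scale, so the logistic smoother
takes them raw.  Smoothing and the surplus posterior are overlaid independently; no
uncertainty is propagated from the surplus fit into the curves.

## Problem sizes and other choices

The default test and acceptance runs use the desk preset (150 sites) with 4 chains ×
(1000 + 1000); recovery and model-comparison checks use shorter 2-chain runs and
3–5 replicates.  These sizes were chosen so the whole suite completes in minutes
while every convergence threshold is met at the full default chain length.  The
simulation-based calibration of interval coverage is a 3-replicate smoke version of
the 20-replicate design, which is the scheduled (non-CI) variant.

Known limitations: one common B_min and r across all reserves; no explicit export
rate (gravity absorbs it phenomenologically — explicit export rates are not
identifiable from single-visit reserve data); no time dynamics at fished sites; the
Pella-Tomlinson exponent is never estimated from data (fixed-n variants are compared
by LOO instead); jurisdiction aggregation assumes sampled reefs represent the
jurisdiction.
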