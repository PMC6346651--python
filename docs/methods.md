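# Methods

## The system being modeled

Male sockeye salmon mature either as "jacks" — precocious males that return
after a single year at sea and spawn by sneaking — or as larger "hooknose"
males that stay at sea two or three years and fight for matings.  Because the
two phenotypes mature at different total ages (modal total ages 4 versus 5–6,
counting the gravel year), the mix of male phenotypes on the spawning grounds
in any calendar year depends on the relative strengths of several distinct
cohorts.  The package quantifies three things for an exploited population
monitored by a weir: (1) the long-term trend in the fraction of each cohort
maturing as jacks, (2) which demographic and environmental covariates predict
that fraction, and (3) how coherent the population's three ocean-age classes
are within cohorts versus within calendar years ("cohort mismatch").

All abundances are organized by nine age classes (freshwater ages 1–3 x ocean
ages 1–3, ocean-major order); class `a` has total age `T_a = 1 + fw + ocean`.
Jacks are the three ocean-age-1 classes.  Numbers-at-age produced by brood
year `y` appear in return year `t = y + T_a` — the lagging that run
reconstruction inverts.

## Estimation models

### Trend model (biased random walk)

For reconstructed series (logit cohort jack proportion; log jack and nonjack
abundance) the drift model is

    J_y = J_{y-1} + u + w_y,   w_y ~ N(0, sigma_error),

with priors u ~ N(0, 10) and sigma_error ~ half-Cauchy(0, 2.5).  The
reconstructed series is treated as the state itself: the early decades of the
record carry no sampling-effort information, so process and observation error
are not separable there and no observation layer is fitted.

### Covariate model for cohort jack proportions

The logit jack proportion of brood year `y` is a latent AR(1) process with
covariate effects:

    J_y = mu_J + phi (J_{y-1} - mu_J) + b . c_y + w_y,  w_y ~ N(0, sigma_proc)

with five Z-scored covariates `c_y`: logit jack share among the males that
sired the cohort and log female spawners (both from the weir census of year
`y`), plus lagged two-year moving averages of NPGO (shifts +2, +3: the ocean
entry window), air temperature and log cladoceran zooplankton biomass
(shifts +1, +2: the lake rearing window).  The total return of brood year
`y` follows a Ricker spawner-recruit curve on observed spawner abundance
with lognormal error sigma_R; the return splits into jacks and nonjacks via
inverse-logit(J_y), spreads over each phenotype's age classes through
year-specific Dirichlet maturity schedules (independent Gamma(xi_a, 1)
intensities divided by their sums, with the nine shapes xi_a shared across
years), lags into return years by total age, and splits into catch and
escapement by year x age exploitation rates u_{t,a} ~ Beta(0.5, 0.5).

Observations by return year: total catch and escapement counts are lognormal
around the predicted totals with fixed SDs (0.5 and 0.1 — weir escapement
counts are near-census; estimating these SDs alongside the process SDs is not
identified and produces divergent transitions), and scale-sample age
compositions are multinomial with effective sample size min(actual, 1000).
Years with no scale samples from a source contribute no composition term;
years with zero recorded catch contribute no catch-abundance term.

Priors: mu_J ~ N(0, 20); phi ~ U(-0.999, 0.999); b ~ N(0, 10) per
coefficient; ln(alpha) ~ N(0, 20); beta ~ N(0, 0.1); sigma_proc, sigma_R ~
half-Cauchy(0, 2.5); xi_a ~ Gamma(0.001, 0.001).

### Ocean-age synchrony (multivariate random walks)

The 3-vector of log ocean-age abundances follows a random walk with
multivariate-normal increments whose covariance Q has a single variance
sigma_proc^2 on the diagonal and a single covariance gamma = sigma_proc^2 *
rho elsewhere; one model walks over brood years, the other over return
years, and both share the maturity/exploitation/observation machinery above
(freshwater-age compositions within each ocean age are the Dirichlet-via-
gamma construction).  Parameterizing the covariance through rho keeps every
draw positive definite; since 3x3 equicorrelation matrices require
rho > -1/2 (eigenvalues 1 - rho, 1 - rho, 1 + 2 rho), rho is uniform on
(-0.499, 0.999) rather than (-0.999, 0.999).

## Inference

Posteriors are sampled with an in-package Hamiltonian Monte Carlo sampler
using No-U-Turn trajectory termination (multinomial leaf sampling, dual-
averaging step-size adaptation targeting 0.8 acceptance, windowed diagonal
mass-matrix estimation, divergence threshold of 1000 on the Hamiltonian
error).  Each model supplies its log posterior and a hand-coded analytic
gradient over an unconstrained parameterization (log for scales and gamma
intensities, scaled logit for interval-bounded parameters, a linear rescaling
for the Ricker capacity parameter so its natural scale of ~1/spawners does
not produce an ill-conditioned mass matrix).  Gradient correctness is
property-tested against central finite differences at 1e-4 relative
tolerance, and every log posterior is tested to equal an independently coded
per-term density sum (scipy.stats, one scalar term at a time) to 1e-8.

Two sampler presets are shipped: `test` (4 chains x 2,000 iterations, half
warmup, no thinning) and `paper` (4 x 30,000, half warmup, keep every fifth
draw).  Recovery experiments in the test suite use shorter two-chain runs
(400–600 iterations); these sizes were chosen as the smallest runs whose
diagnostics stay clean on the study's problem sizes, and the calibration
results they produce are what the acceptance tests assert.

Numerical choices: the AR(1) state is initialized at its conditional
stationary distribution J_1 ~ N(mu_J + b.c_1, sigma_proc / sqrt(1 - phi^2));
return totals are sampled as log abundances (the Ricker lognormal written on
the log scale); multinomial likelihoods with rescaled non-integer counts use
the gamma-function normalization; return years not fully covered by the
modeled brood span are excluded from the likelihood rather than renormalized;
chains initialize at data-informed moment estimates (crude run reconstruction
from observed totals and compositions) with small jitter.

Diagnostics: split-chain R-hat (flag > 1.01), rank-normalized bulk ESS (flag
< 400), divergent-transition counts, and per-chain E-BFMI (flag < 0.3).
Summaries report medians with central 50% and 95% quantile intervals (the
interval type is a documented choice; highest-density intervals are not
used).

## Operating model (synthetic data)

`jackrun.simulate` generates complete datasets with exactly the generative
structure the estimation models assume, so parameter recovery, calibration
and the full pipeline can be exercised without any external data.  Default
truth values are anchored to the fitted estimates where those exist: sire-
jack effect 0.43 (the other four coefficients -0.12, 0.01, 0.05, -0.05),
sigma_R = 0.83, mean exploitation 0.13/0.52/0.60 by ocean age, observation
SDs 0.5/0.1, effective-sample-size cap 1,000.  Remaining defaults are
documented choices of realistic magnitude for a mid-sized sockeye system:
mu_J = -2.5 (about 8% of a cohort maturing as jacks), phi = 0.3, sigma_proc
= 0.3, ln(alpha) = 1.6, beta = 1.5e-6 (peak recruitment near 670k spawners),
Dirichlet maturity means centered on freshwater age 2 with concentration 50,
Beta-distributed exploitation with concentration 30, scale samples of
300 (catch) and 600 (escapement) fish per year.

Spawners in calendar year y are the simulation's own realized escapement
(both sexes); a burn-in of 10 brood years seeded at 200k spawners fills the
age structure before recording.  The two demographic covariates feed back
from the simulated weir counts (jacks are male by definition; males are
assumed to be half of the nonjack escapement).  They enter the AR(1) after
standardization by fixed anchor constants (mean -1.13, SD 0.85 for the sire
logit; 12.48, 0.65 for log females) calibrated once to the process's
stationary moments under the default configuration.  The anchor SDs also
bound the feedback loop gain (roughly b_sire/SD + phi), which must stay
below 1 for the jack dynamics to be stationary.  Environmental covariates
are independent standard normal series.

What the operating model does not emulate: individual maturation thresholds
or frequency-dependent mating success (the fitted models do not represent
them either), sex-stratified harvest, rare fourth-year age classes, stock-
mixing in the fishery, and any model misspecification — so passing recovery
tests demonstrates the estimation machinery is correct and calibrated under
the assumed structure, not that the structure is right for any particular
real population.

Because the estimation pipeline Z-scores its design matrix empirically (as
it must with field data) while the generator standardizes by the fixed
anchors, the effective true coefficient in a finite replicate differs from
the configured 0.43 by the ratio of realized to anchor covariate SD — an
O(1/sqrt(2n)) wobble that the recovery tolerances absorb.

## Validation and the cohort-mismatch report

`jackrun.validation` wires the generator to each estimation model:
100-replicate trend recovery (u = 0.03, sigma = 0.3, n = 41), 10-replicate
jack-model recovery on 25 brood years, and 10-replicate synchrony recovery
(n = 30 return years) at rho = -0.25 and +0.6.  Coverage of 95% intervals,
median bias and sign agreement are reported per parameter.  The posterior-
predictive check re-simulates the observation layer (same code path as the
likelihood's data model) from posterior draws and reports each observation's
predictive quantile; on self-simulated data the fraction inside the central
95% band should sit near or above 95% — above, because the year-specific
exploitation and maturity parameters let the model track each observation.

The cohort-mismatch report Z-scores the log abundance of each ocean age in
both frames and, for each return year, compares the jack source cohort
(return year minus 4) with the source cohorts of the older classes (minus 5
and minus 6); a year is flagged when the jack cohort's Z-score exceeds both
older ones by a configurable margin (default 1 SD).  This operationalizes
the mechanism by which a strong cohort's jacks spawn among older males from
weak earlier cohorts, inflating jack prevalence in the run.

## Known limitations

* The sampler is a straightforward NUTS implementation; it has no
  cross-chain adaptation, and very short warmups (under ~100 iterations)
  leave the mass matrix at its unit default.
* Centered parameterization of the latent states is used throughout; with
  far less informative data than the defaults generate (e.g. tiny scale
  samples), funnel geometry could require a non-centered variant that is not
  implemented.
* The jack model conditions on observed spawner counts in the Ricker curve
  (near-census weir data); a fully latent spawner closure is not implemented.
* Edge cohorts outside the fully covered return window contribute no
  likelihood terms; with short series this discards some information.
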