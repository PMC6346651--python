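# jackrun

Bayesian state-space analysis of alternative male life histories in an
exploited sockeye salmon population.

Male sockeye mature either as **jacks** — precocious sneaker males that
return after one year at sea — or as larger hooknose males after two or
three years.  Jacks are nearly worthless to the fishery, so a rise in their
prevalence is both an economic and an evolutionary puzzle.  This package
implements the statistical machinery for asking what regulates jack
prevalence in a weir-monitored population: age-structured run
reconstruction, trend estimation, a covariate-driven model of the fraction
of each cohort maturing as jacks embedded in a full population model, and a
synchrony analysis of the population's ocean-age classes that exposes
**cohort mismatches** — calendar years in which a strong cohort's jacks
spawn among older males from weak earlier cohorts.

## The models

With `J_y` the logit jack proportion of brood year `y`:

* **Trend**: `J_y = J_{y-1} + u + w_y`, `w_y ~ N(0, sigma_error)` — a biased
  random walk fitted to reconstructed cohort series.
* **Covariate model**: `J_y = mu_J + phi (J_{y-1} - mu_J) + b.c_y + w_y`,
  with five Z-scored covariates (logit jack share among the cohort's sires,
  log female spawners, lagged NPGO, air temperature, zooplankton biomass).
  Total returns follow a Ricker curve `ln B_y = ln S_y + ln(alpha) -
  beta S_y + w_y`; returns split into jacks/nonjacks via `J_y`, spread over
  age classes by year-specific Dirichlet maturity schedules, lag to return
  years by total age, and split into catch and escapement by year x age
  exploitation rates.  Observed totals are lognormal (fixed SDs 0.5 / 0.1);
  scale-sample age compositions are multinomial with effective sample sizes
  capped at 1,000.
* **Synchrony**: log abundances of ocean ages 1–3 as a multivariate random
  walk with equicorrelated increments (`Q` with variance `sigma_proc^2` on
  the diagonal and `gamma = sigma_proc^2 * rho` off it), fitted by brood
  year and by return year.

Posteriors are sampled with the package's own Hamiltonian Monte Carlo
(No-U-Turn) sampler over hand-coded analytic gradients; see
`docs/methods.md` for priors, numerical choices and the operating model
used to validate everything without external data.

## Worked example

The numbered scripts under `analysis/` run the study pipeline on a
simulated dataset (no downloads needed).  The first two steps:

```sh
$ python analysis/01_simulate_dataset.py
seed 42: 30 brood years (1979-2008)
cohort jack proportion: mean 0.102, range 0.035-0.209
spawners: median 547,761
wrote dataset to .../results/data

$ python analysis/02_trend_in_jack_proportions.py
logit_jack_proportion: drift u median -0.014/yr (95% CI -0.261 to +0.226)
log_jack_abundance: drift u median -0.012/yr (95% CI -0.466 to +0.440)
log_nonjack_abundance: drift u median -0.012/yr (95% CI -0.403 to +0.397)
```

The simulated population averages ~10% jacks per cohort, and — because the
operating model is stationary by construction — the fitted drift in logit
jack proportion is indistinguishable from zero (a real upward shift in jack
prevalence would surface here as a positive `u` with an interval excluding
zero).  The covariate model then recovers the generative effects: the
operating model's sire-jack coefficient is 0.43 and the four remaining
effects are small, and the fit finds exactly that pattern —

```sh
$ python analysis/03_jack_covariate_model.py
2 divergent transitions
sire_logit_jack_proportion   median +0.425 (95% CI +0.262 to +0.591)
log_female_spawners          median -0.062 (95% CI -0.228 to +0.093)
npgo_ma                      median -0.020 (95% CI -0.153 to +0.115)
temp_ma                      median -0.001 (95% CI -0.158 to +0.154)
zoop_ma                      median -0.063 (95% CI -0.212 to +0.094)
```

— i.e. a cohort's jack prevalence is driven by the jack share among the
males that sired it, with no consistent environmental signal.
`04_ocean_age_synchrony.py` contrasts `gamma` between frames and writes the
cohort-mismatch table, and `05_recovery_validation.py` re-estimates known
truths from fresh simulations.

The same functionality is exposed as a CLI:

```sh
jackrun simulate --out data/ --seed 42
jackrun fit jack --data data/ --out fit/ --chains 4 --iterations 2000
jackrun diagnose fit/
jackrun recover --model rw --reps 20
```

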