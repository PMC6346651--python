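"""Independent, term-by-term reference implementations of every model
density, built directly from scipy.stats.  These deliberately share no code
with the package's vectorized log posteriors."""

import math

import numpy as np
from scipy import stats
from scipy.special import gammaln

from jackrun.models.common import build_Q


def halfcauchy_lpdf(x, scale):
    return stats.halfcauchy(loc=0, scale=scale).logpdf(x)


def lognormal_lpdf(x, median, sigma):
    return stats.lognorm(s=sigma, scale=median).logpdf(x)


def multinomial_continuous_lpmf(counts, probs):
    """Multinomial kernel with gamma-function normalization (non-integer ok)."""
    counts = np.asarray(counts, dtype=float)
    n = counts.sum()
    keep = counts > 0
    return float(
        gammaln(n + 1.0) - gammaln(counts + 1.0).sum()
        + np.sum(counts[keep] * np.log(np.asarray(probs)[keep]))
    )


def observation_oracle(catch, esc, robs):
    """Observation log likelihood, one scalar term at a time."""
    total = 0.0
    for pred, obs_tot, zeta, has, sigma in (
        (catch, robs.obs_catch, robs.zeta_catch, robs.has_catch_scales,
         robs.spec.sigma_C),
        (esc, robs.obs_esc, robs.zeta_esc, robs.has_esc_scales,
         robs.spec.sigma_E),
    ):
        for t in range(len(robs.years)):
            pred_total = pred[t].sum()
            if np.isfinite(obs_tot[t]):
                total += lognormal_lpdf(obs_tot[t], pred_total, sigma)
            if has[t]:
                total += multinomial_continuous_lpmf(zeta[t], pred[t] / pred_total)
    return total


def rw_oracle(params, series):
    j = np.asarray(series, dtype=float)
    total = stats.norm(0, 10).logpdf(params.u)
    total += halfcauchy_lpdf(params.sigma_error, 2.5)
    for y in range(1, len(j)):
        total += stats.norm(j[y - 1] + params.u, params.sigma_error).logpdf(j[y])
    return float(total)


def jack_oracle(params, data):
    """Full log posterior of the jack model, summed term by term."""
    p = params
    d = data
    n = d.n_years
    c = d.covariates
    total = 0.0

    # scalar priors
    total += stats.norm(0, 20).logpdf(p.mu_J)
    total += stats.uniform(-0.999, 1.998).logpdf(p.phi)
    total += stats.norm(0, 10).logpdf(np.asarray(p.b)).sum()
    total += halfcauchy_lpdf(p.sigma_proc, 2.5)
    total += stats.norm(0, 20).logpdf(p.ricker.ln_alpha)
    total += stats.norm(0, 0.1).logpdf(p.ricker.beta)
    total += halfcauchy_lpdf(p.ricker.sigma_R, 2.5)
    total += stats.gamma(a=0.001, scale=1 / 0.001).logpdf(p.maturity.xi).sum()
    total += stats.beta(0.5, 0.5).logpdf(p.exploitation).sum()

    # AR(1) with stationary initialization
    j = p.states_J
    sd1 = p.sigma_proc / math.sqrt(1 - p.phi**2)
    total += stats.norm(p.mu_J + c[0] @ p.b, sd1).logpdf(j[0])
    for y in range(1, n):
        mean = p.mu_J + p.phi * (j[y - 1] - p.mu_J) + c[y] @ p.b
        total += stats.norm(mean, p.sigma_proc).logpdf(j[y])

    # Ricker recruitment on log returns
    for y in range(n):
        mean = (np.log(d.spawners[y]) + p.ricker.ln_alpha
                - p.ricker.beta * d.spawners[y])
        total += stats.norm(mean, p.ricker.sigma_R).logpdf(p.ln_returns[y])

    # gamma intensities behind the Dirichlet maturity schedules
    for y in range(n):
        for a in range(9):
            total += stats.gamma(a=p.maturity.xi[a], scale=1.0).logpdf(
                p.maturity.lam[y, a]
            )

    # deterministic mapping to predicted catch/escapement at age
    b_total = np.exp(p.ln_returns)
    share = 1 / (1 + np.exp(-j))
    bya = np.zeros((n, 9))
    bya[:, :3] = (b_total * share)[:, None] * p.maturity.p_jack
    bya[:, 3:] = (b_total * (1 - share))[:, None] * p.maturity.p_nonjack
    ta = d.ages.total_ages
    m = d.n_return_years
    catch = np.zeros((m, 9))
    esc = np.zeros((m, 9))
    for i, t in enumerate(d.robs.years):
        for a in range(9):
            cell = bya[t - ta[a] - d.brood_years[0], a]
            catch[i, a] = cell * p.exploitation[i, a]
            esc[i, a] = cell - catch[i, a]
    total += observation_oracle(catch, esc, d.robs)
    return float(total)


def mvrw_oracle(params, data):
    p = params
    d = data
    n = d.n_years
    total = 0.0

    total += halfcauchy_lpdf(p.sigma_proc, 2.5)
    total += stats.uniform(-0.499, 0.999 + 0.499).logpdf(p.rho)
    total += stats.gamma(a=0.001, scale=1 / 0.001).logpdf(p.xi).sum()
    total += stats.beta(0.5, 0.5).logpdf(p.exploitation).sum()
    total += stats.norm(0, 20).logpdf(p.states[0]).sum()

    q = build_Q(p.sigma_proc, p.rho)
    for y in range(1, n):
        total += stats.multivariate_normal(mean=np.zeros(3), cov=q).logpdf(
            p.states[y] - p.states[y - 1]
        )

    for y in range(n):
        for a in range(9):
            total += stats.gamma(a=p.xi[a], scale=1.0).logpdf(p.lam[y, a])

    comp = np.zeros((n, 9))
    for i in range(3):
        block = p.lam[:, 3 * i:3 * i + 3]
        comp[:, 3 * i:3 * i + 3] = block / block.sum(axis=1, keepdims=True)
    bya = np.exp(p.states)[:, [0, 0, 0, 1, 1, 1, 2, 2, 2]] * comp

    ta = d.ages.total_ages
    m = d.n_obs_years
    catch = np.zeros((m, 9))
    esc = np.zeros((m, 9))
    for i, t in enumerate(d.robs.years):
        for a in range(9):
            y = (t - ta[a] - d.state_years[0]) if d.frame == "brood" else (
                t - d.state_years[0])
            catch[i, a] = bya[y, a] * p.exploitation[i, a]
            esc[i, a] = bya[y, a] - catch[i, a]
    total += observation_oracle(catch, esc, d.robs)
    return float(total)
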