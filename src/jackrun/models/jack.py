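"""Covariate-driven jack-proportion model inside an age-structured
state-space population model.

Latent structure, by brood year y:

* logit jack proportion J_y follows an AR(1) process around mu_J with
  Z-scored covariate effects b.c_y and process SD sigma_proc;
* total return B_y follows a Ricker spawner-recruit curve on observed
  spawner abundance S_y with lognormal recruitment error sigma_R;
* B_y splits into jacks/nonjacks via J_y, and each phenotype spreads over
  its age classes through year-specific Dirichlet maturity schedules
  (independent gammas lambda_{y,a} with shared shape xi_a, divided by sums);
* numbers-at-age lag into return years by total age and split into catch
  and escapement by year x age exploitation rates u_{t,a} ~ Beta(0.5, 0.5).

Observations, by return year t: lognormal likelihoods on total catch and
escapement counts (fixed SDs), multinomial likelihoods on harvest and
escapement scale-sample age compositions with capped effective sample sizes.

Priors: mu_J ~ N(0, 20); phi ~ U(-0.999, 0.999); b ~ N(0, 10);
ln alpha ~ N(0, 20); beta ~ N(0, 0.1); sigma_proc, sigma_R ~ half-Cauchy(2.5);
xi_a ~ Gamma(0.001, 0.001).  The AR(1) state is initialized at its
conditional stationary distribution, J_1 ~ N(mu_J + b.c_1,
sigma_proc / sqrt(1 - phi^2)).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import digamma, expit, gammaln

from ..ages import AgeStructure, DEFAULT_AGES, ObservedCounts, ScaleSamples
from ..covariates import CovariateMatrix
from ..infer.transforms import Block, ParameterSpace
from .common import (
    LN_2PI,
    ObservationSpec,
    ReturnObsData,
    half_cauchy_grad,
    half_cauchy_lpdf,
    norm_lpdf,
    observation_terms_grad,
    prepare_return_obs,
)

__all__ = [
    "RickerParams",
    "MaturityParams",
    "JackModelParams",
    "JackModelData",
    "JackModel",
    "prepare_jack_data",
    "jack_model_log_posterior",
    "jack_model_log_posterior_terms",
]

PHI_BOUND = 0.999
MU_PRIOR_SD = 20.0
B_PRIOR_SD = 10.0
LNALPHA_PRIOR_SD = 20.0
BETA_PRIOR_SD = 0.1
SIGMA_PRIOR_SCALE = 2.5
XI_PRIOR_SHAPE = 0.001
XI_PRIOR_RATE = 0.001
U_BETA_A = 0.5
U_BETA_B = 0.5


@dataclass
class RickerParams:
    ln_alpha: float
    beta: float
    sigma_R: float

    def __post_init__(self) -> None:
        if self.sigma_R <= 0:
            raise ValueError("sigma_R must be positive")


@dataclass
class MaturityParams:
    """Year-specific gamma intensities and shared shapes for both phenotypes.

    ``lam`` is (n_years, 9): columns 1-3 are the jack (ocean age-1) Dirichlet,
    columns 4-9 the nonjack one.  ``xi`` holds the nine shared shapes.
    """

    lam: np.ndarray
    xi: np.ndarray

    def __post_init__(self) -> None:
        self.lam = np.asarray(self.lam, dtype=float)
        self.xi = np.asarray(self.xi, dtype=float)
        if np.any(self.lam <= 0) or np.any(self.xi <= 0):
            raise ValueError("gamma intensities and shapes must be positive")

    @property
    def p_jack(self) -> np.ndarray:
        lamj = self.lam[:, :3]
        return lamj / lamj.sum(axis=1, keepdims=True)

    @property
    def p_nonjack(self) -> np.ndarray:
        lamh = self.lam[:, 3:]
        return lamh / lamh.sum(axis=1, keepdims=True)


@dataclass
class JackModelParams:
    """All latent states and parameters of the jack-proportion model."""

    mu_J: float
    phi: float
    b: np.ndarray
    sigma_proc: float
    states_J: np.ndarray  # logit jack proportion per brood year
    ricker: RickerParams
    ln_returns: np.ndarray  # log total return per brood year
    maturity: MaturityParams
    exploitation: np.ndarray  # (n_return_years, 9) in (0, 1)

    def __post_init__(self) -> None:
        if not abs(self.phi) < PHI_BOUND:
            raise ValueError("|phi| must be < 0.999")
        if self.sigma_proc <= 0:
            raise ValueError("sigma_proc must be positive")
        self.exploitation = np.asarray(self.exploitation, dtype=float)
        if np.any(self.exploitation <= 0) or np.any(self.exploitation >= 1):
            raise ValueError("exploitation rates must lie strictly inside (0, 1)")


@dataclass
class JackModelData:
    """Inputs aligned for fitting: covariates, spawners, observations."""

    brood_years: np.ndarray
    covariates: np.ndarray  # (n, 5)
    spawners: np.ndarray  # (n,) observed escapement in each brood year
    robs: ReturnObsData
    ages: AgeStructure = field(default_factory=lambda: DEFAULT_AGES)

    def __post_init__(self) -> None:
        self.brood_years = np.asarray(self.brood_years, dtype=int)
        if len(self.brood_years) < 5:
            raise ValueError("need at least 5 brood years")
        if np.any(self.spawners <= 0):
            raise ValueError("spawner abundance must be positive in every year")
        ta = self.ages.total_ages
        # return row i, age a sources from brood index idx[i, a]; for fixed a
        # the source indices are consecutive, so idx[:, a] = offsets[a] + i
        self.idx = (self.robs.years[:, None] - ta[None, :]
                    - self.brood_years[0]).astype(int)
        if self.idx.min() < 0 or self.idx.max() >= len(self.brood_years):
            raise ValueError(
                "return-year window not fully covered by the modeled brood years"
            )
        self.offsets = self.idx[0]

    @property
    def n_years(self) -> int:
        return len(self.brood_years)

    @property
    def n_return_years(self) -> int:
        return self.robs.n_years


def prepare_jack_data(
    obs: ObservedCounts,
    scales_catch: ScaleSamples | None,
    scales_esc: ScaleSamples | None,
    covs: CovariateMatrix,
    spec: ObservationSpec | None = None,
    ages: AgeStructure = DEFAULT_AGES,
) -> JackModelData:
    """Assemble fitting inputs for a modeled brood-year span.

    The modeled brood years are the covariate matrix rows; spawners are the
    observed escapement totals of those calendar years, and return-year
    likelihoods run over the window fully covered by the modeled cohorts
    (first brood + oldest total age through last brood + youngest total age).
    """
    spec = spec or ObservationSpec()
    years = covs.brood_years
    ta = ages.total_ages
    window = np.arange(years[0] + ta.max(), years[-1] + ta.min() + 1)
    tab = obs.table.set_index("return_year")
    spawners = np.empty(len(years))
    for i, y in enumerate(years):
        if y not in tab.index:
            raise ValueError(f"no observed escapement for brood year {y}")
        spawners[i] = tab.loc[y, "escapement_total"]
    robs = prepare_return_obs(window, obs, scales_catch, scales_esc, spec)
    return JackModelData(
        brood_years=years, covariates=covs.values, spawners=spawners,
        robs=robs, ages=ages,
    )


def _deterministic_chain(params: JackModelParams, data: JackModelData):
    """Latent states -> predicted catch/escapement numbers-at-age."""
    s = expit(params.states_J)
    b_total = np.exp(params.ln_returns)
    pj = params.maturity.p_jack
    ph = params.maturity.p_nonjack
    bya = np.concatenate(
        [(b_total * s)[:, None] * pj, (b_total * (1 - s))[:, None] * ph], axis=1
    )
    cols = np.arange(9)
    r = bya[data.idx, cols]  # (n_t, 9)
    catch = r * params.exploitation
    esc = r - catch
    return bya, r, catch, esc


class JackModel:
    """Log posterior with analytic gradient, over the unconstrained vector."""

    def __init__(self, data: JackModelData):
        self.data = data
        n, m = data.n_years, data.n_return_years
        self.s_scale = float(np.mean(data.spawners))
        self.space = ParameterSpace([
            Block("mu_J", ()),
            Block("phi", (), "interval", -PHI_BOUND, PHI_BOUND),
            Block("b", (5,)),
            Block("sigma_proc", (), "log"),
            Block("states_J", (n,)),
            Block("ln_alpha", ()),
            Block("beta", (), "scale", scale=1.0 / self.s_scale),
            Block("sigma_R", (), "log"),
            Block("ln_returns", (n,)),
            Block("lam", (n, 9), "log"),
            Block("xi", (9,), "log"),
            Block("exploitation", (m, 9), "interval", 0.0, 1.0),
        ])

    # -- initial values ----------------------------------------------------

    def initial_params(self) -> dict:
        d = self.data
        robs = d.robs
        n, m = d.n_years, d.n_return_years

        def comp(zeta, has):
            th = np.full((m, 9), 1.0 / 9)
            fallback = None
            if np.any(has):
                avg = zeta[has].sum(axis=0) + 0.5
                fallback = avg / avg.sum()
            for i in range(m):
                if has[i]:
                    w = zeta[i] + 0.5
                    th[i] = w / w.sum()
                elif fallback is not None:
                    th[i] = fallback
            return th

        th_c = comp(robs.zeta_catch, robs.has_catch_scales)
        th_e = comp(robs.zeta_esc, robs.has_esc_scales)
        nc = np.where(np.isfinite(robs.obs_catch), robs.obs_catch, 0.0)
        ne = np.where(np.isfinite(robs.obs_esc), robs.obs_esc,
                      np.nanmean(robs.obs_esc) if np.any(np.isfinite(robs.obs_esc))
                      else 1000.0)
        r_c = nc[:, None] * th_c
        r_e = ne[:, None] * th_e
        r_hat = r_c + r_e + 1e-6
        u0 = np.clip(r_c / r_hat, 0.03, 0.95)

        b_hat = np.full((n, 9), np.nan)
        cols = np.arange(9)
        b_hat[d.idx, cols] = r_hat
        col_med = np.nanmedian(b_hat, axis=0)
        col_med = np.where(np.isfinite(col_med) & (col_med > 0), col_med, 1.0)
        for a in range(9):
            miss = ~np.isfinite(b_hat[:, a])
            b_hat[miss, a] = col_med[a]
        b_hat = np.maximum(b_hat, 1e-3)

        jack = b_hat[:, d.ages.jack_set].sum(axis=1)
        total = b_hat.sum(axis=1)
        j0 = np.log(np.clip(jack / total, 1e-3, 0.6)) - np.log(
            1 - np.clip(jack / total, 1e-3, 0.6))
        ln_b0 = np.log(total)

        pj = b_hat[:, :3] / b_hat[:, :3].sum(axis=1, keepdims=True)
        ph = b_hat[:, 3:] / b_hat[:, 3:].sum(axis=1, keepdims=True)
        lam0 = np.concatenate([20 * pj, 20 * ph], axis=1)
        xi0 = np.clip(
            np.concatenate([20 * pj.mean(axis=0), 20 * ph.mean(axis=0)]), 0.2, 50.0
        )

        y = ln_b0 - np.log(d.spawners)
        design = np.column_stack([np.ones(n), -d.spawners])
        coef, *_ = np.linalg.lstsq(design, y, rcond=None)
        ln_alpha0 = float(np.clip(coef[0], -3.0, 5.0))
        beta0 = float(np.clip(coef[1], -1.0 / self.s_scale, 10.0 / self.s_scale))
        resid = y - design @ coef
        sig_r0 = max(float(resid.std(ddof=1)), 0.2)

        return {
            "mu_J": float(j0.mean()),
            "phi": 0.2,
            "b": np.zeros(5),
            "sigma_proc": max(float(np.diff(j0).std(ddof=1)) * 0.8, 0.1),
            "states_J": j0,
            "ln_alpha": ln_alpha0,
            "beta": beta0,
            "sigma_R": sig_r0,
            "ln_returns": ln_b0,
            "lam": lam0,
            "xi": xi0,
            "exploitation": u0,
        }

    # -- log posterior -----------------------------------------------------

    def _terms_and_grads(self, x: dict):
        d = self.data
        n = d.n_years
        c_mat = d.covariates
        mu, phi, b = x["mu_J"], x["phi"], x["b"]
        sigp, sigr = x["sigma_proc"], x["sigma_R"]
        j, ln_b = x["states_J"], x["ln_returns"]
        lna, beta = x["ln_alpha"], x["beta"]
        lam, xi, u = x["lam"], x["xi"], x["exploitation"]

        g = {k: np.zeros_like(np.asarray(v, dtype=float)) for k, v in x.items()}
        gs = {k: 0.0 for k in ("mu_J", "phi", "sigma_proc", "ln_alpha",
                               "beta", "sigma_R")}

        # deterministic chain
        s = expit(j)
        b_total = np.exp(ln_b)
        lamj, lamh = lam[:, :3], lam[:, 3:]
        tj = lamj.sum(axis=1)
        th = lamh.sum(axis=1)
        pj = lamj / tj[:, None]
        ph = lamh / th[:, None]
        bj = b_total * s
        bh = b_total * (1 - s)
        bya = np.concatenate([bj[:, None] * pj, bh[:, None] * ph], axis=1)
        m = d.n_return_years
        off = d.offsets
        r = np.empty((m, 9))
        for a in range(9):
            r[:, a] = bya[off[a]:off[a] + m, a]
        catch = r * u
        esc = r - catch

        lp_ab, lp_comp, gc, ge = observation_terms_grad(catch, esc, d.robs)

        # chain observation gradients back through the mapping
        gr = gc * u + ge * (1 - u)
        g["exploitation"] = (gc - ge) * r
        gbya = np.zeros((n, 9))
        for a in range(9):
            gbya[off[a]:off[a] + m, a] = gr[:, a]
        gbj = (gbya[:, :3] * pj).sum(axis=1)
        gbh = (gbya[:, 3:] * ph).sum(axis=1)
        gpj = gbya[:, :3] * bj[:, None]
        gph = gbya[:, 3:] * bh[:, None]
        glamj = (gpj - (gpj * pj).sum(axis=1, keepdims=True)) / tj[:, None]
        glamh = (gph - (gph * ph).sum(axis=1, keepdims=True)) / th[:, None]
        g["lam"] = np.concatenate([glamj, glamh], axis=1)
        g["ln_returns"] = b_total * (gbj * s + gbh * (1 - s))
        g["states_J"] = b_total * s * (1 - s) * (gbj - gbh)

        # AR(1) process with stationary initialization
        c_eff = c_mat @ b
        sd1 = sigp / math.sqrt(1 - phi**2)
        r1 = j[0] - mu - c_eff[0]
        rr = j[1:] - mu - phi * (j[:-1] - mu) - c_eff[1:]
        lp_ar = float(norm_lpdf(r1, 0, sd1) + np.sum(norm_lpdf(rr, 0, sigp)))
        g["states_J"][0] += -r1 / sd1**2
        g["states_J"][1:] += -rr / sigp**2
        g["states_J"][:-1] += phi * rr / sigp**2
        gs["mu_J"] += r1 / sd1**2 + float(np.sum(rr)) * (1 - phi) / sigp**2
        gs["phi"] += (-phi / (1 - phi**2) + r1**2 * phi / sigp**2
                      + float(np.sum(rr * (j[:-1] - mu))) / sigp**2)
        g["b"] += r1 / sd1**2 * c_mat[0] + c_mat[1:].T @ rr / sigp**2
        gs["sigma_proc"] += (-1 / sigp + r1**2 * (1 - phi**2) / sigp**3
                             + float(np.sum(-1 / sigp + rr**2 / sigp**3)))

        # Ricker recruitment
        q = ln_b - (np.log(d.spawners) + lna - beta * d.spawners)
        lp_ricker = float(np.sum(norm_lpdf(q, 0, sigr)))
        g["ln_returns"] += -q / sigr**2
        gs["ln_alpha"] += float(np.sum(q)) / sigr**2
        gs["beta"] += -float(np.sum(q * d.spawners)) / sigr**2
        gs["sigma_R"] += float(np.sum(-1 / sigr + q**2 / sigr**3))

        # Dirichlet-via-gamma maturity schedules
        log_lam = np.log(lam)
        lp_mat = float(np.sum((xi - 1) * log_lam - lam) - n * np.sum(gammaln(xi)))
        g["lam"] += (xi - 1) / lam - 1.0
        g["xi"] = log_lam.sum(axis=0) - n * digamma(xi)

        # priors
        lp_prior = float(
            norm_lpdf(mu, 0, MU_PRIOR_SD)
            + np.sum(norm_lpdf(b, 0, B_PRIOR_SD))
            + norm_lpdf(lna, 0, LNALPHA_PRIOR_SD)
            + norm_lpdf(beta, 0, BETA_PRIOR_SD)
            + half_cauchy_lpdf(sigp, SIGMA_PRIOR_SCALE)
            + half_cauchy_lpdf(sigr, SIGMA_PRIOR_SCALE)
            - math.log(2 * PHI_BOUND)  # uniform phi
            + np.sum((U_BETA_A - 1) * np.log(u) + (U_BETA_B - 1) * np.log1p(-u)
                     - (gammaln(U_BETA_A) + gammaln(U_BETA_B)
                        - gammaln(U_BETA_A + U_BETA_B)))
            + np.sum((XI_PRIOR_SHAPE - 1) * np.log(xi) - XI_PRIOR_RATE * xi
                     + XI_PRIOR_SHAPE * math.log(XI_PRIOR_RATE)
                     - gammaln(XI_PRIOR_SHAPE))
        )
        gs["mu_J"] += -mu / MU_PRIOR_SD**2
        g["b"] += -b / B_PRIOR_SD**2
        gs["ln_alpha"] += -lna / LNALPHA_PRIOR_SD**2
        gs["beta"] += -beta / BETA_PRIOR_SD**2
        gs["sigma_proc"] += half_cauchy_grad(sigp, SIGMA_PRIOR_SCALE)
        gs["sigma_R"] += half_cauchy_grad(sigr, SIGMA_PRIOR_SCALE)
        g["exploitation"] += (U_BETA_A - 1) / u - (U_BETA_B - 1) / (1 - u)
        g["xi"] += (XI_PRIOR_SHAPE - 1) / xi - XI_PRIOR_RATE

        for k, v in gs.items():
            g[k] = g[k] + v

        terms = {
            "ar1": lp_ar,
            "ricker": lp_ricker,
            "maturity": lp_mat,
            "priors": lp_prior,
            "obs_abundance": lp_ab,
            "obs_composition": lp_comp,
        }
        return terms, g

    def logp_grad(self, z: np.ndarray):
        x = self.space.unpack(z)
        try:
            terms, g = self._terms_and_grads(x)
        except (ValueError, FloatingPointError):
            return -np.inf, np.zeros(self.space.dim)
        lp = sum(terms.values()) + self.space.log_jacobian(z)
        if not np.isfinite(lp):
            return -np.inf, np.zeros(self.space.dim)
        return lp, self.space.chain_grad(z, g)

    # -- typed surface -----------------------------------------------------

    def params_to_dict(self, params: JackModelParams) -> dict:
        return {
            "mu_J": params.mu_J,
            "phi": params.phi,
            "b": np.asarray(params.b, dtype=float),
            "sigma_proc": params.sigma_proc,
            "states_J": np.asarray(params.states_J, dtype=float),
            "ln_alpha": params.ricker.ln_alpha,
            "beta": params.ricker.beta,
            "sigma_R": params.ricker.sigma_R,
            "ln_returns": np.asarray(params.ln_returns, dtype=float),
            "lam": params.maturity.lam,
            "xi": params.maturity.xi,
            "exploitation": params.exploitation,
        }

    def log_posterior_terms(self, params: JackModelParams) -> dict[str, float]:
        terms, _ = self._terms_and_grads(self.params_to_dict(params))
        return terms

    def predicted_tables(self, params: JackModelParams):
        """Predicted catch and escapement numbers-at-age over the window."""
        _, _, catch, esc = _deterministic_chain(params, self.data)
        return catch, esc

    def predicted_tables_dict(self, x: dict):
        """As :meth:`predicted_tables` but from a plain draw dict."""
        d = self.data
        s = expit(np.asarray(x["states_J"], dtype=float))
        b_total = np.exp(np.asarray(x["ln_returns"], dtype=float))
        lam = np.asarray(x["lam"], dtype=float)
        pj = lam[:, :3] / lam[:, :3].sum(axis=1, keepdims=True)
        ph = lam[:, 3:] / lam[:, 3:].sum(axis=1, keepdims=True)
        bya = np.concatenate(
            [(b_total * s)[:, None] * pj, (b_total * (1 - s))[:, None] * ph],
            axis=1,
        )
        r = bya[d.idx, np.arange(9)]
        catch = r * np.asarray(x["exploitation"], dtype=float)
        return catch, r - catch


def jack_model_log_posterior_terms(
    params: JackModelParams, data: JackModelData
) -> dict[str, float]:
    return JackModel(data).log_posterior_terms(params)


def jack_model_log_posterior(params: JackModelParams, data: JackModelData) -> float:
    """Log posterior density (constrained parameterization, no Jacobians)."""
    return sum(jack_model_log_posterior_terms(params, data).values())
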