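"""Shared density terms and deterministic primitives for the state-space models.

All three estimation models share the same return-year observation layer:
lognormal likelihoods on total catch and escapement counts (with fixed
observation SDs, since process and observation variance cannot both be
estimated here) and multinomial likelihoods on scale-sample age compositions
with effective sample sizes capped at 1,000.  The deterministic chain from
latent cohort abundance to predicted catch/escapement-at-age (logit split,
Dirichlet-via-gamma maturity schedules, brood-to-return lagging, exploitation
split) also lives here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln

__all__ = [
    "ObservationSpec",
    "ReturnObsData",
    "effective_sample_size",
    "inverse_logit_split",
    "ricker_log_mean",
    "dirichlet_from_gamma",
    "build_Q",
    "prepare_return_obs",
    "observation_log_likelihood",
    "observation_terms_grad",
    "norm_lpdf",
    "half_cauchy_lpdf",
    "half_cauchy_grad",
]

LN_2PI = math.log(2.0 * math.pi)


@dataclass(frozen=True)
class ObservationSpec:
    """Fixed observation-error settings for the return-year likelihoods."""

    sigma_C: float = 0.5
    sigma_E: float = 0.1
    ess_cap: int = 1000

    def __post_init__(self) -> None:
        if self.sigma_C <= 0 or self.sigma_E <= 0:
            raise ValueError("observation SDs must be positive")
        if self.ess_cap < 1:
            raise ValueError("effective-sample-size cap must be >= 1")


def effective_sample_size(n_actual: int, spec: ObservationSpec) -> int:
    """Multinomial effective sample size: the actual size, capped."""
    if n_actual < 0:
        raise ValueError("sample size must be non-negative")
    return int(min(n_actual, spec.ess_cap))


def inverse_logit_split(b_total, j_logit):
    """Split a total abundance into (jack, nonjack) by a logit proportion.

    The two parts sum to the total exactly.
    """
    b_total = np.asarray(b_total, dtype=float)
    if np.any(b_total < 0):
        raise ValueError("total abundance must be non-negative")
    s = 1.0 / (1.0 + np.exp(-np.asarray(j_logit, dtype=float)))
    b_jack = b_total * s
    return b_jack, b_total - b_jack


def ricker_log_mean(spawners, ln_alpha: float, beta: float):
    """Expected log return under the Ricker spawner-recruit curve.

    ``ln B = ln S + ln(alpha) - beta * S``; ``alpha`` is productivity at low
    density and ``1/beta`` the spawner abundance of maximum recruitment.
    """
    spawners = np.asarray(spawners, dtype=float)
    if np.any(spawners <= 0):
        raise ValueError("spawner abundance must be positive")
    return np.log(spawners) + ln_alpha - beta * spawners


def dirichlet_from_gamma(lam):
    """Compositions as independent gammas divided by their sum."""
    lam = np.asarray(lam, dtype=float)
    if np.any(lam <= 0):
        raise ValueError("gamma intensities must be positive")
    return lam / lam.sum(axis=-1, keepdims=True)


def build_Q(sigma_proc: float, rho: float) -> np.ndarray:
    """3x3 equicorrelation process covariance: variance on the diagonal,
    gamma = sigma^2 * rho everywhere else.

    Positive definite only for rho in (-1/2, 1): the eigenvalues are
    sigma^2(1 - rho) (twice) and sigma^2(1 + 2 rho).
    """
    if sigma_proc <= 0:
        raise ValueError("sigma_proc must be positive")
    if not (-0.5 < rho < 1.0):
        raise ValueError(
            f"rho={rho} gives a non-positive-definite 3x3 equicorrelation matrix"
        )
    gamma = sigma_proc**2 * rho
    return sigma_proc**2 * np.eye(3) + gamma * (1.0 - np.eye(3))


# ---------------------------------------------------------------------------
# Scalar density helpers (kept explicit so gradients stay hand-checkable)
# ---------------------------------------------------------------------------


def norm_lpdf(x, mu, sd):
    x = np.asarray(x, dtype=float)
    return -0.5 * LN_2PI - np.log(sd) - 0.5 * ((x - mu) / sd) ** 2


def half_cauchy_lpdf(x, scale):
    """log density of a half-Cauchy(0, scale) at x > 0."""
    return math.log(2.0 / (math.pi * scale)) - np.log1p((x / scale) ** 2)


def half_cauchy_grad(x, scale):
    return -2.0 * x / (scale**2 + x**2)


# ---------------------------------------------------------------------------
# Return-year observation layer
# ---------------------------------------------------------------------------


@dataclass
class ReturnObsData:
    """Observed return-year data aligned to the modeled window.

    ``obs_catch`` / ``obs_esc`` are the total counts (NaN where a year has no
    usable abundance observation, e.g. zero recorded catch).  ``zeta_*`` are
    the scale-sample age counts rescaled to the effective sample size, with
    zero rows for years outside the source's sampled set ``V^s`` (masked by
    ``has_*``).
    """

    years: np.ndarray
    obs_catch: np.ndarray
    obs_esc: np.ndarray
    zeta_catch: np.ndarray  # (n_t, 9)
    zeta_esc: np.ndarray
    has_catch_scales: np.ndarray  # bool (n_t,)
    has_esc_scales: np.ndarray
    spec: ObservationSpec = field(default_factory=ObservationSpec)

    def __post_init__(self) -> None:
        # cache the parameter-free pieces of the likelihood
        self._cache = {}
        for src, obs, zeta, has, sigma in (
            ("catch", self.obs_catch, self.zeta_catch, self.has_catch_scales,
             self.spec.sigma_C),
            ("esc", self.obs_esc, self.zeta_esc, self.has_esc_scales,
             self.spec.sigma_E),
        ):
            m = np.isfinite(obs)
            log_obs = np.where(m, np.log(np.where(m, obs, 1.0)), 0.0)
            const_ab = float(
                np.sum(-log_obs[m] - math.log(sigma) - 0.5 * LN_2PI)
            )
            eps = zeta.sum(axis=1)
            const_comp = float(
                np.sum(gammaln(eps[has] + 1.0)) - np.sum(gammaln(zeta[has] + 1.0))
            )
            self._cache[src] = (m, log_obs, const_ab, eps, const_comp)

    @property
    def n_years(self) -> int:
        return len(self.years)


def prepare_return_obs(years, obs, scales_catch, scales_esc, spec) -> ReturnObsData:
    """Align observed totals and rescaled scale samples to a year window."""
    years = np.asarray(years, dtype=int)
    tab = obs.table.set_index("return_year")
    n_t = len(years)
    oc = np.full(n_t, np.nan)
    oe = np.full(n_t, np.nan)
    for i, t in enumerate(years):
        if t in tab.index:
            c, e = tab.loc[t, "catch_total"], tab.loc[t, "escapement_total"]
            oc[i] = c if c > 0 else np.nan  # zero recorded catch: no lognormal term
            oe[i] = e if e > 0 else np.nan

    def _zeta(scales):
        z = np.zeros((n_t, 9))
        has = np.zeros(n_t, dtype=bool)
        if scales is None:
            return z, has
        for j, t in enumerate(scales.years):
            i = np.searchsorted(years, t)
            if i < n_t and years[i] == t and scales.n_sample[j] > 0:
                eps = effective_sample_size(int(scales.n_sample[j]), spec)
                z[i] = eps * scales.counts[j] / scales.counts[j].sum()
                has[i] = True
        return z, has

    zc, hc = _zeta(scales_catch)
    ze, he = _zeta(scales_esc)
    return ReturnObsData(
        years=years, obs_catch=oc, obs_esc=oe,
        zeta_catch=zc, zeta_esc=ze,
        has_catch_scales=hc, has_esc_scales=he, spec=spec,
    )


def observation_terms_grad(pred_catch, pred_esc, data: ReturnObsData):
    """Observation log likelihood and gradients w.r.t. predicted cells.

    Returns ``(logp_abundance, logp_composition, d/dCatch, d/dEsc)``; the two
    log-likelihood components are separated for term-wise checking.
    """
    lc_a, lc_c, gc = _source_terms(pred_catch, data.zeta_catch,
                                   data.has_catch_scales, data.spec.sigma_C,
                                   data._cache["catch"])
    le_a, le_c, ge = _source_terms(pred_esc, data.zeta_esc,
                                   data.has_esc_scales, data.spec.sigma_E,
                                   data._cache["esc"])
    return lc_a + le_a, lc_c + le_c, gc, ge


def _source_terms(pred, zeta, has_scales, sigma, cache):
    """Lognormal-total and multinomial-composition terms for one source."""
    m, log_obs, const_ab, eps, const_comp = cache
    total = pred.sum(axis=1)
    grad = np.zeros_like(pred)
    lp_ab = 0.0
    lp_comp = 0.0

    if m.any():
        tm = total[m]
        if np.any(tm <= 0):
            raise ValueError("zero predicted total in an observed year")
        resid = log_obs[m] - np.log(tm)
        lp_ab = const_ab - 0.5 * float(resid @ resid) / sigma**2
        coef = np.zeros(len(total))
        coef[m] = resid / sigma**2 / tm
        grad += coef[:, None]

    s = has_scales
    if s.any():
        ts = total[s]
        ps = pred[s]
        zs = zeta[s]
        if np.any(ts <= 0):
            raise ValueError("zero predicted total in a scale-sampled year")
        zpos = zs > 0
        if np.any(ps[zpos] <= 0):
            raise ValueError("zero predicted share for an observed age class")
        log_theta = np.log(np.where(zpos, ps, 1.0)) - np.log(ts)[:, None]
        lp_comp = const_comp + float(np.sum(zs * np.where(zpos, log_theta, 0.0)))
        g = np.zeros_like(ps)
        np.divide(zs, ps, out=g, where=zpos)
        g -= (eps[s] / ts)[:, None]
        grad[s] += g
    return lp_ab, lp_comp, grad


def observation_log_likelihood(pred_catch, pred_esc, data: ReturnObsData) -> float:
    """Total observation log likelihood (lognormal totals + multinomial ages)."""
    a, c, _, _ = observation_terms_grad(
        np.asarray(pred_catch, float), np.asarray(pred_esc, float), data
    )
    return a + c
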