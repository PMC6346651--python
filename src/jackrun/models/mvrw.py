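"""Multivariate random walks on ocean-age log abundances.

Two variants of one model quantify the coherence of the population's three
marine age classes: one walks over brood years (cohort frame), the other over
return years (calendar frame).  The 3-vector of log abundances follows a
random walk with multivariate-normal increments whose covariance has a single
variance sigma_proc^2 on the diagonal and a single covariance
gamma = sigma_proc^2 * rho off the diagonal, so the synchrony of the age
classes is carried by one correlation parameter.  rho is restricted to
(-0.499, 0.999): a 3x3 equicorrelation matrix is positive definite only for
rho > -1/2 (eigenvalues 1 - rho, 1 - rho, 1 + 2 rho).

Each ocean age spreads over its three freshwater ages through year-specific
Dirichlet compositions (independent gammas with shared shapes, as in the
jack model); numbers-at-age are lagged to return years in the brood frame
(identity in the return frame) and split into catch and escapement by
year x age exploitation rates.  The observation layer is shared with the
jack model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import digamma, gammaln

from ..ages import AgeStructure, DEFAULT_AGES, ObservedCounts, ScaleSamples
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
from .jack import (
    SIGMA_PRIOR_SCALE,
    U_BETA_A,
    U_BETA_B,
    XI_PRIOR_RATE,
    XI_PRIOR_SHAPE,
)

__all__ = [
    "MVRWParams",
    "MVRWData",
    "MVRWModel",
    "prepare_mvrw_data",
    "mvrw_log_posterior",
    "mvrw_log_posterior_terms",
]

RHO_LO = -0.499
RHO_HI = 0.999
X1_PRIOR_SD = 20.0


@dataclass
class MVRWParams:
    """States and parameters of one frame's multivariate random walk."""

    states: np.ndarray  # (n_years, 3) log abundance by ocean age
    sigma_proc: float
    rho: float
    lam: np.ndarray  # (n_years, 9) freshwater-composition gamma intensities
    xi: np.ndarray  # (9,)
    exploitation: np.ndarray  # (n_obs_years, 9) in (0, 1)

    def __post_init__(self) -> None:
        if self.sigma_proc <= 0:
            raise ValueError("sigma_proc must be positive")
        if not RHO_LO <= self.rho <= RHO_HI:
            raise ValueError("rho outside the positive-definite range")
        self.lam = np.asarray(self.lam, dtype=float)
        self.xi = np.asarray(self.xi, dtype=float)
        self.states = np.asarray(self.states, dtype=float)
        self.exploitation = np.asarray(self.exploitation, dtype=float)
        if np.any(self.exploitation <= 0) or np.any(self.exploitation >= 1):
            raise ValueError("exploitation rates must lie strictly inside (0, 1)")

    @property
    def gamma(self) -> float:
        """Off-diagonal process covariance, sigma_proc^2 * rho."""
        return self.sigma_proc**2 * self.rho

    @property
    def Q(self) -> np.ndarray:
        from .common import build_Q

        return build_Q(self.sigma_proc, self.rho)


@dataclass
class MVRWData:
    """State years, frame, and aligned observations."""

    frame: str  # "brood" | "return"
    state_years: np.ndarray
    robs: ReturnObsData
    ages: AgeStructure = field(default_factory=lambda: DEFAULT_AGES)

    def __post_init__(self) -> None:
        if self.frame not in ("brood", "return"):
            raise ValueError("frame must be 'brood' or 'return'")
        self.state_years = np.asarray(self.state_years, dtype=int)
        if len(self.state_years) < 3:
            raise ValueError("need at least 3 state years")
        if self.frame == "brood":
            ta = self.ages.total_ages
            self.idx = (self.robs.years[:, None] - ta[None, :]
                        - self.state_years[0]).astype(int)
        else:
            self.idx = (self.robs.years[:, None] - self.state_years[0]
                        + np.zeros((1, 9), dtype=int))
        if self.idx.min() < 0 or self.idx.max() >= len(self.state_years):
            raise ValueError("observation window not covered by the state years")
        self.offsets = self.idx[0]  # per-age source indices are consecutive

    @property
    def n_years(self) -> int:
        return len(self.state_years)

    @property
    def n_obs_years(self) -> int:
        return self.robs.n_years


def prepare_mvrw_data(
    obs: ObservedCounts,
    scales_catch: ScaleSamples | None,
    scales_esc: ScaleSamples | None,
    years,
    frame: str,
    spec: ObservationSpec | None = None,
    ages: AgeStructure = DEFAULT_AGES,
) -> MVRWData:
    """Align observations to a state-year span in the chosen frame.

    In the return frame the states are the observation years themselves; in
    the brood frame the observation window is the span of return years fully
    covered by the state (brood) years.
    """
    spec = spec or ObservationSpec()
    years = np.asarray(years, dtype=int)
    if frame == "brood":
        ta = ages.total_ages
        window = np.arange(years[0] + ta.max(), years[-1] + ta.min() + 1)
    else:
        window = years
    robs = prepare_return_obs(window, obs, scales_catch, scales_esc, spec)
    return MVRWData(frame=frame, state_years=years, robs=robs, ages=ages)


OCEAN_OF_AGE = np.array([0, 0, 0, 1, 1, 1, 2, 2, 2])


class MVRWModel:
    """Log posterior with analytic gradient for one frame's model."""

    def __init__(self, data: MVRWData):
        self.data = data
        n, m = data.n_years, data.n_obs_years
        self.space = ParameterSpace([
            Block("states", (n, 3)),
            Block("sigma_proc", (), "log"),
            Block("rho", (), "interval", RHO_LO, RHO_HI),
            Block("lam", (n, 9), "log"),
            Block("xi", (9,), "log"),
            Block("exploitation", (m, 9), "interval", 0.0, 1.0),
        ])

    def initial_params(self) -> dict:
        d = self.data
        robs = d.robs
        n, m = d.n_years, d.n_obs_years

        def comp(zeta, has):
            th = np.full((m, 9), 1.0 / 9)
            if np.any(has):
                avg = zeta[has].sum(axis=0) + 0.5
                fb = avg / avg.sum()
            else:
                fb = th[0]
            for i in range(m):
                w = zeta[i] + 0.5 if has[i] else fb
                th[i] = w / np.sum(w)
            return th

        th_c = comp(robs.zeta_catch, robs.has_catch_scales)
        th_e = comp(robs.zeta_esc, robs.has_esc_scales)
        nc = np.where(np.isfinite(robs.obs_catch), robs.obs_catch, 0.0)
        ne = np.where(np.isfinite(robs.obs_esc), robs.obs_esc,
                      np.nanmean(robs.obs_esc) if np.any(np.isfinite(robs.obs_esc))
                      else 1000.0)
        r_hat = nc[:, None] * th_c + ne[:, None] * th_e + 1e-6
        u0 = np.clip(nc[:, None] * th_c / r_hat, 0.03, 0.95)

        b_hat = np.full((n, 9), np.nan)
        cols = np.arange(9)
        b_hat[d.idx, cols] = r_hat
        col_med = np.nanmedian(b_hat, axis=0)
        col_med = np.where(np.isfinite(col_med) & (col_med > 0), col_med, 1.0)
        for a in range(9):
            miss = ~np.isfinite(b_hat[:, a])
            b_hat[miss, a] = col_med[a]
        b_hat = np.maximum(b_hat, 1e-3)

        x0 = np.column_stack(
            [np.log(b_hat[:, d.ages.ocean_set(o)].sum(axis=1)) for o in (1, 2, 3)]
        )
        p0 = np.concatenate(
            [b_hat[:, 3 * i:3 * i + 3]
             / b_hat[:, 3 * i:3 * i + 3].sum(axis=1, keepdims=True)
             for i in range(3)],
            axis=1,
        )
        sig0 = max(float(np.diff(x0, axis=0).std(ddof=1)), 0.2)
        return {
            "states": x0,
            "sigma_proc": sig0,
            "rho": 0.1,
            "lam": 20 * p0,
            "xi": np.clip(20 * p0.mean(axis=0), 0.2, 50.0),
            "exploitation": u0,
        }

    def _terms_and_grads(self, x: dict):
        d = self.data
        n = d.n_years
        xs, sig, rho = x["states"], x["sigma_proc"], x["rho"]
        lam, xi, u = x["lam"], x["xi"], x["exploitation"]

        g = {k: np.zeros_like(np.asarray(v, dtype=float)) for k, v in x.items()}
        gsig = 0.0
        grho = 0.0

        # deterministic chain: states + compositions -> numbers-at-age
        tsum = np.stack(
            [lam[:, 3 * i:3 * i + 3].sum(axis=1) for i in range(3)], axis=1
        )  # (n, 3)
        p = lam / tsum[:, OCEAN_OF_AGE]
        ab = np.exp(xs)  # (n, 3) ocean-age abundances
        bya = ab[:, OCEAN_OF_AGE] * p
        m = d.n_obs_years
        off = d.offsets
        r = np.empty((m, 9))
        for a in range(9):
            r[:, a] = bya[off[a]:off[a] + m, a]
        catch = r * u
        esc = r - catch
        lp_ab, lp_comp, gc, ge = observation_terms_grad(catch, esc, d.robs)

        gr = gc * u + ge * (1 - u)
        g["exploitation"] = (gc - ge) * r
        gbya = np.zeros((n, 9))
        for a in range(9):
            gbya[off[a]:off[a] + m, a] = gr[:, a]
        # states: dB/dx = B
        for i in range(3):
            sl = slice(3 * i, 3 * i + 3)
            g["states"][:, i] = (gbya[:, sl] * bya[:, sl]).sum(axis=1)
            gp = gbya[:, sl] * ab[:, i][:, None]
            pp = p[:, sl]
            g["lam"][:, sl] = (
                gp - (gp * pp).sum(axis=1, keepdims=True)
            ) / tsum[:, i][:, None]

        # multivariate random-walk process
        w = np.diff(xs, axis=0)  # (n-1, 3)
        c = rho / (1 + 2 * rho)
        sw = w.sum(axis=1)
        w2 = (w**2).sum(axis=1)
        quad = (w2 - c * sw**2) / (sig**2 * (1 - rho))
        logdet = 6 * math.log(sig) + 2 * math.log(1 - rho) + math.log(1 + 2 * rho)
        lp_proc = float(-0.5 * np.sum(quad) - (n - 1) * (0.5 * logdet + 1.5 * LN_2PI))
        aw = (w - c * sw[:, None]) / (sig**2 * (1 - rho))  # Q^{-1} w per year
        g["states"][1:] += -aw
        g["states"][:-1] += aw
        gsig += float(np.sum(quad)) / sig - (n - 1) * 3.0 / sig
        dquad = (-sw**2 / ((1 + 2 * rho) ** 2 * sig**2 * (1 - rho))
                 + (w2 - c * sw**2) / (sig**2 * (1 - rho) ** 2))
        grho += float(-0.5 * np.sum(dquad)) + (n - 1) * (
            1 / (1 - rho) - 1 / (1 + 2 * rho)
        )
        # vague normal prior anchors the initial state
        lp_proc += float(np.sum(norm_lpdf(xs[0], 0, X1_PRIOR_SD)))
        g["states"][0] += -xs[0] / X1_PRIOR_SD**2

        # Dirichlet-via-gamma freshwater compositions
        lp_mat = float(np.sum((xi - 1) * np.log(lam) - lam) - n * np.sum(gammaln(xi)))
        g["lam"] += (xi - 1) / lam - 1.0
        g["xi"] = np.log(lam).sum(axis=0) - n * digamma(xi)

        lp_prior = float(
            half_cauchy_lpdf(sig, SIGMA_PRIOR_SCALE)
            - math.log(RHO_HI - RHO_LO)  # uniform rho
            + np.sum((U_BETA_A - 1) * np.log(u) + (U_BETA_B - 1) * np.log1p(-u)
                     - (gammaln(U_BETA_A) + gammaln(U_BETA_B)
                        - gammaln(U_BETA_A + U_BETA_B)))
            + np.sum((XI_PRIOR_SHAPE - 1) * np.log(xi) - XI_PRIOR_RATE * xi
                     + XI_PRIOR_SHAPE * math.log(XI_PRIOR_RATE)
                     - gammaln(XI_PRIOR_SHAPE))
        )
        gsig += half_cauchy_grad(sig, SIGMA_PRIOR_SCALE)
        g["exploitation"] += (U_BETA_A - 1) / u - (U_BETA_B - 1) / (1 - u)
        g["xi"] += (XI_PRIOR_SHAPE - 1) / xi - XI_PRIOR_RATE

        g["sigma_proc"] = gsig
        g["rho"] = grho
        terms = {
            "process": lp_proc,
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

    def params_to_dict(self, params: MVRWParams) -> dict:
        return {
            "states": params.states,
            "sigma_proc": params.sigma_proc,
            "rho": params.rho,
            "lam": params.lam,
            "xi": params.xi,
            "exploitation": params.exploitation,
        }

    def log_posterior_terms(self, params: MVRWParams) -> dict[str, float]:
        terms, _ = self._terms_and_grads(self.params_to_dict(params))
        return terms

    def predicted_tables(self, params: MVRWParams):
        return self.predicted_tables_dict(self.params_to_dict(params))

    def predicted_tables_dict(self, x: dict):
        d = self.data
        lam = np.asarray(x["lam"], dtype=float)
        tsum = np.stack(
            [lam[:, 3 * i:3 * i + 3].sum(axis=1) for i in range(3)], axis=1
        )
        p = lam / tsum[:, OCEAN_OF_AGE]
        bya = np.exp(np.asarray(x["states"], dtype=float))[:, OCEAN_OF_AGE] * p
        r = bya[d.idx, np.arange(9)]
        catch = r * np.asarray(x["exploitation"], dtype=float)
        return catch, r - catch


def mvrw_log_posterior_terms(params: MVRWParams, data: MVRWData) -> dict[str, float]:
    return MVRWModel(data).log_posterior_terms(params)


def mvrw_log_posterior(params: MVRWParams, data: MVRWData) -> float:
    """Log posterior density (constrained parameterization, no Jacobians)."""
    return sum(mvrw_log_posterior_terms(params, data).values())
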