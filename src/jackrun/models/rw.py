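"""Biased random walk for long-term trend in a reconstructed series.

Used for the cohort-frame trend analyses: logit jack proportion, log jack
abundance and log nonjack abundance by brood year.  The reconstructed series
is treated as the state directly (the early record carries no sampling-effort
information that would let observation error be separated from process
error), so only the drift ``u`` and the innovation SD are estimated:

    J_y = J_{y-1} + u + w_y,   w_y ~ Normal(0, sigma_error)

Priors: u ~ Normal(0, 10), sigma_error ~ half-Cauchy(0, 2.5).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..infer.transforms import Block, ParameterSpace
from .common import half_cauchy_grad, half_cauchy_lpdf, norm_lpdf

__all__ = ["RWTrendParams", "RWTrendModel", "rw_log_posterior",
           "rw_log_posterior_terms"]

U_PRIOR_SD = 10.0
SIGMA_PRIOR_SCALE = 2.5


@dataclass
class RWTrendParams:
    """Drift, innovation SD and (optionally) the per-year states.

    ``states=None`` means the observed series itself plays the role of the
    state, which is how the trend fits are run.
    """

    u: float
    sigma_error: float
    states: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.sigma_error <= 0:
            raise ValueError("sigma_error must be positive")


def _states(params: RWTrendParams, series) -> np.ndarray:
    j = params.states if params.states is not None else series
    j = np.asarray(j, dtype=float)
    if len(j) < 2:
        raise ValueError("need at least two years")
    if not np.all(np.isfinite(j)):
        raise ValueError("non-finite values in the state series")
    return j


def rw_log_posterior_terms(params: RWTrendParams, series) -> dict[str, float]:
    """Named components: the process term and the two priors."""
    j = _states(params, series)
    resid = np.diff(j) - params.u
    return {
        "process": float(np.sum(norm_lpdf(resid, 0.0, params.sigma_error))),
        "prior_u": float(norm_lpdf(params.u, 0.0, U_PRIOR_SD)),
        "prior_sigma": float(half_cauchy_lpdf(params.sigma_error, SIGMA_PRIOR_SCALE)),
    }


def rw_log_posterior(params: RWTrendParams, series) -> float:
    return sum(rw_log_posterior_terms(params, series).values())


class RWTrendModel:
    """Sampling wrapper: posterior over (u, sigma_error) given a series."""

    def __init__(self, series):
        self.series = np.asarray(series, dtype=float)
        if len(self.series) < 2 or not np.all(np.isfinite(self.series)):
            raise ValueError("series must be finite with length >= 2")
        self.space = ParameterSpace([
            Block("u", ()),
            Block("sigma_error", (), "log"),
        ])
        self._diffs = np.diff(self.series)

    def initial_params(self) -> dict:
        sd = float(self._diffs.std(ddof=1)) if len(self._diffs) > 1 else 1.0
        return {"u": float(self._diffs.mean()), "sigma_error": max(sd, 0.05)}

    def logp_grad(self, z: np.ndarray):
        x = self.space.unpack(z)
        u, sig = x["u"], x["sigma_error"]
        r = self._diffs - u
        n = len(r)
        lp = float(np.sum(norm_lpdf(r, 0.0, sig)))
        lp += float(norm_lpdf(u, 0.0, U_PRIOR_SD))
        lp += half_cauchy_lpdf(sig, SIGMA_PRIOR_SCALE)
        gu = float(np.sum(r) / sig**2 - u / U_PRIOR_SD**2)
        gsig = float(-n / sig + np.sum(r**2) / sig**3
                     + half_cauchy_grad(sig, SIGMA_PRIOR_SCALE))
        lp += self.space.log_jacobian(z)
        gz = self.space.chain_grad(z, {"u": gu, "sigma_error": gsig})
        return lp, gz
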