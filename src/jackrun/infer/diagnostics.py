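"""Convergence diagnostics: split R-hat, bulk ESS, divergences, E-BFMI.

Thresholds follow current practice: R-hat above 1.01, bulk effective sample
size below 400 and chain E-BFMI below 0.3 are flagged.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["split_rhat", "ess_bulk", "bfmi", "diagnostics_table"]

RHAT_FLAG = 1.01
ESS_FLAG = 400.0
BFMI_FLAG = 0.3


def split_rhat(x: np.ndarray) -> float:
    """Gelman-Rubin potential scale reduction on half-split chains.

    ``x`` has shape (chains, draws).  Each chain is split in half, and the
    classic between/within-variance ratio is computed on the split chains.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("split_rhat needs at least 2 chains of draws")
    n = x.shape[1] // 2
    if n < 2:
        raise ValueError("too few draws to split chains")
    halves = np.concatenate([x[:, :n], x[:, x.shape[1] - n:]], axis=0)
    chain_means = halves.mean(axis=1)
    chain_vars = halves.var(axis=1, ddof=1)
    w = chain_vars.mean()
    b = n * chain_means.var(ddof=1)
    if w == 0:
        return 1.0 if b == 0 else np.inf
    var_plus = (n - 1) / n * w + b / n
    return float(np.sqrt(var_plus / w))


def ess_bulk(x: np.ndarray) -> float:
    """Rank-normalized bulk effective sample size (via arviz)."""
    import arviz as az

    return float(az.ess(np.asarray(x, dtype=float), method="bulk"))


def bfmi(energy: np.ndarray) -> np.ndarray:
    """E-BFMI per chain: mean squared energy increment over energy variance."""
    energy = np.atleast_2d(np.asarray(energy, dtype=float))
    num = np.mean(np.diff(energy, axis=1) ** 2, axis=1)
    den = np.var(energy, axis=1)
    return num / den


def diagnostics_table(draws) -> pd.DataFrame:
    """Per-scalar-parameter convergence table for a :class:`PosteriorDraws`.

    Requires at least two chains.  Columns: rhat, ess_bulk, and a ``flagged``
    indicator; divergence count and per-chain E-BFMI are attached as frame
    attrs.
    """
    if draws.n_chains < 2:
        raise ValueError("diagnostics require at least 2 chains")
    rows = []
    for name, x in draws.iter_scalars():
        r = split_rhat(x)
        e = ess_bulk(x)
        rows.append(
            {
                "parameter": name,
                "rhat": r,
                "ess_bulk": e,
                "flagged": bool(r > RHAT_FLAG or e < ESS_FLAG),
            }
        )
    out = pd.DataFrame(rows)
    out.attrs["divergences"] = int(draws.sample_stats["diverging"].sum())
    out.attrs["bfmi"] = bfmi(draws.sample_stats["energy"]).tolist()
    out.attrs["low_bfmi_chains"] = [
        i for i, v in enumerate(out.attrs["bfmi"]) if v < BFMI_FLAG
    ]
    return out
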