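"""Brood-year-aligned covariate design matrix for the jack-proportion model.

Five covariates are evaluated for their effect on the fraction of a cohort
maturing as jacks: the logit jack proportion among the males that sired the
cohort, the log abundance of females that spawned it (both from weir
censuses of the brood year's spawners), and lagged moving averages of three
environmental series — the NPGO index (ocean entry window: brood year +2 and
+3), Kodiak air temperature and log cladoceran zooplankton biomass (lake
rearing window: +1 and +2).  All columns are Z-scored before fitting.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ages import ObservedCounts

__all__ = [
    "CovariateMatrix",
    "COVARIATE_NAMES",
    "DEFAULT_SHIFTS",
    "lagged_moving_average",
    "impute_leading_value",
    "zscore",
    "safe_logit",
    "build_design_matrix",
]

COVARIATE_NAMES = [
    "sire_logit_jack_proportion",
    "log_female_spawners",
    "npgo_ma",
    "temp_ma",
    "zoop_ma",
]

DEFAULT_SHIFTS = {"npgo": (2, 3), "temp": (1, 2), "zoop": (1, 2)}


class MissingCovariateError(ValueError):
    """A year required by the design matrix is absent from an input series."""


@dataclass
class CovariateMatrix:
    """Design matrix: one row per modeled brood year, one column per covariate."""

    brood_years: np.ndarray
    values: np.ndarray  # (n_years, 5)
    zscored: bool

    def __post_init__(self) -> None:
        self.brood_years = np.asarray(self.brood_years, dtype=int)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.brood_years), len(COVARIATE_NAMES)):
            raise ValueError("covariate matrix shape mismatch")
        if np.any(~np.isfinite(self.values)):
            raise ValueError("covariate matrix contains missing values")
        if self.zscored:
            mu = self.values.mean(axis=0)
            sd = self.values.std(axis=0, ddof=1)
            if np.any(np.abs(mu) > 1e-9) or np.any(np.abs(sd - 1) > 1e-9):
                raise ValueError("zscored matrix does not have mean 0 / SD 1")

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=COVARIATE_NAMES)
        df.insert(0, "brood_year", self.brood_years)
        return df


def _series_lookup(series: pd.Series, year: int, name: str) -> float:
    if year not in series.index or pd.isna(series.loc[year]):
        raise MissingCovariateError(f"covariate {name!r}: no value for year {year}")
    return float(series.loc[year])


def lagged_moving_average(
    series: pd.Series, shifts: tuple[int, ...], brood_years: np.ndarray
) -> pd.Series:
    """Mean of the series over the shifted years, aligned to brood years.

    The value for brood year ``y`` is ``mean(series[y + s] for s in shifts)``;
    e.g. NPGO with shifts (2, 3) averages the two years in which most of a
    cohort migrates to sea.
    """
    name = series.name or "covariate"
    out = np.empty(len(brood_years))
    for i, y in enumerate(np.asarray(brood_years, dtype=int)):
        out[i] = np.mean([_series_lookup(series, y + s, name) for s in shifts])
    return pd.Series(out, index=np.asarray(brood_years, dtype=int), name=name)


def impute_leading_value(series: pd.Series) -> pd.Series:
    """Fill a missing first value with the mean of the following two years.

    Mirrors the handling of the zooplankton series, whose first required year
    had no biomass estimate.  A series whose first value is present is
    returned unchanged.
    """
    s = series.copy()
    if len(s) and pd.isna(s.iloc[0]):
        following = s.iloc[1:3].dropna()
        if len(following) < 2:
            raise ValueError(
                "cannot impute leading value: fewer than 2 following observations"
            )
        s.iloc[0] = following.mean()
    return s


def zscore(values: np.ndarray) -> np.ndarray:
    """Center and scale to sample (n-1) standard deviation 1."""
    x = np.asarray(values, dtype=float)
    sd = x.std(ddof=1)
    if not np.isfinite(sd) or sd == 0:
        raise ValueError("cannot Z-score a constant (or too-short) series")
    return (x - x.mean()) / sd


def safe_logit(successes: float, trials: float) -> float:
    """Logit of an empirically adjusted proportion, finite at 0 and 100%.

    Uses ``(k + 0.5) / (n + 1)``, which is symmetric: ``safe_logit(k, n) ==
    -safe_logit(n - k, n)``.
    """
    if trials <= 0:
        raise ValueError("safe_logit requires trials > 0")
    if successes < 0 or successes > trials:
        raise ValueError("successes must lie in [0, trials]")
    p = (successes + 0.5) / (trials + 1.0)
    return float(np.log(p) - np.log1p(-p))


def build_design_matrix(
    obs: ObservedCounts,
    env: dict[str, pd.Series],
    brood_years: np.ndarray,
    shifts: dict[str, tuple[int, ...]] | None = None,
) -> CovariateMatrix:
    """Assemble and Z-score the five-column covariate matrix.

    ``env`` maps ``{"npgo", "temp", "zoop"}`` to year-indexed series (the
    zooplankton series should already be on the log scale).  The two
    demographic columns come from the weir census rows of ``obs`` for the
    brood years themselves; the environmental columns are lagged moving
    averages with the configured forward shifts.
    """
    shifts = {**DEFAULT_SHIFTS, **(shifts or {})}
    brood_years = np.asarray(brood_years, dtype=int)
    weir = obs.table.set_index("return_year")

    sire = np.empty(len(brood_years))
    females = np.empty(len(brood_years))
    for i, y in enumerate(brood_years):
        if y not in weir.index:
            raise MissingCovariateError(f"no weir census for brood year {y}")
        row = weir.loc[y]
        sire[i] = safe_logit(row["male_jacks"], row["males_total"])
        if row["females_total"] <= 0:
            raise MissingCovariateError(f"no female spawners recorded in year {y}")
        females[i] = np.log(row["females_total"])

    cols = [sire, females]
    for key in ("npgo", "temp", "zoop"):
        series = impute_leading_value(env[key])
        cols.append(
            lagged_moving_average(series, tuple(shifts[key]), brood_years).to_numpy()
        )

    raw = np.column_stack(cols)
    z = np.column_stack([zscore(c) for c in raw.T])
    return CovariateMatrix(brood_years=brood_years, values=z, zscored=True)
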