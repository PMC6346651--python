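import numpy as np
import pandas as pd
import pytest

from jackrun.ages import ObservedCounts, ScaleSamples
from jackrun.models import (
    JackModelData,
    JackModelParams,
    MaturityParams,
    MVRWData,
    MVRWParams,
    ObservationSpec,
    RickerParams,
)
from jackrun.models.common import prepare_return_obs
from jackrun.simulate import make_default_config, simulate_population


@pytest.fixture(scope="session")
def default_dataset():
    """One 25-brood-year simulated dataset shared across tests."""
    return simulate_population(make_default_config(n_brood_years=25), seed=101)


def toy_observations(rng, years, zero_catch_year=None):
    """Random but schema-valid observed counts for the given return years."""
    rows = []
    for t in years:
        males = int(rng.integers(2000, 30000))
        rows.append({
            "return_year": int(t),
            "catch_total": 0.0 if t == zero_catch_year
            else float(rng.uniform(1e4, 8e5)),
            "escapement_total": float(rng.uniform(5e4, 8e5)),
            "male_jacks": int(rng.integers(0, males)),
            "males_total": males,
            "females_total": int(rng.integers(2000, 30000)),
        })
    return ObservedCounts(table=pd.DataFrame(rows))


def toy_scales(rng, source, years, n_lo=50, n_hi=400):
    counts = []
    ns = []
    for _ in years:
        n = int(rng.integers(n_lo, n_hi))
        c = rng.multinomial(n, rng.dirichlet(np.ones(9)))
        counts.append(c)
        ns.append(n)
    return ScaleSamples(source=source, years=np.asarray(years, dtype=int),
                        n_sample=np.asarray(ns), counts=np.asarray(counts))


def toy_jack_instance(rng, n_years=6):
    """Random small jack-model data + parameters for term-wise checks.

    Scale samples are absent from the harvest in the first window year and a
    middle window year has zero recorded catch, so both skip rules are
    exercised.
    """
    y0 = 2000
    brood_years = np.arange(y0, y0 + n_years)
    window = np.arange(y0 + 7, y0 + n_years - 1 + 3 + 1)
    obs = toy_observations(rng, np.arange(y0, window[-1] + 1),
                           zero_catch_year=int(window[len(window) // 2]))
    sc = toy_scales(rng, "catch", window[1:])
    se = toy_scales(rng, "escapement", window)
    robs = prepare_return_obs(window, obs, sc, se, ObservationSpec())
    data = JackModelData(
        brood_years=brood_years,
        covariates=rng.normal(size=(n_years, 5)),
        spawners=rng.uniform(5e4, 5e5, n_years),
        robs=robs,
    )
    m = len(window)
    params = JackModelParams(
        mu_J=float(rng.normal(0, 1)),
        phi=float(rng.uniform(-0.9, 0.9)),
        b=rng.normal(0, 0.5, 5),
        sigma_proc=float(rng.uniform(0.1, 1.0)),
        states_J=rng.normal(-2, 0.7, n_years),
        ricker=RickerParams(
            ln_alpha=float(rng.uniform(0.5, 2.5)),
            beta=float(rng.uniform(0, 5e-6)),
            sigma_R=float(rng.uniform(0.3, 1.2)),
        ),
        ln_returns=rng.normal(13, 0.7, n_years),
        maturity=MaturityParams(
            lam=rng.uniform(0.5, 30.0, (n_years, 9)),
            xi=rng.uniform(0.1, 20.0, 9),
        ),
        exploitation=rng.uniform(0.05, 0.95, (m, 9)),
    )
    return params, data


def toy_mvrw_instance(rng, frame, n_years=6):
    y0 = 2000
    years = np.arange(y0, y0 + n_years)
    if frame == "brood":
        window = np.arange(y0 + 7, y0 + n_years - 1 + 3 + 1)
    else:
        window = years
    obs = toy_observations(rng, np.arange(min(y0, window[0]), window[-1] + 1))
    sc = toy_scales(rng, "catch", window[1:])
    se = toy_scales(rng, "escapement", window)
    robs = prepare_return_obs(window, obs, sc, se, ObservationSpec())
    data = MVRWData(frame=frame, state_years=years, robs=robs)
    params = MVRWParams(
        states=rng.normal(12, 0.8, (n_years, 3)),
        sigma_proc=float(rng.uniform(0.2, 1.0)),
        rho=float(rng.uniform(-0.4, 0.9)),
        lam=rng.uniform(0.5, 30.0, (n_years, 9)),
        xi=rng.uniform(0.1, 20.0, 9),
        exploitation=rng.uniform(0.05, 0.95, (len(window), 9)),
    )
    return params, data
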