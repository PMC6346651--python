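import numpy as np
import pandas as pd
import pytest

from jackrun.infer import PosteriorDraws, SamplerConfig
from jackrun.report import (
    RecoveryReport,
    cohort_mismatch_report,
    recovery_experiment,
    summarize,
)


def _fake_draws(arrays, n_chains=2):
    stats = None
    posterior = {}
    for name, x in arrays.items():
        x = np.asarray(x, dtype=float)
        posterior[name] = x
        if stats is None:
            n = x.shape[1]
            stats = {
                "diverging": np.zeros((n_chains, n), dtype=bool),
                "energy": np.random.default_rng(0).normal(size=(n_chains, n)),
            }
    return PosteriorDraws(posterior=posterior, sample_stats=stats,
                          config=SamplerConfig(n_chains=n_chains,
                                               n_iterations=2 * n,
                                               seed=0))


def test_summarize_quantiles_match_sorting_oracle():
    vals = np.arange(1.0, 101.0)
    draws = _fake_draws({"a": vals.reshape(2, 50)})
    s = summarize(draws, ["a"], diagnostics=False)
    assert s.loc[0, "median"] == pytest.approx(50.5)
    # direct sorting oracle for every reported quantile
    for col, q in (("q2.5", 0.025), ("q25", 0.25), ("q75", 0.75),
                   ("q97.5", 0.975)):
        assert s.loc[0, col] == pytest.approx(np.quantile(vals, q))


def test_summarize_symmetric_draws_and_unknown_parameter():
    rng = np.random.default_rng(1)
    x = rng.normal(size=(2, 4000))
    sym = np.concatenate([x, -x], axis=1)
    s = summarize(_fake_draws({"a": sym}), ["a"], diagnostics=False)
    assert s.loc[0, "median"] == pytest.approx(0.0, abs=1e-12)
    assert s.loc[0, "q2.5"] == pytest.approx(-s.loc[0, "q97.5"], rel=1e-12)
    with pytest.raises(KeyError):
        summarize(_fake_draws({"a": x}), ["nope"])


def test_summarize_flattens_vector_parameters():
    rng = np.random.default_rng(2)
    draws = _fake_draws({"b": rng.normal(size=(2, 30, 5))})
    s = summarize(draws, diagnostics=False)
    assert list(s["parameter"]) == [f"b[{i}]" for i in range(5)]


def test_recovery_experiment_coverage_on_conjugate_normal():
    """Normal mean with known SD: exact posterior, coverage near nominal."""

    def sim(seed):
        rng = np.random.default_rng(seed)
        return rng.normal(2.0, 1.0, 25), {"mu": 2.0}

    def fit(data, seed):
        # flat-prior posterior: Normal(xbar, 1/sqrt(n)); draw from it directly
        rng = np.random.default_rng(seed)
        post = rng.normal(data.mean(), 1 / np.sqrt(len(data)),
                          size=(2, 500))
        return _fake_draws({"mu": post})

    rep = recovery_experiment(sim, fit, ["mu"], n_replicates=60, seed=3)
    s = rep.summary()
    assert s.loc[0, "n_replicates"] == 60
    assert 0.85 <= s.loc[0, "coverage95"] <= 1.0
    assert abs(s.loc[0, "median_bias"]) < 0.15
    assert len(rep.seeds) == 60
    with pytest.raises(ValueError):
        recovery_experiment(sim, fit, ["mu"], n_replicates=1, seed=0)


def _frames(brood_vals, ret_vals, brood_years, ret_years):
    b = pd.DataFrame(brood_vals, columns=["x_o1", "x_o2", "x_o3"])
    b.insert(0, "brood_year", brood_years)
    r = pd.DataFrame(ret_vals, columns=["x_o1", "x_o2", "x_o3"])
    r.insert(0, "return_year", ret_years)
    return b, r


def test_cohort_mismatch_flags_constructed_scenario():
    """Two weak brood years followed by a strong one: the strong cohort's
    jacks return 4 years later among older fish from the weak cohorts."""
    brood_years = np.arange(1990, 2000)
    base = np.full((10, 3), 10.0)
    base[7] += 3.0  # strong 1997 cohort
    base[5:7] -= 1.0  # weak 1995-1996 cohorts
    ret_years = np.arange(1997, 2004)
    rng = np.random.default_rng(4)
    ret = 10.0 + 0.1 * rng.normal(size=(len(ret_years), 3))
    b, r = _frames(base, ret, brood_years, ret_years)
    rep = cohort_mismatch_report(b, r, margin=1.0)
    flagged = rep.loc[rep["mismatch"], "return_year"].tolist()
    assert flagged == [1997 + 4]
    row = rep[rep["return_year"] == 2001].iloc[0]
    assert row["source_brood_o1"] == 1997
    assert row["source_brood_o2"] == 1996
    assert row["source_brood_o3"] == 1995


def test_cohort_mismatch_constant_broods_no_flags():
    brood_years = np.arange(1990, 2000)
    ret_years = np.arange(1997, 2004)
    b, r = _frames(np.full((10, 3), 8.0), np.full((7, 3), 8.0),
                   brood_years, ret_years)
    rep = cohort_mismatch_report(b, r)
    assert not rep["mismatch"].any()
    assert np.allclose(rep["jack_fraction_of_run"], 1 / 3)


def test_recovery_report_sign_agreement():
    table = pd.DataFrame({
        "replicate": [0, 1, 2],
        "parameter": ["rho"] * 3,
        "truth": [0.6, 0.6, 0.6],
        "median": [0.5, 0.7, -0.1],
        "q2.5": [0.1, 0.2, -0.4],
        "q97.5": [0.9, 0.9, 0.3],
        "covered": [True, True, False],
    })
    s = RecoveryReport(table=table).summary()
    assert s.loc[0, "sign_agreement"] == pytest.approx(2 / 3)
    assert s.loc[0, "coverage95"] == pytest.approx(2 / 3)
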