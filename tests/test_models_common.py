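import numpy as np
import pytest

from jackrun.models import (
    ObservationSpec,
    build_Q,
    dirichlet_from_gamma,
    effective_sample_size,
    inverse_logit_split,
    observation_log_likelihood,
    ricker_log_mean,
)
from jackrun.models.common import observation_terms_grad, prepare_return_obs

from conftest import toy_observations, toy_scales
from oracles import observation_oracle


def test_inverse_logit_split():
    bj, bh = inverse_logit_split(100.0, 0.0)
    assert bj == pytest.approx(50.0) and bh == pytest.approx(50.0)
    bj, bh = inverse_logit_split(500.0, -40.0)
    assert bj == pytest.approx(0.0, abs=1e-10) and bh == pytest.approx(500.0)
    logit_009 = np.log(0.09 / 0.91)
    bj, bh = inverse_logit_split(1000.0, logit_009)
    assert bj == pytest.approx(90.0) and bh == pytest.approx(910.0)
    # conservation to the final floating-point ulp
    rng = np.random.default_rng(0)
    b = rng.uniform(0, 1e6, 50)
    j = rng.normal(0, 3, 50)
    bj, bh = inverse_logit_split(b, j)
    assert np.allclose(bj + bh, b, rtol=5e-16, atol=0.0)


def test_ricker_log_mean():
    assert ricker_log_mean(1000.0, 1.0, 0.0) == pytest.approx(np.log(1000) + 1)
    # replacement point: S = ln(alpha) / beta gives expected log return = ln S
    ln_a, beta = 1.2, 2e-6
    s_star = ln_a / beta
    assert ricker_log_mean(s_star, ln_a, beta) == pytest.approx(np.log(s_star))
    assert ricker_log_mean(1000.0, 1.0, 0.001) == pytest.approx(
        np.log(1000) + 1 - 1.0
    )
    with pytest.raises(ValueError):
        ricker_log_mean(0.0, 1.0, 0.001)


def test_dirichlet_from_gamma():
    assert np.allclose(dirichlet_from_gamma([2.0, 2.0, 2.0]), 1 / 3)
    assert np.allclose(dirichlet_from_gamma([1.0, 2.0, 3.0]),
                       [1 / 6, 1 / 3, 1 / 2])
    rng = np.random.default_rng(1)
    lam = rng.uniform(0.01, 50, (20, 9))
    p = dirichlet_from_gamma(lam)
    assert np.allclose(p.sum(axis=1), 1.0, atol=1e-12)
    with pytest.raises(ValueError):
        dirichlet_from_gamma([1.0, 0.0, 2.0])


def test_build_Q():
    assert np.allclose(build_Q(1.0, 0.0), np.eye(3))
    q = build_Q(0.7, 0.4)
    off = q[~np.eye(3, dtype=bool)]
    assert np.allclose(off, 0.7**2 * 0.4)  # gamma = sigma^2 * rho
    assert np.all(np.linalg.eigvalsh(q) > 0)
    with pytest.raises(ValueError):
        build_Q(1.0, -0.6)  # eigenvalue 1 + 2*rho would be negative
    with pytest.raises(ValueError):
        build_Q(0.0, 0.2)


def test_effective_sample_size_cap():
    spec = ObservationSpec()
    assert effective_sample_size(1500, spec) == 1000
    assert effective_sample_size(400, spec) == 400
    assert effective_sample_size(1000, spec) == 1000


def test_observation_likelihood_matches_termwise_oracle():
    rng = np.random.default_rng(7)
    years = np.arange(2000, 2006)
    obs = toy_observations(rng, years, zero_catch_year=2002)
    sc = toy_scales(rng, "catch", years[2:])
    se = toy_scales(rng, "escapement", years, n_lo=800, n_hi=3000)  # hits cap
    robs = prepare_return_obs(years, obs, sc, se, ObservationSpec())
    # capped years carry rescaled (non-integer) counts summing to the cap
    capped = robs.zeta_esc.sum(axis=1) == 1000
    assert capped.any()
    for _ in range(5):
        catch = rng.uniform(1e3, 1e5, (6, 9))
        esc = rng.uniform(1e3, 1e5, (6, 9))
        ours = observation_log_likelihood(catch, esc, robs)
        assert ours == pytest.approx(observation_oracle(catch, esc, robs),
                                     abs=1e-8)


def test_observation_likelihood_skip_rules():
    rng = np.random.default_rng(8)
    years = np.arange(2000, 2004)
    obs = toy_observations(rng, years, zero_catch_year=2001)
    se = toy_scales(rng, "escapement", years)
    robs = prepare_return_obs(years, obs, None, se, ObservationSpec())
    # no catch scales at all -> no catch multinomial terms
    assert not robs.has_catch_scales.any()
    # zero recorded catch -> that year contributes no abundance term
    assert np.isnan(robs.obs_catch[1])
    catch = rng.uniform(1e3, 1e5, (4, 9))
    esc = rng.uniform(1e3, 1e5, (4, 9))
    base = observation_log_likelihood(catch, esc, robs)
    catch2 = catch.copy()
    catch2[1] *= 10  # year with no catch information at all
    assert observation_log_likelihood(catch2, esc, robs) == pytest.approx(base)


def test_single_age_multinomial_term_is_zero():
    """A sample concentrated on one age, with prediction concentrated on the
    same age, has multinomial log probability 0."""
    import pandas as pd

    from jackrun.ages import ObservedCounts, ScaleSamples

    obs = ObservedCounts(table=pd.DataFrame([{
        "return_year": 2000, "catch_total": 0.0, "escapement_total": 0.0,
        "male_jacks": 0, "males_total": 1, "females_total": 1,
    }]))
    counts = np.zeros((1, 9), dtype=int)
    counts[0, 4] = 100
    se = ScaleSamples(source="escapement", years=[2000], n_sample=[100],
                      counts=counts)
    robs = prepare_return_obs([2000], obs, None, se, ObservationSpec())
    esc = np.full((1, 9), 1e-9)
    esc[0, 4] = 5000.0
    pred_catch = np.ones((1, 9))
    assert observation_log_likelihood(pred_catch, esc, robs) == pytest.approx(
        0.0, abs=1e-4
    )


def test_observation_gradients_match_finite_differences():
    rng = np.random.default_rng(9)
    years = np.arange(2000, 2004)
    obs = toy_observations(rng, years)
    sc = toy_scales(rng, "catch", years[1:])
    se = toy_scales(rng, "escapement", years)
    robs = prepare_return_obs(years, obs, sc, se, ObservationSpec())
    catch = rng.uniform(1e3, 1e5, (4, 9))
    esc = rng.uniform(1e3, 1e5, (4, 9))
    a, c, gc, ge = observation_terms_grad(catch, esc, robs)
    h = 1.0  # abundances are ~1e4, so unit steps are tiny relative steps
    for (i, j) in [(0, 0), (1, 4), (3, 8), (2, 2)]:
        cp = catch.copy()
        cp[i, j] += h
        cm = catch.copy()
        cm[i, j] -= h
        fd = (sum(observation_terms_grad(cp, esc, robs)[:2])
              - sum(observation_terms_grad(cm, esc, robs)[:2])) / (2 * h)
        assert fd == pytest.approx(gc[i, j], rel=1e-4, abs=1e-10)
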