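import numpy as np
import pytest

from jackrun.models.common import build_Q
from jackrun.simulate import (
    make_default_config,
    simulate_mvrw,
    simulate_mvrw_population,
    simulate_population,
    simulate_rw_series,
)


def test_default_config_anchored_values():
    cfg = make_default_config()
    assert cfg.b[0] == pytest.approx(0.43)
    assert cfg.sigma_R == pytest.approx(0.83)
    assert cfg.exploitation_mean == (0.13, 0.52, 0.60)
    assert (cfg.sigma_C, cfg.sigma_E) == (0.5, 0.1)
    with pytest.raises(ValueError):
        make_default_config(phi=1.2)
    with pytest.raises(ValueError):
        make_default_config(sigma_R=-0.1)


def test_simulation_deterministic_given_seed(default_dataset):
    cfg = make_default_config(n_brood_years=25)
    again = simulate_population(cfg, seed=101)
    assert np.array_equal(again.truth.states_J, default_dataset.truth.states_J)
    assert again.observed.table.equals(default_dataset.observed.table)
    assert np.array_equal(again.scales_catch.counts,
                          default_dataset.scales_catch.counts)
    other = simulate_population(cfg, seed=102)
    assert not np.array_equal(other.truth.states_J,
                              default_dataset.truth.states_J)


def test_simulation_conserves_fish(default_dataset):
    t = default_dataset.truth
    assert np.allclose(t.catch.values + t.escapement.values, t.run.values,
                       rtol=1e-12)
    # brood table rows reassemble the cohort totals
    assert np.allclose(t.brood_table.values.sum(axis=1), t.returns_total)
    assert np.allclose(t.returns_jack + t.returns_nonjack, t.returns_total)


def test_scale_samples_sum_to_sample_size(default_dataset):
    for scales in (default_dataset.scales_catch, default_dataset.scales_esc):
        assert np.array_equal(scales.counts.sum(axis=1), scales.n_sample)


def test_noise_free_simulation_matches_forward_recursion():
    """With all noise off, the simulator must equal an independently coded
    deterministic recursion."""
    cfg = make_default_config(
        n_brood_years=8, sigma_R=0.0, sigma_proc=0.0, sigma_C=0.0, sigma_E=0.0,
        maturity_concentration=None, exploitation_concentration=None,
        scale_samples_catch=0, scale_samples_esc=0, b=(0.0,) * 5,
    )
    ds = simulate_population(cfg, seed=1)

    # independent recursion: constant age-class shares of each cohort
    share = 1 / (1 + np.exp(-cfg.mu_J))
    p = np.concatenate([
        share * np.asarray(cfg.maturity_mean_jack),
        (1 - share) * np.asarray(cfg.maturity_mean_nonjack),
    ])
    u = np.asarray(cfg.exploitation_mean)[[0, 0, 0, 1, 1, 1, 2, 2, 2]]
    ta = np.array([1 + f + o for o in (1, 2, 3) for f in (1, 2, 3)])
    y0 = cfg.start_year - cfg.burn_in
    years = np.arange(y0, cfg.start_year + cfg.n_brood_years)
    esc_arrivals = {}
    spawners = {}
    b_total = {}
    for y in years:
        esc_y = esc_arrivals.get(y)
        s = esc_y.sum() if (esc_y is not None and y - 7 >= y0) else (
            cfg.initial_spawners)
        ln_b = np.log(s) + cfg.ln_alpha - cfg.beta * s
        b = np.exp(ln_b)
        cells = b * p
        for a in range(9):
            t = y + ta[a]
            esc_arrivals.setdefault(t, np.zeros(9))[a] = (
                esc_arrivals.setdefault(t, np.zeros(9))[a]
                + cells[a] * (1 - u[a])
            )
        spawners[y], b_total[y] = s, b

    rec = ds.truth.brood_years
    expect_s = np.array([spawners[y] for y in rec])
    expect_b = np.array([b_total[y] for y in rec])
    assert np.allclose(ds.truth.spawners, expect_s, rtol=1e-10)
    assert np.allclose(ds.truth.returns_total, expect_b, rtol=1e-10)
    assert np.allclose(ds.truth.states_J, cfg.mu_J)
    # noise-free observations equal the latent totals
    obs = ds.observed.table.set_index("return_year")
    for i, t in enumerate(ds.truth.return_years):
        assert obs.loc[t, "catch_total"] == pytest.approx(
            ds.truth.catch.values[i].sum(), rel=1e-10)
        assert obs.loc[t, "escapement_total"] == pytest.approx(
            ds.truth.escapement.values[i].sum(), rel=1e-10)


def test_rw_series_properties():
    assert np.allclose(simulate_rw_series(0.5, 0.0, 5, seed=0),
                       [0, 0.5, 1.0, 1.5, 2.0])
    x = simulate_rw_series(0.03, 0.3, 10_000, seed=4)
    incr = np.diff(x)
    assert abs(incr.mean() - 0.03) < 3 * 0.3 / np.sqrt(len(incr))
    assert np.array_equal(x, simulate_rw_series(0.03, 0.3, 10_000, seed=4))
    with pytest.raises(ValueError):
        simulate_rw_series(0.0, -1.0, 10, seed=0)


def test_mvrw_series_properties():
    x = simulate_mvrw(0.0, 0.3, 6, seed=0)
    assert np.allclose(x, x[0])
    x = simulate_mvrw(1.0, 0.0, 10_000, seed=5)
    incr = np.diff(x, axis=0)
    corr = np.corrcoef(incr.T)
    off = corr[~np.eye(3, dtype=bool)]
    assert np.all(np.abs(off) < 0.05)
    assert np.array_equal(x, simulate_mvrw(1.0, 0.0, 10_000, seed=5))
    with pytest.raises(ValueError):
        simulate_mvrw(1.0, -0.6, 100, seed=0)
    # empirical covariance approaches the construction target
    x = simulate_mvrw(0.7, 0.4, 20_000, seed=6)
    emp = np.cov(np.diff(x, axis=0).T)
    assert np.allclose(emp, build_Q(0.7, 0.4), atol=0.03)


def test_mvrw_population_layer():
    sim = simulate_mvrw_population(sigma=0.4, rho=0.2, n_years=12, seed=9)
    t = sim["truth"]
    assert np.allclose(t["catch"] + t["escapement"], t["run"], rtol=1e-12)
    assert t["gamma"] == pytest.approx(0.4**2 * 0.2)
    assert np.array_equal(sim["scales_catch"].counts.sum(axis=1),
                          sim["scales_catch"].n_sample)


def test_write_dataset_round_trips(tmp_path, default_dataset):
    from jackrun.ages import (
        read_brood_table,
        read_covariate_table,
        read_observed_counts,
        read_scale_samples,
    )
    from jackrun.simulate import write_dataset

    write_dataset(default_dataset, tmp_path)
    brood = read_brood_table(tmp_path / "brood_table.csv")
    assert np.allclose(brood.values, default_dataset.truth.brood_table.values)
    obs = read_observed_counts(tmp_path / "observations.csv")
    assert len(obs.years) == len(default_dataset.observed.years)
    sc = read_scale_samples(tmp_path / "scales_catch.csv", "catch")
    assert np.array_equal(sc.counts, default_dataset.scales_catch.counts)
    cov = read_covariate_table(tmp_path / "covariates.csv")
    assert {"npgo", "kodiak_temp", "zoop_log_biomass"} <= set(cov.columns)
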