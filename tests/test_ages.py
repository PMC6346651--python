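import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from jackrun.ages import (
    AgeClass,
    AgeStructure,
    BroodTable,
    SchemaError,
    AGE_COLUMNS,
    apply_exploitation,
    brood_summaries,
    brood_to_return,
    read_brood_table,
    read_observed_counts,
    read_scale_samples,
    return_to_brood,
    total_age,
)


@pytest.mark.parametrize(
    "fw, ocean, expected",
    [(2, 1, 4), (1, 1, 3), (3, 3, 7), (2, 2, 5), (2, 3, 6)],
)
def test_total_age(fw, ocean, expected):
    """Total age = gravel year + freshwater + ocean years; jacks with the
    modal 2 lake years mature at total age 4."""
    assert total_age(fw, ocean) == expected


@pytest.mark.parametrize("fw, ocean", [(0, 1), (4, 2), (1, 0), (2, 4)])
def test_total_age_rejects_out_of_range(fw, ocean):
    with pytest.raises(ValueError):
        total_age(fw, ocean)


def test_age_structure_index_sets():
    ages = AgeStructure()
    assert [c.index_a for c in ages.classes] == list(range(1, 10))
    assert ages.classes[0].column == "o1_f1"
    assert list(ages.jack_set) == [0, 1, 2]
    assert list(ages.nonjack_set) == [3, 4, 5, 6, 7, 8]
    assert all(len(ages.ocean_set(o)) == 3 for o in (1, 2, 3))
    assert AgeClass(fw_age=2, ocean_age=3).total_age_Ta == 6


def _table_strategy():
    return arrays(
        float, (5, 9), elements=st.floats(0, 1e6, allow_nan=False)
    ).map(lambda v: BroodTable(years=np.arange(1995, 2000), values=v))


@given(_table_strategy())
@settings(max_examples=30, deadline=None)
def test_brood_return_round_trip(brood):
    """Lagging to return years and back recovers every cohort cell."""
    ret = brood_to_return(brood)
    back = return_to_brood(ret)
    i0 = brood.years[0] - back.years[0]
    sub = back.values[i0:i0 + len(brood.years)]
    assert np.array_equal(sub, brood.values, equal_nan=True)


def test_brood_to_return_lags_match_reindexing_oracle():
    """A jack (total age 4) from brood 1999 returns in 2003; an ocean age-3
    fish from brood 1997 also returns in 2003."""
    rng = np.random.default_rng(1)
    brood = BroodTable(years=np.arange(1996, 2001),
                       values=rng.uniform(0, 100, (5, 9)))
    ret = brood_to_return(brood)
    ta = AgeStructure().total_ages
    # brute-force per-cell oracle
    for i, t in enumerate(ret.years):
        for a in range(9):
            y = t - ta[a]
            if brood.years[0] <= y <= brood.years[-1]:
                assert ret.values[i, a] == brood.values[y - brood.years[0], a]
            else:
                assert np.isnan(ret.values[i, a])
    jack_col = 1  # ocean 1, fw 2 -> total age 4
    assert (ret.values[ret.years == 2003, jack_col]
            == brood.values[brood.years == 1999, jack_col])
    o3_col = 7  # ocean 3, fw 2 -> total age 6
    assert (ret.values[ret.years == 2003, o3_col]
            == brood.values[brood.years == 1997, o3_col])


def test_single_cohort_single_age_shifts_by_total_age():
    vals = np.zeros((1, 9))
    vals[0, 4] = 50.0  # ocean 2, fw 2 -> total age 5
    ret = brood_to_return(BroodTable(years=np.array([2000]), values=vals))
    populated = np.argwhere(~np.isnan(ret.values) & (ret.values > 0))
    assert len(populated) == 1
    assert ret.years[populated[0][0]] == 2005


@given(
    arrays(float, (4, 9), elements=st.floats(0, 1e6, allow_nan=False)),
    arrays(float, (4, 9), elements=st.floats(0, 1, allow_nan=False)),
)
@settings(max_examples=30, deadline=None)
def test_exploitation_conserves_fish(values, u):
    """catch + escapement reassembles the run cell by cell (to the final
    floating-point ulp)."""
    from jackrun.ages import ReturnTable

    ret = ReturnTable(years=np.arange(2000, 2004), values=values)
    catch, esc = apply_exploitation(ret, u)
    assert np.allclose(catch.values + esc.values, ret.values,
                       rtol=5e-16, atol=0.0)


def test_exploitation_limits_and_validation():
    from jackrun.ages import ReturnTable

    ret = ReturnTable(years=np.array([2000]), values=np.full((1, 9), 80.0))
    catch, esc = apply_exploitation(ret, 0.0)
    assert np.all(catch.values == 0) and np.array_equal(esc.values, ret.values)
    catch, esc = apply_exploitation(ret, 1.0)
    assert np.all(esc.values == 0) and np.array_equal(catch.values, ret.values)
    catch, esc = apply_exploitation(ret, 0.25)
    assert np.all(catch.values == 20.0) and np.all(esc.values == 60.0)
    with pytest.raises(ValueError):
        apply_exploitation(ret, 1.2)


def test_brood_summaries_against_per_cell_sums():
    rng = np.random.default_rng(2)
    vals = rng.uniform(0, 1000, (6, 9))
    vals[2] = 0.0  # a wiped-out cohort has no defined jack proportion
    brood = BroodTable(years=np.arange(1990, 1996), values=vals)
    s = brood_summaries(brood)
    for i in range(6):
        assert s["jack_abundance"][i] == pytest.approx(vals[i, :3].sum())
        assert s["nonjack_abundance"][i] == pytest.approx(vals[i, 3:].sum())
    assert bool(s["undefined"][2]) and np.isnan(s["jack_proportion"][2])
    ok = ~s["undefined"]
    assert ((s.loc[ok, "jack_proportion"] >= 0)
            & (s.loc[ok, "jack_proportion"] <= 1)).all()
    row = vals[0]
    assert s["jack_proportion"][0] == pytest.approx(
        row[:3].sum() / row.sum()
    )


def test_read_brood_table_round_trip(tmp_path):
    rng = np.random.default_rng(3)
    brood = BroodTable(years=np.arange(2000, 2003),
                       values=rng.uniform(0, 10, (3, 9)))
    path = tmp_path / "brood.csv"
    brood.to_csv(path)
    assert read_brood_table(path) == brood


def test_read_brood_table_schema_errors(tmp_path):
    path = tmp_path / "bad.csv"
    df = pd.DataFrame({"brood_year": [2000], **{c: [1.0] for c in AGE_COLUMNS}})
    df.loc[0, "o1_f2"] = -5
    df.to_csv(path, index=False)
    with pytest.raises(SchemaError, match="negative"):
        read_brood_table(path)
    df.loc[0, "o1_f2"] = 1.0
    pd.concat([df, df]).to_csv(path, index=False)
    with pytest.raises(SchemaError, match="duplicated"):
        read_brood_table(path)
    df.drop(columns=["o3_f3"]).to_csv(path, index=False)
    with pytest.raises(SchemaError, match="missing columns"):
        read_brood_table(path)


def test_read_drops_rare_age_classes_with_warning(tmp_path):
    path = tmp_path / "brood.csv"
    df = pd.DataFrame({"brood_year": [2000, 2001],
                       **{c: [1.0, 2.0] for c in AGE_COLUMNS},
                       "o4_f2": [0.5, 0.1]})
    df.to_csv(path, index=False)
    with pytest.warns(UserWarning, match="rare age-class"):
        brood = read_brood_table(path)
    assert brood.values.shape == (2, 9)


def test_read_observed_counts_validation(tmp_path):
    path = tmp_path / "obs.csv"
    df = pd.DataFrame({
        "return_year": [2000, 2001, 2002],
        "catch_total": [10.0, 5.0, 3.0],
        "escapement_total": [20.0, 10.0, 6.0],
        "male_jacks": [1, 2, 3],
        "males_total": [5, 5, 5],
        "females_total": [4, 4, 4],
    })
    df.to_csv(path, index=False)
    obs = read_observed_counts(path)
    assert len(obs.years) == 3
    df.loc[1, "catch_total"] = -1
    df.to_csv(path, index=False)
    with pytest.raises(SchemaError, match="negative"):
        read_observed_counts(path)


def test_scale_samples_sum_validation():
    from jackrun.ages import ScaleSamples

    with pytest.raises(SchemaError, match="sum"):
        ScaleSamples(source="catch", years=[2000], n_sample=[10],
                     counts=np.ones((1, 9), dtype=int))
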