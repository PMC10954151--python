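"""Season bins, binary diagnostic ratios and the ANOVA/t machinery."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats

from pm25elements.core import ConcentrationTable, ElementPanel, ValidationError
from pm25elements.ratios import (anova_oneway, assign_season, binary_ratios,
                                 pearson_matrix, seasonal_ratio_table,
                                 ttest_two_sample)
from pm25elements.synth import SynthConfig, simulate_dataset


def _table(cols: dict, site="A"):
    panel = ElementPanel(symbols=tuple(cols),
                         native_units={c: "ng/m3" for c in cols})
    n = len(next(iter(cols.values())))
    values = pd.DataFrame({"site": site,
                           "date": pd.date_range("2020-07-01", periods=n)})
    for c, v in cols.items():
        values[c] = np.asarray(v, float)
    flags = pd.DataFrame("measured", index=values.index, columns=list(cols))
    return ConcentrationTable(panel, values, flags)


# -------------------------------------------------------------------- season

@pytest.mark.parametrize("date,season", [
    ("2021-02-17", "November-February"),
    ("2020-07-01", "July-October"),
    ("2021-03-01", "March-June"),
    ("2020-11-30", "November-February"),
])
def test_assign_season(date, season):
    assert assign_season(date) == season


def test_seasons_partition_all_months():
    seen = [assign_season(f"2021-{m:02d}-15") for m in range(1, 13)]
    assert len(seen) == 12
    assert set(seen) == {"March-June", "July-October", "November-February"}


# -------------------------------------------------------------------- ratios

def test_binary_ratio_values():
    t = _table({"Na": [4.0, 3.0], "Mg": [2.0, 3.0]})
    out = binary_ratios(t, "Na", "Mg")
    np.testing.assert_allclose(out["ratio"], [2.0, 1.0])


def test_equal_elements_give_unit_ratio():
    vals = [1.0, 5.5, 2.25]
    out = binary_ratios(_table({"Na": vals, "Mg": vals}), "Na", "Mg")
    np.testing.assert_allclose(out["ratio"], 1.0)


def test_zero_denominators_rejected():
    with pytest.raises(ValidationError):
        binary_ratios(_table({"Na": [1.0, 2.0], "Mg": [0.0, 0.0]}), "Na", "Mg")


def test_jensen_gap_on_skewed_data():
    rng = np.random.default_rng(2)
    num = rng.lognormal(0, 1.0, 500)
    den = rng.lognormal(0, 1.0, 500)
    t = _table({"Na": num, "Mg": den})
    mean_of_ratios = binary_ratios(t, "Na", "Mg")["ratio"].mean()
    ratio_of_means = num.mean() / den.mean()
    assert abs(mean_of_ratios - ratio_of_means) > 0.1 * ratio_of_means


# --------------------------------------------------------------------- tests

def test_anova_identical_groups_not_significant():
    g = [1.0, 2.0, 3.0]
    res = anova_oneway([g, g, g])
    assert res.statistic == 0.0
    assert not res.significant


def test_anova_matches_brute_force_sums_of_squares():
    groups = [np.array([1.0, 2.0, 3.0]), np.array([2.0, 3.0, 4.0]),
              np.array([7.0, 8.0, 9.0])]
    res = anova_oneway(groups)
    # independent decomposition by hand
    allv = np.concatenate(groups)
    grand = allv.mean()
    ssb = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ssw = sum(((g - g.mean()) ** 2).sum() for g in groups)
    f_hand = (ssb / 2) / (ssw / 6)
    assert res.statistic == pytest.approx(f_hand, rel=1e-12)
    f_scipy, _ = stats.f_oneway(*groups)
    assert res.statistic == pytest.approx(f_scipy, rel=1e-10)
    assert res.df == (2, 6)


def test_published_critical_values():
    """The campaign prints F_crit 3.109 for (2, 79) df and a t critical
    1.678 at df = 46; both match at two decimals."""
    res = anova_oneway([np.arange(22.0), np.arange(31.0), np.arange(29.0)])
    assert res.df == (2, 79)
    assert round(res.critical, 2) == round(3.109, 2)
    a, b = np.arange(24.0), np.arange(24.0) + 1
    t = ttest_two_sample(a, b)
    assert t.df == (46,)
    assert round(t.critical, 2) == round(1.678, 2)


def test_t_statistic_matches_scipy_pooled():
    rng = np.random.default_rng(4)
    a, b = rng.normal(0, 1, 12), rng.normal(0.8, 1, 15)
    res = ttest_two_sample(a, b)
    t_scipy, _ = stats.ttest_ind(a, b, equal_var=True)
    assert res.statistic == pytest.approx(t_scipy, rel=1e-10)


def test_t_identical_groups_zero():
    a = [1.0, 1.0, 1.0]
    assert ttest_two_sample(a, a).statistic == 0.0


@given(st.floats(-50, 50), st.floats(0.1, 20))
def test_anova_f_invariant_to_affine_maps(shift, scale):
    groups = [np.array([1.0, 2.0, 3.0]), np.array([2.0, 4.0, 5.0]),
              np.array([7.0, 8.0, 10.0])]
    base = anova_oneway(groups).statistic
    mapped = anova_oneway([g * scale + shift for g in groups]).statistic
    assert mapped == pytest.approx(base, rel=1e-6)


# ------------------------------------------------------------------- pearson

def test_pearson_perfect_linear():
    x = np.arange(1.0, 8.0)
    m = pearson_matrix(pd.DataFrame({"a": x, "b": 2 * x}))
    assert m.loc["a", "b"] == pytest.approx(1.0)


def test_pearson_matches_pairwise_formula():
    df = pd.DataFrame({"a": [1.0, 2.0, 4.0, 3.0],
                       "b": [2.0, 1.0, 5.0, 2.0],
                       "c": [0.5, 2.5, 1.0, 4.0]})
    m = pearson_matrix(df)
    for i in df.columns:
        for j in df.columns:
            r, _ = stats.pearsonr(df[i], df[j])
            assert m.loc[i, j] == pytest.approx(r, abs=1e-12)


def test_pearson_matrix_positive_semidefinite(mixture_200):
    table, _, _ = mixture_200
    m = pearson_matrix(table.matrix())
    eig = np.linalg.eigvalsh(m.to_numpy())
    assert eig.min() > -1e-10
    assert np.allclose(np.diag(m), 1.0)


def test_sodium_magnesium_share_a_source(preset_profiles):
    """Na and Mg both load on the crustal/marine source, so when the
    shared-source variation dominates measurement noise their correlation
    is very strong (r^2 > 0.9)."""
    cfg = SynthConfig(n_samples={"S1": 300}, cv=0.05, seed=12)
    table, _, _ = simulate_dataset(preset_profiles, cfg)
    m = pearson_matrix(table.matrix())
    assert m.loc["Na", "Mg"] ** 2 > 0.9


def test_seasonal_table_layout(preset_profiles):
    cfg = SynthConfig(seed=3)   # three sites, study-sized, study seasons
    table, _, _ = simulate_dataset(preset_profiles, cfg)
    out = seasonal_ratio_table(table, pairs=(("Na", "Mg"), ("Fe", "Al")))
    # Bangkok has two populated seasons -> t test; the others -> ANOVA
    namg = out.xs("Na/Mg", level="ratio")
    assert set(namg.xs("BOS", level="site")["test"]) <= {"t", ""}
    assert "anova" in set(namg.xs("COS", level="site")["test"])
    counts = namg.xs("COS", level="site")["n"]
    assert counts.sum() == 82
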