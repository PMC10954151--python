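"""PCA, varimax, APCS scores and the regression receptor model."""

from itertools import permutations

import numpy as np
import pandas as pd
import pytest

from pm25elements.core import ConcentrationTable, ElementPanel, ValidationError
from pm25elements.receptor import (ApcsModel, PcaModel, apcs_scores, fit_pca,
                                   fit_receptor_model, mlr_contributions,
                                   mp_ratios, retain_components, rotate_model,
                                   site_mean_mp, standardize, varimax_criterion,
                                   varimax_rotate)
from pm25elements.synth import SourceProfileSet, SynthConfig, simulate_dataset


def _match(columns: np.ndarray, targets: np.ndarray, absolute=True):
    """Best per-target |r| over column assignments (greedy over permutations)."""
    k = targets.shape[1]
    best = None
    for perm in permutations(range(columns.shape[1]), k):
        rs = [np.corrcoef(columns[:, perm[i]], targets[:, i])[0, 1]
              for i in range(k)]
        rs = [abs(r) if absolute else r for r in rs]
        if best is None or min(rs) > min(best):
            best = rs
    return best


# ---------------------------------------------------------------- standardize

def test_standardize_hand_arithmetic():
    z = standardize(pd.DataFrame({"a": [1.0, 2.0, 3.0]}))
    np.testing.assert_allclose(z.z[:, 0], [-1.0, 0.0, 1.0])


def test_standardize_idempotent_and_invertible():
    rng = np.random.default_rng(0)
    x = pd.DataFrame(rng.lognormal(size=(30, 4)), columns=list("abcd"))
    z = standardize(x)
    z2 = standardize(pd.DataFrame(z.z, columns=list("abcd")))
    np.testing.assert_allclose(z2.z, z.z, atol=1e-12)
    np.testing.assert_allclose(z.inverse(), x.to_numpy(), atol=1e-10)


def test_standardize_rejects_constant_column():
    with pytest.raises(ValidationError, match="b"):
        standardize(pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [5.0, 5.0, 5.0]}))


# ----------------------------------------------------------------------- PCA

def test_two_perfectly_correlated_variables():
    x = np.arange(10.0)
    model = fit_pca(standardize(pd.DataFrame({"a": x, "b": 2 * x + 1})))
    np.testing.assert_allclose(model.eigenvalues, [2.0, 0.0], atol=1e-10)


def test_explained_variance_sums_to_100(mixture_200):
    table, _, _ = mixture_200
    model = fit_pca(standardize(table.matrix()))
    assert model.explained_variance_pct.sum() == pytest.approx(100.0)
    assert model.eigenvalues.sum() == pytest.approx(len(model.columns))


def test_noise_free_mixture_rank(noise_free_60):
    table, _, _ = noise_free_60
    model = fit_pca(standardize(table.matrix()))
    assert (model.eigenvalues > 1e-8).sum() == 3


def test_retain_components_strict_inequality():
    model = PcaModel(np.array([3.2, 1.5, 1.0, 0.3]), np.eye(4), ("a", "b", "c", "d"))
    assert retain_components(model) == 2
    with pytest.raises(ValidationError):
        retain_components(PcaModel(np.array([0.9, 0.5]), np.eye(2), ("a", "b")))


# ------------------------------------------------------------------- varimax

def test_varimax_identity_like_loadings_unchanged():
    L = np.array([[1.0, 0.0], [0.0, 1.0], [1.0, 0.0], [0.0, 1.0]])
    rotated, R, _, conv = varimax_rotate(L)
    assert conv
    np.testing.assert_allclose(np.abs(R), np.eye(2), atol=1e-6)
    np.testing.assert_allclose(np.abs(rotated), L, atol=1e-6)


def test_varimax_improves_criterion_and_is_orthogonal():
    rng = np.random.default_rng(3)
    L = rng.normal(size=(6, 2))
    rotated, R, _, _ = varimax_rotate(L)
    assert varimax_criterion(rotated) >= varimax_criterion(L) - 1e-12
    np.testing.assert_allclose(R.T @ R, np.eye(2), atol=1e-10)
    # communalities preserved
    np.testing.assert_allclose((rotated ** 2).sum(axis=1),
                               (L ** 2).sum(axis=1), atol=1e-8)


def test_varimax_matches_statsmodels_oracle():
    sm = pytest.importorskip("statsmodels.multivariate.factor_rotation")
    rng = np.random.default_rng(5)
    L = rng.normal(size=(12, 3))
    ours, *_ = varimax_rotate(L, tol=1e-10, max_iter=1000, kaiser=False)
    theirs, _ = sm.rotate_factors(L, "varimax")
    assert varimax_criterion(ours) == pytest.approx(
        varimax_criterion(theirs), rel=1e-6)


def test_varimax_k1_passthrough():
    L = np.array([[0.3], [0.8]])
    rotated, R, iters, conv = varimax_rotate(L)
    np.testing.assert_array_equal(rotated, L)
    assert iters == 0 and conv


# ---------------------------------------------------------------- APCS + MLR

def test_apcs_zero_sample_maps_to_zero(mixture_200):
    table, _, _ = mixture_200
    z = standardize(table.matrix())
    model = rotate_model(fit_pca(z))
    apcs = apcs_scores(z, model)
    # the artificial zero-concentration sample has APCS identically 0
    z0 = -z.means / z.sds
    corr = z.z.T @ z.z / (len(z.z) - 1)
    W = np.linalg.solve(corr, model.rotated_loadings)
    np.testing.assert_allclose(z0 @ W - apcs.zero_scores,
                               np.zeros(model.retained), atol=1e-10)
    # a sample sitting at the mean of every element scores 0, APCS=-zeroscore
    np.testing.assert_allclose(np.zeros(len(z.means)) @ W, 0.0, atol=1e-12)


def test_ols_matches_normal_equations_oracle():
    rng = np.random.default_rng(8)
    n, k, p = 30, 3, 4
    apcs = rng.normal(size=(n, k))
    y = pd.DataFrame(rng.normal(size=(n, p)), columns=list("wxyz"))
    model = ApcsModel(scores=apcs, zero_scores=np.zeros(k), apcs=apcs)
    model = mlr_contributions(model, y)
    X = np.column_stack([np.ones(n), apcs])
    beta = np.linalg.inv(X.T @ X) @ X.T @ y.to_numpy()
    np.testing.assert_allclose(model.intercepts, beta[0], atol=1e-8)
    np.testing.assert_allclose(model.coefficients, beta[1:], atol=1e-8)


def test_ols_permutation_invariant(mixture_200):
    table, _, _ = mixture_200
    _, apcs, _ = fit_receptor_model(table)
    perm = np.random.default_rng(1).permutation(table.n_samples)
    shuffled = ConcentrationTable(
        table.panel, table.values.iloc[perm].reset_index(drop=True),
        table.flags.iloc[perm].reset_index(drop=True))
    _, apcs2, _ = fit_receptor_model(shuffled)
    np.testing.assert_allclose(np.sort(np.abs(apcs2.coefficients), axis=None),
                               np.sort(np.abs(apcs.coefficients), axis=None),
                               rtol=1e-6)


def test_noise_free_perfect_fit_and_unit_mp(noise_free_60):
    table, _, _ = noise_free_60
    _, apcs, mp = fit_receptor_model(table)
    meas = table.matrix().to_numpy()
    resid = meas - apcs.predicted
    r2 = 1 - (resid ** 2).sum(0) / ((meas - meas.mean(0)) ** 2).sum(0)
    assert r2.min() > 1 - 1e-8
    np.testing.assert_allclose(mp["MP"], 1.0, atol=1e-8)


def test_noise_free_orthogonal_sources_recovered_exactly():
    """With disjoint-support profiles the APCS axes align with the true
    sources almost perfectly."""
    panel = ElementPanel(symbols=("A", "B", "C", "D", "E", "F"),
                         native_units={s: "ng/m3" for s in "ABCDEF"})
    profiles = SourceProfileSet(
        np.array([[0.7, 0.3, 0.0, 0.0, 0.0, 0.0],
                  [0.0, 0.0, 0.6, 0.4, 0.0, 0.0],
                  [0.0, 0.0, 0.0, 0.0, 0.5, 0.5]]),
        ("s1", "s2", "s3"), panel)
    cfg = SynthConfig(n_samples={"S1": 500}, mu=(1e4, 1e4, 1e4), cv=0.0, seed=6)
    table, _, truth = simulate_dataset(profiles, cfg)
    _, apcs, _ = fit_receptor_model(table, k=3)
    best = _match(apcs.apcs, truth[["s1", "s2", "s3"]].to_numpy())
    assert min(best) > 0.999


def test_mp_scale_invariance(mixture_200):
    table, _, _ = mixture_200
    _, apcs, mp = fit_receptor_model(table)
    doubled = ConcentrationTable(table.panel, table.values.copy(),
                                 table.flags.copy())
    cols = list(table.panel.symbols)
    doubled.values[cols] = doubled.values[cols] * 2
    _, apcs2, mp2 = fit_receptor_model(doubled)
    np.testing.assert_allclose(mp2["MP"], mp["MP"], rtol=1e-8)


# ------------------------------------------------------------ end-to-end

def test_recovery_on_k3_mixture(mixture_200, preset_profiles):
    """k=3, n=200, 10% noise: three components retained, loading patterns
    and per-sample contributions both recovered, site-mean M/P near one."""
    table, _, truth = mixture_200
    model, apcs, mp = fit_receptor_model(table)
    assert model.retained == 3
    x = table.matrix().to_numpy()
    g = truth[list(preset_profiles.names)].to_numpy()
    implied = np.array([[np.corrcoef(x[:, j], g[:, s])[0, 1]
                         for s in range(3)] for j in range(x.shape[1])])
    assert min(_match(model.rotated_loadings, implied)) > 0.9
    assert min(_match(apcs.apcs, g, absolute=False)) > 0.9
    mean_mp = site_mean_mp(mp)
    assert 0.95 <= float(mean_mp.iloc[0]) <= 1.05
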