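"""Polychoric correlations, minres EFA, parallel analysis, fit and
bifactor indices, local-independence residuals."""

import numpy as np
import pandas as pd
import pytest

from catbank.dimensionality import (bifactor_indices, efa, fit_indices,
                                    parallel_analysis, polychoric_matrix,
                                    polychoric_pair, residual_correlations,
                                    split_half)


def _ordinalize(z, cuts):
    return np.digitize(z, cuts).astype(float)


# --- polychoric ------------------------------------------------------------

def test_polychoric_null_on_dichotomized_normals():
    rng = np.random.default_rng(1)
    z = rng.multivariate_normal([0, 0], np.eye(2), size=20_000)
    r = polychoric_pair((z[:, 0] > 0).astype(int), (z[:, 1] > 0).astype(int))
    assert abs(r) < 0.03


def test_polychoric_recovers_generating_correlation():
    rng = np.random.default_rng(2)
    z = rng.multivariate_normal([0, 0], [[1, 0.5], [0.5, 1]], size=20_000)
    cuts = [-1.2, -0.4, 0.3, 1.0]
    r = polychoric_pair(_ordinalize(z[:, 0], cuts), _ordinalize(z[:, 1], cuts))
    assert r == pytest.approx(0.5, abs=0.04)


def test_polychoric_consistency_bias_shrinks_with_n():
    rng = np.random.default_rng(3)
    biases = {}
    for n in (2_000, 20_000):
        reps = []
        for _ in range(3):
            z = rng.multivariate_normal([0, 0], [[1, 0.6], [0.6, 1]], size=n)
            reps.append(polychoric_pair((z[:, 0] > 0).astype(int),
                                        (z[:, 1] > 0).astype(int)) - 0.6)
        biases[n] = np.abs(np.mean(reps))
    assert biases[20_000] < biases[2_000] + 0.02


def test_polychoric_matrix_diagonal_and_symmetry(study_data):
    _, _, _, responses, _ = study_data
    sub = responses.iloc[:, :5]
    m = polychoric_matrix(sub)
    np.testing.assert_allclose(np.diag(m), 1.0)
    np.testing.assert_allclose(m, m.T)


def test_degenerate_pair_is_flagged_undefined():
    resp = pd.DataFrame({"a": [0.0, 1.0, 0.0, 1.0], "b": [1.0, 1.0, 1.0, 1.0]})
    with pytest.warns(UserWarning, match="undefined"):
        m = polychoric_matrix(resp)
    assert np.isnan(m.loc["a", "b"])


# --- EFA / parallel analysis ----------------------------------------------

def test_one_factor_structure_recovered():
    rng = np.random.default_rng(4)
    n, p, lam = 1000, 21, 0.7
    f = rng.normal(size=(n, 1))
    x = lam * f + np.sqrt(1 - lam**2) * rng.normal(size=(n, p))
    ordinal = pd.DataFrame(_ordinalize(x, [-1.0, -0.2, 0.5, 1.2]))
    assert parallel_analysis(ordinal, n_reps=60, seed=0) == 1
    sol = efa(polychoric_matrix(ordinal), 1, n_obs=n)
    assert np.all(sol.loadings[:, 0] > 0.40)


def test_identity_correlation_retains_no_factors():
    rng = np.random.default_rng(5)
    resp = pd.DataFrame(rng.integers(0, 5, (2000, 8)).astype(float))
    assert parallel_analysis(resp, n_reps=60, seed=1) == 0
    sol = efa(np.eye(8), 1, n_obs=2000)
    np.testing.assert_allclose(sol.eigenvalues, 1.0)


def test_eigenvalues_sum_to_item_count(study_data):
    _, _, _, responses, _ = study_data
    sub = responses.iloc[:, :6]
    sol = efa(polychoric_matrix(sub), 1, n_obs=len(sub))
    assert sol.eigenvalues.sum() == pytest.approx(6.0, abs=1e-8)
    assert np.all(np.diff(sol.eigenvalues) <= 1e-12)


def test_strong_first_factor_reported_from_eigendecomposition():
    """A dominant factor yields a large eigenvalue ratio and a first-factor
    variance share matching the eigen-decomposition."""
    rng = np.random.default_rng(6)
    n, p, lam = 1500, 12, 0.78
    f = rng.normal(size=(n, 1))
    x = lam * f + np.sqrt(1 - lam**2) * rng.normal(size=(n, p))
    ordinal = pd.DataFrame(_ordinalize(x, [-0.8, 0.0, 0.8]))
    sol = efa(polychoric_matrix(ordinal), 1, n_obs=n)
    assert sol.explained_variance_first == pytest.approx(
        sol.eigenvalues[0] / p, abs=1e-12)
    assert sol.explained_variance_first > 0.5
    assert sol.eigenvalue_ratio > 4


def test_one_factor_model_beats_independence_on_one_factor_data():
    rng = np.random.default_rng(7)
    n, p, lam = 800, 10, 0.7
    f = rng.normal(size=(n, 1))
    x = lam * f + np.sqrt(1 - lam**2) * rng.normal(size=(n, p))
    R = np.corrcoef(x.T)
    m1 = efa(R, 1, n_obs=n)
    m0 = efa(R, 0, n_obs=n)
    rmsea0 = np.sqrt(max(m0.chi2_model - m0.df_model, 0) / (m0.df_model * (n - 1)))
    assert m1.fit.rmsea < rmsea0


# --- fit indices -----------------------------------------------------------

def test_exact_fit_limit():
    fi = fit_indices(50.0, 50, 500.0, 60, 400)
    assert fi.rmsea == 0.0
    assert fi.cfi == 1.0
    assert fi.rmsea_ci[0] == 0.0


def test_fit_indices_closed_form_example():
    fi = fit_indices(100.0, 50, 1000.0, 60, 201)
    assert fi.rmsea == pytest.approx(np.sqrt(50 / (50 * 200)), abs=1e-12)
    assert fi.cfi == pytest.approx(1 - 50 / 940, abs=1e-12)
    assert fi.tli == pytest.approx(((1000 / 60) - 2) / ((1000 / 60) - 1), abs=1e-12)


def test_cfi_capped_at_one_when_baseline_no_worse():
    fi = fit_indices(30.0, 50, 40.0, 60, 200)
    assert fi.cfi == 1.0


def test_baseline_without_df_rejected():
    with pytest.raises(ValueError):
        fit_indices(10.0, 5, 20.0, 0, 100)


# --- bifactor indices ------------------------------------------------------

def test_general_only_model_has_full_ecv():
    bi = bifactor_indices(np.full(6, 0.6), np.zeros((6, 0)))
    assert bi.ecv_general == pytest.approx(100.0)


def test_omega_h_closed_form_nine_items():
    bi = bifactor_indices(np.full(9, 0.7), np.zeros((9, 0)))
    assert bi.omega_h == pytest.approx(39.69 / (39.69 + 9 * 0.51), abs=1e-9)


def test_equal_general_and_group_loadings_split_ecv():
    g = np.full(8, 0.5)
    S = np.zeros((8, 2))
    S[:4, 0] = 0.5
    S[4:, 1] = 0.5
    bi = bifactor_indices(g, S)
    assert bi.ecv_general == pytest.approx(50.0)
    assert sum(bi.ecv_groups) == pytest.approx(50.0)
    assert bi.ecv_general + sum(bi.ecv_groups) == pytest.approx(100.0)


def test_item_on_two_group_factors_rejected():
    S = np.zeros((4, 2))
    S[0, 0] = S[0, 1] = 0.4
    with pytest.raises(ValueError):
        bifactor_indices(np.full(4, 0.6), S)


def test_omega_h_not_above_total_omega():
    rng = np.random.default_rng(8)
    g = rng.uniform(0.4, 0.8, 10)
    S = np.zeros((10, 2))
    S[:5, 0] = rng.uniform(0.2, 0.5, 5)
    S[5:, 1] = rng.uniform(0.2, 0.5, 5)
    bi = bifactor_indices(g, S)
    uniq = np.clip(1 - (g**2 + (S**2).sum(axis=1)), 0, None).sum()
    omega_total = (g.sum()**2 + S[:, 0].sum()**2 + S[:, 1].sum()**2) / \
        (g.sum()**2 + S[:, 0].sum()**2 + S[:, 1].sum()**2 + uniq)
    assert bi.omega_h <= omega_total + 1e-12


# --- residual correlations -------------------------------------------------

def test_perfect_model_leaves_no_residual_flags():
    lam = np.full((6, 1), 0.7)
    R = lam @ lam.T
    np.fill_diagonal(R, 1.0)
    sol = efa(R, 1)
    flagged, suggestion = residual_correlations(pd.DataFrame(R), sol)
    assert flagged == []
    assert suggestion is None


def test_locally_dependent_pair_is_flagged():
    rng = np.random.default_rng(9)
    n, p, lam = 2000, 8, 0.6
    f = rng.normal(size=(n, 1))
    x = lam * f + np.sqrt(1 - lam**2) * rng.normal(size=(n, p))
    nuisance = rng.normal(size=n)
    x[:, 2] += 0.9 * nuisance
    x[:, 5] += 0.9 * nuisance
    R = pd.DataFrame(np.corrcoef(x.T),
                     index=[f"v{i}" for i in range(p)],
                     columns=[f"v{i}" for i in range(p)])
    sol = efa(R, 1, n_obs=n)
    flagged, suggestion = residual_correlations(R, sol, threshold=0.20)
    assert any({a, b} == {"v2", "v5"} for a, b, _ in flagged)
    assert suggestion in {"v2", "v5"}


def test_stricter_threshold_flags_subset():
    rng = np.random.default_rng(10)
    x = rng.normal(size=(500, 6))
    R = pd.DataFrame(np.corrcoef(x.T))
    sol = efa(R, 1, n_obs=500)
    loose, _ = residual_correlations(R, sol, threshold=0.20)
    strict, _ = residual_correlations(R, sol, threshold=0.25)
    assert {(a, b) for a, b, _ in strict} <= {(a, b) for a, b, _ in loose}


def test_split_half_partitions_everyone():
    a, b = split_half(458, seed=0)
    assert len(a) + len(b) == 458
    assert len(np.intersect1d(a, b)) == 0
    a2, _ = split_half(458, seed=0)
    np.testing.assert_array_equal(a, a2)
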