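"""GPCM response model, MMLE-EM calibration, scoring and diagnostics."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from catbank.bank import Item, ItemBank
from catbank.gpcm import (collapse_categories, compare_models, eap_score, eap_scores,
                          fit_gpcm, gpcm_prob, infit_mnsq, information_share,
                          inverse_transform_score, item_information,
                          low_discrimination_items, suggest_collapsing,
                          transform_score)
from catbank.gpcm import test_information as total_information
from catbank.synthetic import SimulationConfig, generate_bank, simulate_responses


# --- response law ----------------------------------------------------------

def test_dichotomous_midpoint():
    np.testing.assert_allclose(gpcm_prob(np.array(0.0), 1.0, [0.0]), [0.5, 0.5])


def test_three_category_closed_form():
    e2 = math.e ** 2
    np.testing.assert_allclose(gpcm_prob(np.array(0.0), 2.0, [-1.0, 1.0]),
                               np.array([1.0, e2, 1.0]) / (2 + e2), rtol=1e-12)


@settings(max_examples=200, derandomize=True)
@given(theta=st.floats(-5, 5),
       a=st.floats(0.1, 5),
       b=st.lists(st.floats(-4, 4), min_size=1, max_size=6))
def test_probabilities_sum_to_one(theta, a, b):
    p = gpcm_prob(np.array(theta), a, b)
    assert p.shape == (len(b) + 1,)
    assert np.all(p >= 0)
    assert p.sum() == pytest.approx(1.0, abs=1e-12)


def test_non_finite_inputs_rejected():
    with pytest.raises(ValueError):
        gpcm_prob(np.array(np.nan), 1.0, [0.0])
    with pytest.raises(ValueError):
        gpcm_prob(np.array(0.0), -1.0, [0.0])


# --- calibration -----------------------------------------------------------

def test_parameter_recovery_from_known_bank(clean_cohort):
    _, params, _, responses, _ = clean_cohort
    result = fit_gpcm(responses, n_categories=5)
    assert result.converged
    a_hat = result.bank.discriminations
    assert np.corrcoef(params.a_true, a_hat)[0, 1] >= 0.90
    bias = np.mean([np.abs(bh - bt).mean()
                    for bh, bt in zip(result.bank.thresholds, params.b_true)])
    assert bias <= 0.15


def test_pcm_constraint_gives_identical_slopes(clean_cohort):
    _, _, _, responses, _ = clean_cohort
    sub = responses.iloc[:300, :6]
    result = fit_gpcm(sub, n_categories=5, equal_slopes=True)
    a = result.bank.discriminations
    np.testing.assert_allclose(a, a[0])
    assert result.model == "PCM"


def test_marginal_likelihood_nondecreasing_over_em(monkeypatch, clean_cohort):
    """EM ascent: the marginal log-likelihood never decreases across cycles."""
    from catbank import gpcm as mod

    _, _, _, responses, _ = clean_cohort
    sub = responses.iloc[:400, :8]
    seen = []
    orig = mod._posterior

    def spy(X, log_probs, log_w):
        post, ll = orig(X, log_probs, log_w)
        seen.append(ll)
        return post, ll

    monkeypatch.setattr(mod, "_posterior", spy)
    fit_gpcm(sub, n_categories=5, max_cycles=60, compute_infit=False)
    diffs = np.diff(seen[:-1])  # last call re-evaluates the final iterate
    assert np.all(diffs > -1e-6)


def test_aic_bic_identities(clean_cohort):
    _, _, _, responses, _ = clean_cohort
    sub = responses.iloc[:300, :5]
    res = fit_gpcm(sub, n_categories=5, compute_infit=False)
    assert res.aic == pytest.approx(-2 * res.log_likelihood + 2 * res.n_params)
    assert res.bic == pytest.approx(-2 * res.log_likelihood + res.n_params * np.log(300))


def test_recovery_improves_with_sample_size():
    errs = {}
    for n in (500, 4000):
        cfg = SimulationConfig(n_persons=n, n_items=8, n_categories=4, seed=101)
        params, _ = generate_bank(cfg)
        resp, _ = simulate_responses(params, cfg)
        res = fit_gpcm(resp, n_categories=4, compute_infit=False)
        errs[n] = np.abs(res.bank.discriminations - params.a_true).mean()
    assert errs[4000] < errs[500]


def test_unobserved_category_auto_collapsed():
    rng = np.random.default_rng(0)
    x = rng.integers(0, 2, (300, 2)).astype(float) * 2  # categories {0, 2} only
    with pytest.warns(UserWarning, match="collapsed"):
        res = fit_gpcm(pd.DataFrame(x), n_categories=3, compute_infit=False)
    assert all(it.n_categories == 2 for it in res.bank)
    assert res.bank[0].collapse_map == [0, 0, 1] or res.bank[0].collapse_map == [0, 1, 1]


# --- model comparison ------------------------------------------------------

def test_identical_fits_give_null_lrt(clean_cohort):
    _, _, _, responses, _ = clean_cohort
    sub = responses.iloc[:200, :4]
    res = fit_gpcm(sub, n_categories=5, equal_slopes=True, compute_infit=False)
    cmp = compare_models(res, res)
    assert cmp.chi2 == 0.0
    assert cmp.p_value == 1.0


def test_lrt_degrees_of_freedom_is_items_minus_one(clean_cohort):
    _, _, _, responses, _ = clean_cohort
    sub = responses.iloc[:200, :]
    pcm = fit_gpcm(sub, n_categories=5, equal_slopes=True, compute_infit=False)
    gpcm = fit_gpcm(sub, n_categories=5, compute_infit=False)
    assert compare_models(pcm, gpcm).df == 20


def test_comparing_different_item_sets_errors(clean_cohort):
    _, _, _, responses, _ = clean_cohort
    a = fit_gpcm(responses.iloc[:150, :4], n_categories=5, compute_infit=False)
    b = fit_gpcm(responses.iloc[:150, 1:5], n_categories=5, compute_infit=False)
    with pytest.raises(ValueError):
        compare_models(a, b)


# --- infit -----------------------------------------------------------------

def test_infit_near_one_for_well_fitting_model():
    cfg = SimulationConfig(n_persons=2000, n_items=21, n_categories=5, seed=55,
                           discrimination_logmean=0.15, discrimination_logsd=0.35)
    params, bank = generate_bank(cfg)
    resp, _ = simulate_responses(params, cfg)
    theta, _ = eap_scores(resp, bank)
    infit = infit_mnsq(resp, bank, theta)
    vals = np.array(list(infit.values()))
    assert np.all(vals > 0.8) and np.all(vals < 1.2)


def test_permuted_item_shows_misfit(clean_cohort):
    _, _, bank, responses, _ = clean_cohort
    rng = np.random.default_rng(7)
    broken = responses.copy()
    col = broken.columns[0]
    broken[col] = rng.permutation(broken[col].to_numpy())
    theta, _ = eap_scores(broken, bank)
    infit = infit_mnsq(broken, bank, theta)
    assert infit[bank.ids[0]] > 1.3


def test_model_expected_responses_overfit(clean_cohort):
    _, _, bank, responses, _ = clean_cohort
    theta, _ = eap_scores(responses, bank)
    rounded = np.column_stack([
        np.round(gpcm_prob(theta, it.discrimination, it.thresholds)
                 @ np.arange(it.n_categories))
        for it in bank])
    infit = infit_mnsq(rounded, bank, theta)
    assert all(v < 1.0 for v in infit.values())


def test_low_discrimination_flagging():
    bank = ItemBank([Item("weak", 3, 0.3, [-1.0, 1.0]),
                     Item("strong", 3, 1.5, [-1.0, 1.0])])
    assert low_discrimination_items(bank) == ["weak"]


# --- information -----------------------------------------------------------

def test_dichotomous_information_closed_form(dichotomous_bank):
    assert item_information(np.array(0.0), dichotomous_bank[0]) == pytest.approx(0.25)


def test_information_share_full_range_is_one(symmetric_bank):
    assert information_share(symmetric_bank, -6, 6) == pytest.approx(1.0)


def test_doubling_slope_quadruples_peak_information():
    i1 = Item("a", 2, 1.0, [0.0])
    i2 = Item("b", 2, 2.0, [0.0])
    r = item_information(np.array(0.0), i2) / item_information(np.array(0.0), i1)
    assert r == pytest.approx(4.0)


def test_test_information_is_sum_of_items(symmetric_bank):
    grid = np.linspace(-3, 3, 41)
    total = total_information(symmetric_bank, grid)
    parts = sum(item_information(grid, it) for it in symmetric_bank)
    np.testing.assert_allclose(total, parts)


def test_information_share_rejects_bad_interval(symmetric_bank):
    with pytest.raises(ValueError):
        information_share(symmetric_bank, 1.0, -1.0)


# --- EAP scoring -----------------------------------------------------------

def test_all_missing_pattern_returns_prior(symmetric_bank):
    est = eap_score([np.nan] * 5, symmetric_bank)
    assert est.theta == pytest.approx(0.0, abs=1e-10)
    assert est.sem == pytest.approx(1.0, abs=0.01)
    assert est.n_items_used == 0
    assert est.score_0_100 == pytest.approx(50.0)


def test_single_item_eap_matches_dense_grid_oracle(dichotomous_bank):
    """Brute-force posterior integration on 10,001 points: the posterior mean
    of N(0,1) x logistic(theta) after a positive response is 0.41324."""
    est = eap_score([1], dichotomous_bank, grid=np.linspace(-8, 8, 10_001))
    assert est.theta == pytest.approx(0.41324, abs=0.01)


def test_eap_matches_brute_force_for_random_patterns(symmetric_bank):
    rng = np.random.default_rng(42)
    dense = np.linspace(-8, 8, 10_001)
    from scipy import stats

    for _ in range(20):
        pattern = np.array([rng.integers(0, it.n_categories) if rng.random() > 0.2
                            else np.nan for it in symmetric_bank], dtype=float)
        est = eap_score(pattern, symmetric_bank, grid=dense)
        # independent direct integration
        logpost = stats.norm.logpdf(dense)
        for i, it in enumerate(symmetric_bank):
            if np.isfinite(pattern[i]):
                logpost = logpost + np.log(
                    gpcm_prob(dense, it.discrimination, it.thresholds)[:, int(pattern[i])])
        w = np.exp(logpost - logpost.max())
        w /= w.sum()
        assert est.theta == pytest.approx(float(w @ dense), abs=1e-4)


def test_mirror_symmetry_flips_sign(symmetric_bank):
    rng = np.random.default_rng(5)
    pattern = np.array([rng.integers(0, it.n_categories) for it in symmetric_bank],
                       dtype=float)
    mirrored = np.array([it.n_categories - 1 - pattern[i]
                         for i, it in enumerate(symmetric_bank)])
    t1 = eap_score(pattern, symmetric_bank).theta
    t2 = eap_score(mirrored, symmetric_bank).theta
    assert t1 == pytest.approx(-t2, abs=1e-8)


def test_out_of_range_response_names_item(symmetric_bank):
    bad = [0.0, 9.0, 0.0, 0.0, 0.0]
    with pytest.raises(ValueError, match="s2"):
        eap_score(bad, symmetric_bank)


# --- transform -------------------------------------------------------------

@pytest.mark.parametrize("theta, score", [(0.0, 50.0), (-4.0, 0.0), (4.0, 100.0),
                                          (-5.0, 0.0), (6.0, 100.0)])
def test_score_transform_map(theta, score):
    assert transform_score(theta) == pytest.approx(score)


def test_transform_invertible_inside_clip_range():
    thetas = np.linspace(-3.9, 3.9, 11)
    np.testing.assert_allclose(inverse_transform_score(transform_score(thetas)), thetas,
                               atol=1e-12)


# --- category collapsing ---------------------------------------------------

def test_disordered_steps_flag_never_modal_category():
    bank = ItemBank([Item("rev", 3, 1.5, [1.0, -1.0])])  # reversed steps
    proposals = suggest_collapsing(bank)
    assert "rev" in proposals
    assert len(set(proposals["rev"])) == 2


def test_well_separated_steps_need_no_collapsing(symmetric_bank):
    assert suggest_collapsing(symmetric_bank) == {}


def test_collapse_map_validation():
    resp = pd.DataFrame({"x": [0.0, 1.0, 2.0]})
    with pytest.raises(ValueError):
        collapse_categories(resp, "x", [0, 0, 0])       # < 2 categories
    with pytest.raises(ValueError):
        collapse_categories(resp, "x", [1, 0, 2])       # order broken


def test_collapsing_never_modal_category_improves_aic():
    """Refit after merging a never-modal category: AIC delta (final - initial)
    is negative, the direction the recoding procedure requires."""
    rng = np.random.default_rng(77)
    n = 800
    theta = rng.normal(size=n)
    item = Item("x", 4, 1.4, [1.2, -1.2, 0.4])          # middle category starved
    probs = gpcm_prob(theta, item.discrimination, item.thresholds)
    u = rng.random(n)
    x = (probs.cumsum(axis=1) < u[:, None]).sum(axis=1).astype(float)
    other = Item("y", 4, 1.0, [-1.0, 0.0, 1.0])
    po = gpcm_prob(theta, other.discrimination, other.thresholds)
    y = (po.cumsum(axis=1) < rng.random(n)[:, None]).sum(axis=1).astype(float)
    resp = pd.DataFrame({"x": x, "y": y})

    initial = fit_gpcm(resp, n_categories=4, compute_infit=False)
    proposals = suggest_collapsing(initial.bank, resp)
    assert "x" in proposals
    collapsed = collapse_categories(resp, "x", proposals["x"])
    final = fit_gpcm(collapsed, compute_infit=False)
    assert final.aic - initial.aic < 0
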