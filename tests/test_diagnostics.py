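import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import tickabund as ta
from tickabund.diagnostics import (FitCriteria, compare_models, compute_dic,
                                   compute_pit, compute_waic, fit_criteria,
                                   pit_from_result,
                                   posterior_predictive_monthly, zero_profile)


# ---------------------------------------------------------------------------
# information criteria against hand-computed brute force
# ---------------------------------------------------------------------------

def _waic_brute(ll):
    """Independent WAIC: plain python/math over the definition."""
    S, n = ll.shape
    lppd = 0.0
    p = 0.0
    for i in range(n):
        col = [ll[s, i] for s in range(S)]
        lppd += math.log(sum(math.exp(v) for v in col) / S)
        mean = sum(col) / S
        p += sum((v - mean) ** 2 for v in col) / (S - 1)
    return -2.0 * (lppd - p), lppd, p


def test_waic_matches_brute_force_two_draws():
    ll = np.array([[-1.0, -2.5, -0.3],
                   [-1.7, -2.0, -0.9]])
    w_brute, lppd, p = _waic_brute(ll)
    crit = compute_waic(ll)
    assert crit.waic == pytest.approx(w_brute, abs=1e-10)
    assert crit.lppd == pytest.approx(lppd, abs=1e-10)
    assert crit.p_waic == pytest.approx(p, abs=1e-10)
    assert crit.n_obs == 3


def test_dic_matches_brute_force_two_draws():
    ll = np.array([[-1.0, -2.5, -0.3],
                   [-1.7, -2.0, -0.9]])
    ll_hat = np.array([-1.2, -2.2, -0.5])
    dbar = (-2 * (-1.0 - 2.5 - 0.3) + -2 * (-1.7 - 2.0 - 0.9)) / 2
    dhat = -2 * (-1.2 - 2.2 - 0.5)
    p_dic = dbar - dhat
    crit = compute_dic(ll, ll_hat)
    assert crit.dic == pytest.approx(dhat + 2 * p_dic, abs=1e-10)
    assert crit.p_dic == pytest.approx(p_dic, abs=1e-10)
    assert crit.dbar == pytest.approx(dbar, abs=1e-10)


def test_waic_additive_and_permutation_invariant():
    rng = np.random.default_rng(0)
    ll = -np.abs(rng.normal(size=(40, 25)))
    full = compute_waic(ll)
    parts = compute_waic(ll[:, :10]).waic + compute_waic(ll[:, 10:]).waic
    assert full.waic == pytest.approx(parts, abs=1e-10)
    perm = rng.permutation(25)
    assert compute_waic(ll[:, perm]).waic == pytest.approx(full.waic,
                                                           abs=1e-10)


def test_criteria_errors():
    with pytest.raises(ValueError):
        compute_waic(np.zeros(5))
    with pytest.raises(ValueError):
        compute_waic(np.zeros((1, 5)))
    with pytest.raises(ValueError):
        compute_dic(np.zeros((3, 5)), np.zeros(4))
    with pytest.raises(ValueError):
        FitCriteria(n_obs=3).merged(FitCriteria(n_obs=4))


def test_merged_combines_halves():
    a = compute_waic(-np.ones((4, 6)) - np.arange(6))
    b = compute_dic(-np.ones((4, 6)) - np.arange(6), -np.ones(6))
    m = a.merged(b)
    assert m.waic == a.waic and m.dic == b.dic
    assert m.p_waic == a.p_waic and m.p_dic == b.p_dic


def test_fit_criteria_on_fit(nb_fit_small):
    crit = fit_criteria(nb_fit_small)
    assert crit.waic == pytest.approx(compute_waic(nb_fit_small.loglik).waic)
    assert crit.dic == pytest.approx(
        compute_dic(nb_fit_small.loglik, nb_fit_small.loglik_plugin).dic)
    assert crit.n_obs == nb_fit_small.loglik.shape[1]
    assert crit.p_waic > 0 and crit.p_dic > 0


def test_comparison_report_printed_deltas():
    """Structured comparison reproduces the deltas implied by a published
    joint-model comparison: DIC 11251.57 vs 11242.28 and WAIC 11280.74 vs
    11271.14 give differences of 9.29 and 9.60 favouring the ZINB."""
    nb = FitCriteria(dic=11251.57, waic=11280.74, n_obs=10)
    zinb = FitCriteria(dic=11242.28, waic=11271.14, n_obs=10)
    rep = compare_models(nb, zinb)
    assert rep.delta_dic == pytest.approx(9.29)
    assert rep.delta_waic == pytest.approx(9.60)
    frame = rep.to_frame()
    assert frame.loc["DIC", "NB"] == 11251.57
    assert frame.loc["WAIC", "delta (NB - ZINB)"] == pytest.approx(9.60)
    assert "No model is auto-selected" in rep.note
    with pytest.raises(ValueError):
        compare_models(nb, FitCriteria(n_obs=9))


# ---------------------------------------------------------------------------
# randomized PIT
# ---------------------------------------------------------------------------

def test_compute_pit_degenerate_point_mass():
    """If the predictive puts all mass on the observed value, F(y-1) = 0 and
    F(y) = 1, so the randomised PIT reduces to the uniform noise itself."""
    y = np.arange(50)
    F = lambda v: (v >= y).astype(float)
    res = compute_pit(y, F, seed=123)
    v = np.random.default_rng(123).random(y.shape)
    assert res.pit_values == pytest.approx(v)


def test_compute_pit_calibrated_nb():
    """Counts drawn from the same NB used as the predictive give uniform PIT."""
    rng = np.random.default_rng(5)
    mu, phi = 4.0, 0.8
    y = rng.negative_binomial(phi, phi / (phi + mu), size=2000)
    res = compute_pit(y, lambda v: ta.nb_cdf(v, mu, phi), seed=0)
    assert res.ks_p > 0.01
    assert res.hist_counts.sum() == 2000
    assert len(res.hist_edges) == 21
    # and a badly miscalibrated predictive fails
    bad = compute_pit(y, lambda v: ta.nb_cdf(v, 30.0, 5.0), seed=0)
    assert bad.ks_p < 1e-6


def test_compute_pit_direction_overprediction():
    """When the predictive mean far exceeds the data, PIT mass piles up near
    zero (the observations sit in the lower predictive tail)."""
    rng = np.random.default_rng(9)
    y = rng.poisson(1.0, size=500)
    res = compute_pit(y, lambda v: ta.nb_cdf(v, 50.0, 1e6), seed=0)
    assert res.pit_values.mean() < 0.2
    assert res.ks_p < 1e-6


def test_compute_pit_validates_cdf():
    with pytest.raises(ValueError):
        compute_pit(np.array([1, 2]), lambda v: np.full(v.shape, 2.0))


def test_pit_from_result(nb_fit_small):
    res = pit_from_result(nb_fit_small, seed=0)
    n_ll = nb_fit_small.loglik.shape[1]
    assert res.pit_values.shape == (n_ll,)
    assert ((res.pit_values >= 0) & (res.pit_values <= 1)).all()
    # a model fitted to its own data should not be wildly miscalibrated
    assert res.ks_statistic < 0.1


# ---------------------------------------------------------------------------
# posterior predictive checks and zero profiles
# ---------------------------------------------------------------------------

def _point_mass_result(panel, latents, draws=200, seed=0):
    """A fake PosteriorResult whose draws sit exactly at the generator truth,
    for testing predictive machinery independently of the fitting code."""
    from tickabund.design import build_design
    from tickabund.inference import ModelSpec, PosteriorResult

    truth = ta.default_truth()
    design = build_design(panel)
    S = draws
    ones = np.ones(S)
    years = list(latents["years"])
    gamma = np.array([latents["gamma_year"][years.index(y)]
                      for y in design.years])
    locs = list(latents["locations"])
    u = latents["u_location"][[locs.index(l) for l in design.locations]]
    derived = {
        "alpha": np.tile(truth.alpha, (S, 1)),
        "beta_sin": np.tile(truth.beta_sin, (S, 1)),
        "beta_cos": np.tile(truth.beta_cos, (S, 1)),
        "beta_grass": ones * truth.beta_grass,
        "beta_woods": ones * truth.beta_woods,
        "beta_lagL": ones * truth.beta_lagL,
        "beta_lagN": ones * truth.beta_lagN,
        "phi": np.tile(truth.phi, (S, 1)),
        "tau_year": ones * truth.tau_year,
        "gamma": np.tile(gamma, (S, 1)),
        "u": np.tile(u, (S, 1, 1)),
    }
    return PosteriorResult(
        spec=ModelSpec(family="nb", draws=S, seed=seed), design=design,
        param_names=[], hyper_map=np.zeros(1), x_map=np.zeros(1),
        derived=derived, loglik=np.zeros((S, 1)),
        ll_stage=np.zeros(1, int), ll_row=np.zeros(1, int),
        loglik_plugin=np.zeros(1), convergence=pd.DataFrame(),
        converged=True, optimizer_message="point mass")


def test_posterior_predictive_monthly_under_truth(small_panel):
    """With the posterior a point mass at the generating parameters, the
    observed monthly means should fall inside the 95% predictive bands for
    nearly every month."""
    panel, latents = small_panel
    res = _point_mass_result(panel, latents, draws=400)
    tab = posterior_predictive_monthly(res, panel, seed=1)
    assert set(tab["stage"]) == set(ta.STAGES)
    for stage in ta.STAGES:
        sub = tab[tab["stage"] == stage]
        assert len(sub) == 12
        inside = ((sub["observed_mean"] >= sub["lo"])
                  & (sub["observed_mean"] <= sub["hi"])).sum()
        assert inside >= 11, f"{stage}: only {inside}/12 months covered"
    assert (tab["lo"] <= tab["hi"]).all()
    assert (tab["n"] >= 1).all()


def test_point_mass_pit_is_calibrated(small_panel):
    """True-parameter predictive passes the PIT KS test on its own data."""
    panel, latents = small_panel
    res = _point_mass_result(panel, latents, draws=50)
    pit = pit_from_result(res, seed=0)
    assert pit.ks_p > 0.01


def test_zero_profile_counting():
    panel = pd.DataFrame({
        "location": ["A"] * 4, "habitat": ["edge", "edge", "grass", "grass"],
        "year": [2010] * 4, "month": [1, 7, 1, 7], "n_visits": [1] * 4,
        "larvae": [0, 5, 0, 0], "nymphs": [1, 0, 0, 2],
        "adults": [0, 0, 0, 0],
        "lag_log_larvae": np.nan, "lag_log_nymphs": np.nan,
    })
    prof = zero_profile(panel)
    assert prof.by_habitat.loc["edge", "larvae"] == 0.5
    assert prof.by_habitat.loc["grass", "larvae"] == 1.0
    assert prof.by_month.loc[1, "nymphs"] == 0.5
    assert prof.by_habitat.loc["edge", "adults"] == 1.0
    assert prof.by_habitat_month["larvae"].loc["edge", 7] == 0.0
    assert prof.group_sizes["n"].sum() == 4
    with pytest.raises(ValueError):
        zero_profile(panel.iloc[:0])


def test_zero_profile_winter_gradient(small_panel):
    panel, _ = small_panel
    prof = zero_profile(panel)
    assert prof.by_month.loc[1, "larvae"] > prof.by_month.loc[8, "larvae"]
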