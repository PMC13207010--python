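import math
import warnings

import numpy as np
import pandas as pd
import pytest

import tickabund as ta
from tickabund.design import build_design
from tickabund.inference import (ConvergenceWarning, ModelSpec,
                                 PosteriorResult, _Model, summarize)
from tickabund.priors import PriorConfig, build_prior_set
from conftest import small_config


def _nb_brute(y, mu, phi):
    return (math.lgamma(y + phi) - math.lgamma(phi) - math.lgamma(y + 1)
            + phi * math.log(phi / (phi + mu))
            + y * math.log(mu / (phi + mu)))


def _toy_panel():
    rows = []
    counts = [(12, 3, 1), (0, 0, 2), (7, 1, 0), (30, 5, 2), (2, 0, 0)]
    for k, (l, n, a) in enumerate(counts):
        rows.append(dict(location="A", habitat="edge", year=2010,
                         month=4 + k, n_visits=1, larvae=l, nymphs=n,
                         adults=a, lag_log_larvae=np.nan,
                         lag_log_nymphs=np.nan))
    return ta.attach_lags(pd.DataFrame(rows))


def test_joint_loglik_matches_brute_force():
    """The model's stage log-likelihood at x = 0 (all mu = 1) equals an
    independently computed sum over the included (row, stage) pairs."""
    panel = _toy_panel()
    design = build_design(panel)
    model = _Model(design, ModelSpec(family="nb"))
    phi = np.array([0.5, 1.0, 2.0])
    x = np.zeros(model.dim_x)
    P, _ = model.x_prior_precision(5.0, np.linalg.cholesky(np.eye(3)))
    f, _, _ = model.joint_x_parts(x, phi, None, P)
    expected = 0.0
    y = design.counts
    for j in range(3):
        for i in np.flatnonzero(design.stage_mask(j)):
            expected += _nb_brute(int(y[i, j]), 1.0, phi[j])
    assert f == pytest.approx(expected, abs=1e-10)   # quad term is 0 at x = 0


def test_joint_loglik_nonzero_eta():
    """Same check at a non-trivial latent field (intercepts only)."""
    panel = _toy_panel()
    design = build_design(panel)
    model = _Model(design, ModelSpec(family="nb"))
    phi = np.array([1.0, 1.0, 1.0])
    x = np.zeros(model.dim_x)
    alpha = (1.5, -0.3, 0.2)
    x[:3] = alpha
    P, _ = model.x_prior_precision(5.0, np.linalg.cholesky(np.eye(3)))
    f, _, _ = model.joint_x_parts(x, phi, None, P)
    expected = -0.5 * x @ (P @ x)
    for j in range(3):
        for i in np.flatnonzero(design.stage_mask(j)):
            expected += _nb_brute(int(design.counts[i, j]),
                                  math.exp(alpha[j]), phi[j])
    assert f == pytest.approx(expected, abs=1e-10)


def test_linear_predictor_examples():
    params = dict(alpha=(0.0, 0.0, 0.0),
                  beta_sin=(-5.285, -0.430, 1.154),
                  beta_cos=(-2.483, -3.624, -5.093),
                  beta_grass=-1.298, beta_woods=0.496,
                  beta_lagL=0.212, beta_lagN=0.107)
    # June: sin = 0, cos = -1 -> eta_A = 5.093 at an edge site with no lags
    row = dict(sin_term=0.0, cos_term=-1.0, grass_ind=0.0, woods_ind=0.0,
               lag_log_larvae=0.0, lag_log_nymphs=0.0)
    eta = ta.linear_predictor(row, params)
    assert eta[2] == pytest.approx(5.093)
    assert eta[1] == pytest.approx(3.624)
    # woods adds beta_woods to all stages; lagL feeds only the nymph equation
    row2 = dict(row, woods_ind=1.0, lag_log_larvae=2.0)
    eta2 = ta.linear_predictor(row2, params)
    assert eta2 - eta == pytest.approx([0.496, 0.496 + 0.212 * 2.0, 0.496])
    # year and location effects shift directly
    row3 = dict(row, gamma=0.3, u=(0.1, -0.2, 0.0))
    assert ta.linear_predictor(row3, params) - eta == pytest.approx(
        [0.4, 0.1, 0.3])
    with pytest.raises(ValueError):
        ta.linear_predictor(dict(row, lag_log_larvae=np.nan), params)


@pytest.mark.parametrize("kwargs", [
    dict(family="poisson"),
    dict(year_effect="ar1"),
    dict(draws=1),
    dict(chains=0),
    dict(ci_level=1.0),
])
def test_modelspec_validation(kwargs):
    with pytest.raises(ValueError):
        ModelSpec(**kwargs)


def test_prior_sets():
    s1, s2, s3 = (build_prior_set(n) for n in ("set1", "set2", "set3"))
    # all sets share the fixed-effect and zero-inflation priors
    for s in (s2, s3):
        assert s.fixed_effect_sd == s1.fixed_effect_sd
        assert (s.pi_a, s.pi_b) == (s1.pi_a, s1.pi_b)
        assert (s.phi_shape, s.phi_rate) == (s1.phi_shape, s1.phi_rate)
    assert (s2.tau_year_shape, s2.tau_year_rate) == (0.01, 0.01)
    assert s2.sigma_df == 10.0
    assert (s3.tau_year_shape, s3.tau_year_rate) == (1.0, 0.01)
    assert s3.sigma_scale == pytest.approx(0.5 * np.eye(3))
    assert build_prior_set(s2) is s2
    with pytest.raises(ValueError):
        build_prior_set("set4")
    with pytest.raises(ValueError):
        PriorConfig(sigma_df=2.0)
    with pytest.raises(ValueError):
        PriorConfig(tau_year_rate=0.0)


def _fake_result(derived, spec):
    s = next(iter(derived.values())).shape[0]
    return PosteriorResult(
        spec=spec, design=None, param_names=[], hyper_map=np.zeros(1),
        x_map=np.zeros(1), derived=derived, loglik=np.zeros((s, 1)),
        ll_stage=np.zeros(1, int), ll_row=np.zeros(1, int),
        loglik_plugin=np.zeros(1), convergence=pd.DataFrame(),
        converged=True, optimizer_message="ok")


def test_summarize_hand_built():
    s = 3
    col = np.array([1.0, 2.0, 3.0])
    derived = {
        "alpha": np.column_stack([col, col * 0, col * 0]),
        "beta_sin": np.zeros((s, 3)), "beta_cos": np.zeros((s, 3)),
        "beta_grass": col, "beta_woods": np.zeros(s),
        "beta_lagL": np.zeros(s), "beta_lagN": np.zeros(s),
        "phi": np.ones((s, 3)), "tau_year": np.full(s, 4.0),
        "tau_loc3d": np.ones((s, 3)),
        "rho": np.column_stack([np.full(s, 0.5), np.zeros(s), np.zeros(s)]),
    }
    res = _fake_result(derived, ModelSpec(family="nb", ci_level=0.5))
    tab = summarize(res)
    assert tab.loc["alpha_L", "mean"] == pytest.approx(2.0)
    assert tab.loc["alpha_L", "sd"] == pytest.approx(1.0)        # ddof = 1
    # equal-tailed 50% interval of {1,2,3}: the 25% and 75% quantiles
    assert tab.loc["alpha_L", "ci_low"] == pytest.approx(1.5)
    assert tab.loc["alpha_L", "ci_high"] == pytest.approx(2.5)
    assert tab.loc["rho_L:N", "mean"] == pytest.approx(0.5)
    assert "pi_L" not in tab.index
    # reporting order: harmonics, habitat/lag, intercepts, sizes, precisions
    names = list(tab.index)
    assert names[:2] == ["beta_sin_L", "beta_cos_L"]
    assert names.index("beta_grass") < names.index("alpha_L") \
        < names.index("phi_L") < names.index("tau_year") \
        < names.index("tau_loc3d_L") < names.index("rho_L:N")


def test_fit_smoke(nb_fit_small, small_panel):
    panel, _ = small_panel
    res = nb_fit_small
    assert res.converged
    n_draws = res.n_draws
    assert n_draws == 300
    d = res.derived
    assert d["alpha"].shape == (n_draws, 3)
    assert (d["phi"] > 0).all() and (d["tau_year"] > 0).all()
    # year effects sum to zero in every draw
    assert np.abs(d["gamma"].sum(axis=1)).max() < 1e-8
    assert np.abs(d["rho"]).max() <= 1.0
    # Sigma draws are SPD and consistent with the reported precisions
    for s in (0, n_draws // 2, n_draws - 1):
        Sig = d["Sigma_loc"][s]
        assert np.linalg.eigvalsh(Sig).min() > 0
        assert d["tau_loc3d"][s] == pytest.approx(1.0 / np.diag(Sig))
        sd = np.sqrt(np.diag(Sig))
        expect = [Sig[a, b] / (sd[a] * sd[b])
                  for a, b in ((0, 1), (0, 2), (1, 2))]
        assert d["rho"][s] == pytest.approx(expect)
    # the NB family has no zero-inflation parameter
    assert "pi" not in d
    # log-likelihood matrix covers larvae rows plus lag-complete rows
    n_lagged = int((~panel["lag_log_larvae"].isna()).sum())
    assert res.loglik.shape == (n_draws, len(panel) + 2 * n_lagged)
    assert np.isfinite(res.loglik).all()
    tab = res.summarize()
    assert (tab["ci_low"] <= tab["mean"]).all()
    assert (tab["mean"] <= tab["ci_high"]).all()
    # convergence metrics are reported for every scalar parameter
    assert set(res.convergence.index) == set(tab.index)


def test_location_relabeling_invariance(nb_fit_small, small_panel):
    """Renaming locations (which permutes their internal encoding order)
    leaves the fixed-effect posteriors unchanged up to Monte Carlo error."""
    panel, _ = small_panel
    locs = sorted(panel["location"].unique())
    mapping = {old: f"Z{len(locs) - k:02d}" for k, old in enumerate(locs)}
    relabeled = panel.assign(location=panel["location"].map(mapping))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rr = ta.fit(relabeled, ModelSpec(family="nb", draws=300, seed=1))
    base = nb_fit_small.summarize()
    other = rr.summarize()
    for name in ("alpha_L", "alpha_N", "alpha_A", "beta_sin_L", "beta_cos_L",
                 "beta_grass", "beta_woods", "beta_lagL", "beta_lagN"):
        diff = abs(base.loc[name, "mean"] - other.loc[name, "mean"])
        assert diff < 0.25 * base.loc[name, "sd"], \
            f"{name}: |d-mean| {diff:.4f} vs sd {base.loc[name, 'sd']:.4f}"


def test_fit_reproducible(small_panel):
    panel, _ = small_panel
    spec = ModelSpec(family="nb", draws=100, seed=7)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        r1 = ta.fit(panel, spec)
        r2 = ta.fit(panel, ModelSpec(family="nb", draws=100, seed=7))
    for key in ("alpha", "phi", "tau_year", "gamma"):
        assert np.array_equal(r1.derived[key], r2.derived[key])
    assert np.array_equal(r1.loglik, r2.loglik)


def test_zinb_pinned_at_zero_matches_nb(small_panel):
    """ZINB with all pi pinned to 0 is the NB model: posteriors of every
    scalar parameter agree in distribution across independent draw seeds."""
    from scipy.stats import ks_2samp
    panel, _ = small_panel
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rn = ta.fit(panel, ModelSpec(family="nb", draws=300, seed=3))
        rz = ta.fit(panel, ModelSpec(family="zinb", pin_pi=0.0,
                                     draws=300, seed=11))
    assert np.allclose(rz.derived["pi"], 0.0)
    from tickabund.inference import _scalar_draws
    dn, dz = _scalar_draws(rn), _scalar_draws(rz)
    for name in ("alpha_L", "beta_sin_L", "beta_cos_A", "phi_L",
                 "beta_grass", "tau_year"):
        stat = ks_2samp(dn[name], dz[name]).statistic
        assert stat < 0.1, f"{name}: KS distance {stat:.3f}"


def test_all_zero_stage_warns():
    panel, _ = ta.simulate_panel(small_config(seed=9))
    panel = panel.assign(adults=0)
    with pytest.warns(ConvergenceWarning, match="all adults counts are zero"):
        with warnings.catch_warnings():
            warnings.simplefilter("always")
            ta.fit(panel, ModelSpec(family="nb", draws=50, seed=0))


def test_fit_empty_panel_errors():
    with pytest.raises(ValueError):
        ta.fit(pd.DataFrame(), ModelSpec())


def test_artifact_round_trip(tmp_path, nb_fit_small, small_panel):
    panel, _ = small_panel
    path = tmp_path / "posterior.npz"
    ta.save_posterior(nb_fit_small, path)
    assert path.stat().st_size < 10 * 1024 * 1024
    back = ta.load_posterior(path, panel)
    assert back.spec == nb_fit_small.spec
    for key, arr in nb_fit_small.derived.items():
        assert np.array_equal(back.derived[key], arr), key
    assert np.array_equal(back.loglik, nb_fit_small.loglik)
    assert np.array_equal(back.loglik_plugin, nb_fit_small.loglik_plugin)
    assert back.converged == nb_fit_small.converged
    assert back.weight_ess == pytest.approx(nb_fit_small.weight_ess)
    # a panel that does not match the stored fit is rejected
    with pytest.raises(ValueError):
        ta.load_posterior(path, panel.iloc[:10])
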