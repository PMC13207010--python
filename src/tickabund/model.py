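"""Scikit-learn style estimator wrapping the Bayesian multistage count model.

:class:`MultistageAbundanceModel` follows the sklearn estimator contract
(constructor stores hyperparameters verbatim, ``fit`` learns and sets
trailing-underscore attributes, ``get_params``/``set_params``/``clone``
work), so it composes with sklearn tooling.  ``X`` is a monthly panel
DataFrame in the :mod:`tickabund.panel` layout; the three stage counts inside
the panel are the response, so ``y`` is always ``None``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .design import build_design
from .inference import ModelSpec, fit as _fit
from .panel import PANEL_COLUMNS, STAGES, attach_lags

__all__ = ["MultistageAbundanceModel"]


class MultistageAbundanceModel(BaseEstimator):
    """Joint NB/ZINB model of larval, nymphal and adult monthly counts.

    Parameters
    ----------
    family : {"nb", "zinb"}
        Observation layer: negative binomial, or zero-inflated NB with a
        stage-specific structural-zero probability.
    prior_set : {"set1", "set2", "set3"} or PriorConfig
        Prior configuration; see :mod:`tickabund.priors`.
    year_effect : {"rw1", "iid"}
        Structure of the shared, sum-to-zero year random effect.
    include_offset : bool
        Add ``log(n_visits)`` to the linear predictor.
    draws, chains, seed, ci_level
        Posterior sampling settings (independent Laplace draws; ``chains``
        only partitions draws for the convergence metrics).
    pin_pi : float or None
        Fix all zero-inflation probabilities (ZINB only); mainly for checks.

    Attributes
    ----------
    result_ : PosteriorResult
        Draws, log-likelihood matrix and convergence metrics.
    summary_ : pandas.DataFrame
        Posterior mean / SD / CI per parameter.
    design_ : DesignMatrices
    """

    def __init__(self, family: str = "nb", prior_set="set1",
                 year_effect: str = "rw1", include_offset: bool = False,
                 draws: int = 1000, chains: int = 4, seed: int = 0,
                 ci_level: float = 0.95, pin_pi=None):
        self.family = family
        self.prior_set = prior_set
        self.year_effect = year_effect
        self.include_offset = include_offset
        self.draws = draws
        self.chains = chains
        self.seed = seed
        self.ci_level = ci_level
        self.pin_pi = pin_pi

    def _spec(self) -> ModelSpec:
        return ModelSpec(family=self.family, prior_set=self.prior_set,
                         year_effect=self.year_effect,
                         include_offset=self.include_offset,
                         draws=self.draws, chains=self.chains,
                         seed=self.seed, ci_level=self.ci_level,
                         pin_pi=self.pin_pi)

    @staticmethod
    def _as_panel(X) -> pd.DataFrame:
        if not isinstance(X, pd.DataFrame):
            raise TypeError("X must be a panel DataFrame")
        missing = [c for c in PANEL_COLUMNS[:7] if c not in X.columns]
        if missing:
            raise ValueError(f"panel is missing columns {missing}")
        if "lag_log_larvae" not in X.columns or X["lag_log_larvae"].isna().all():
            X = attach_lags(X.copy())
        return X

    def fit(self, X, y=None):
        """Fit the joint model to a monthly panel (y is unused)."""
        panel = self._as_panel(X)
        self.result_ = _fit(panel, self._spec())
        self.summary_ = self.result_.summarize()
        self.design_ = self.result_.design
        self.n_features_in_ = len(PANEL_COLUMNS)
        return self

    def predict(self, X) -> np.ndarray:
        """Posterior-mean expected counts, shape (n_obs, 3) in stage order.

        Uses the posterior means of the fixed effects, the year effect for
        years seen in training (zero otherwise) and the location effect for
        known locations (zero otherwise).  Entries whose required lag is
        missing are NaN.
        """
        check_is_fitted(self, "result_")
        panel = self._as_panel(X)
        design = build_design(panel)
        d = self.result_.derived
        alpha = d["alpha"].mean(axis=0)
        bs = d["beta_sin"].mean(axis=0)
        bc = d["beta_cos"].mean(axis=0)
        bg = float(d["beta_grass"].mean())
        bw = float(d["beta_woods"].mean())
        blagL = float(d["beta_lagL"].mean())
        blagN = float(d["beta_lagN"].mean())
        gamma = dict(zip(self.design_.years, d["gamma"].mean(axis=0)))
        u_mean = d["u"].mean(axis=0)
        u = dict(zip(self.design_.locations, u_mean))
        pi = d["pi"].mean(axis=0) if "pi" in d else np.zeros(3)

        out = np.full((design.n_obs, 3), np.nan)
        gam = np.array([gamma.get(y_, 0.0) for y_ in design.years])[design.year_index]
        uu = np.stack([u.get(loc, np.zeros(3))
                       for loc in design.locations])[design.location_index]
        for j in range(3):
            eta = (alpha[j] + bs[j] * design.sin_term + bc[j] * design.cos_term
                   + bg * design.grass_ind + bw * design.woods_ind
                   + gam + uu[:, j])
            if j == 1:
                eta = eta + blagL * design.lag_log_larvae
            elif j == 2:
                eta = eta + blagN * design.lag_log_nymphs
            if self.include_offset:
                eta = eta + design.log_visits
            out[:, j] = (1.0 - pi[j]) * np.exp(eta)
        return out

    def score(self, X, y=None) -> float:
        """Mean posterior log predictive density per observation-stage."""
        check_is_fitted(self, "result_")
        from scipy.special import logsumexp
        ll = self.result_.loglik
        return float(np.mean(logsumexp(ll, axis=0) - np.log(ll.shape[0])))
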