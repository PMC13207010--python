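"""Model assessment: WAIC, DIC, randomised PIT, posterior predictive
monthly curves, zero-proportion profiles, and NB-vs-ZINB comparison.

WAIC is computed pointwise from the per-draw, per-observation log-likelihood
matrix (``lppd - p_waic`` with the variance-based complexity penalty); DIC
uses the conditional deviance with the plug-in at the posterior means of the
per-observation linear predictors and hyperparameters.  For discrete counts
the probability integral transform is randomised,
``u = F(y-1) + v * (F(y) - F(y-1))`` with ``v ~ U(0,1)``, which is exactly
uniform when the predictive distribution is the true one.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats

from .inference import PosteriorResult, stage_eta_draws
from .panel import HABITATS, STAGES

__all__ = ["FitCriteria", "PitResult", "compute_waic", "compute_dic",
           "fit_criteria", "compute_pit", "pit_from_result",
           "posterior_predictive_monthly", "zero_profile", "ZeroProfile",
           "compare_models", "ComparisonReport"]


@dataclass
class FitCriteria:
    """Information criteria; ``nan`` fields were not requested."""

    dic: float = np.nan
    waic: float = np.nan
    p_dic: float = np.nan
    p_waic: float = np.nan
    lppd: float = np.nan
    dbar: float = np.nan
    dhat: float = np.nan
    n_obs: int = 0

    def merged(self, other: "FitCriteria") -> "FitCriteria":
        """Combine DIC-only and WAIC-only halves computed on the same data."""
        if self.n_obs != other.n_obs:
            raise ValueError("criteria computed on different observation sets")
        pick = lambda a, b: b if np.isnan(a) else a
        return FitCriteria(*(pick(getattr(self, f), getattr(other, f))
                             for f in ("dic", "waic", "p_dic", "p_waic",
                                       "lppd", "dbar", "dhat")),
                           n_obs=self.n_obs)


def compute_waic(loglik_matrix: np.ndarray) -> FitCriteria:
    """WAIC from a (draws x observations) log-likelihood matrix.

    ``lppd = sum_i log mean_s exp(ll_si)`` (log-mean-exp, stable),
    ``p_waic = sum_i var_s(ll_si)`` (sample variance), and
    ``waic = -2 (lppd - p_waic)``.
    """
    ll = np.asarray(loglik_matrix, float)
    if ll.ndim != 2:
        raise ValueError("loglik_matrix must be draws x observations")
    S = ll.shape[0]
    if S < 2:
        raise ValueError("WAIC needs at least 2 draws for the variance term")
    lppd = float(np.sum(special.logsumexp(ll, axis=0) - np.log(S)))
    p_waic = float(np.sum(np.var(ll, axis=0, ddof=1)))
    return FitCriteria(waic=-2.0 * (lppd - p_waic), p_waic=p_waic, lppd=lppd,
                       n_obs=ll.shape[1])


def compute_dic(loglik_matrix: np.ndarray,
                loglik_at_posterior_mean: np.ndarray) -> FitCriteria:
    """Conditional DIC: ``Dbar = E[-2 sum_i ll]``, ``Dhat`` at the plug-in.

    The plug-in log-likelihood must be evaluated at the posterior means of
    the per-observation linear predictors and the hyperparameters.
    """
    ll = np.asarray(loglik_matrix, float)
    ll_hat = np.asarray(loglik_at_posterior_mean, float)
    if ll.ndim != 2 or ll_hat.ndim != 1 or ll.shape[1] != ll_hat.shape[0]:
        raise ValueError("loglik matrix and plug-in vector are misaligned")
    dbar = float(np.mean(-2.0 * ll.sum(axis=1)))
    dhat = float(-2.0 * ll_hat.sum())
    p_dic = dbar - dhat
    return FitCriteria(dic=dhat + 2.0 * p_dic, p_dic=p_dic, dbar=dbar,
                       dhat=dhat, n_obs=ll.shape[1])


def fit_criteria(result: PosteriorResult) -> FitCriteria:
    """Both criteria for a fitted model."""
    return compute_dic(result.loglik, result.loglik_plugin).merged(
        compute_waic(result.loglik))


@dataclass
class PitResult:
    pit_values: np.ndarray
    ks_statistic: float
    ks_p: float
    hist_counts: np.ndarray = field(default=None)
    hist_edges: np.ndarray = field(default=None)


def compute_pit(y, predictive_cdf, seed: int = 0, bins: int = 20) -> PitResult:
    """Randomised PIT for discrete data plus a KS test against U(0,1).

    ``predictive_cdf`` is a vectorised callable ``F`` with ``F(y)`` the
    per-observation predictive cdf evaluated at the integers (``F(-1) = 0``).
    """
    y = np.asarray(y)
    F_y = np.asarray(predictive_cdf(y), float)
    F_ym1 = np.asarray(predictive_cdf(y - 1), float)
    if np.any((F_y < -1e-9) | (F_y > 1 + 1e-9)) or np.any(F_ym1 > F_y + 1e-9):
        raise ValueError("predictive cdf values outside [0, 1] or decreasing")
    rng = np.random.default_rng(seed)
    v = rng.random(y.shape)
    u = np.clip(F_ym1 + v * (F_y - F_ym1), 0.0, 1.0)
    ks = stats.kstest(u, "uniform")
    counts, edges = np.histogram(u, bins=bins, range=(0.0, 1.0))
    return PitResult(pit_values=u, ks_statistic=float(ks.statistic),
                     ks_p=float(ks.pvalue), hist_counts=counts,
                     hist_edges=edges)


def _posterior_predictive_cdf(result: PosteriorResult):
    """Vectorised predictive cdf mixing over posterior draws, per obs-stage."""
    from .likelihoods import nb_cdf

    mus, phis, pis = [], [], []
    for j in range(3):
        eta = stage_eta_draws(result, j)              # (S, n_j)
        mus.append(np.exp(eta))
        phis.append(np.broadcast_to(result.derived["phi"][:, j:j + 1],
                                    eta.shape))
        if "pi" in result.derived:
            pis.append(np.broadcast_to(result.derived["pi"][:, j:j + 1],
                                       eta.shape))
    mu = np.concatenate(mus, axis=1)
    phi = np.concatenate(phis, axis=1)
    pi = np.concatenate(pis, axis=1) if pis else None

    def F(yvals):
        yv = np.asarray(yvals)[None, :]
        base = nb_cdf(yv, mu, phi)
        if pi is not None:
            base = np.where(yv >= 0, pi + (1.0 - pi) * base, 0.0)
        return base.mean(axis=0)

    return F


def pit_from_result(result: PosteriorResult, seed: int = 0) -> PitResult:
    """Randomised PIT of a fitted model against its own training counts."""
    y = np.concatenate([result.design.counts[result.design.stage_mask(j), j]
                        for j in range(3)])
    return compute_pit(y, _posterior_predictive_cdf(result), seed=seed)


def posterior_predictive_monthly(result: PosteriorResult, panel: pd.DataFrame,
                                 seed: int = 0, level: float = 0.95,
                                 max_draws: int = 400) -> pd.DataFrame:
    """Observed vs posterior-predictive monthly mean counts per stage.

    For each retained draw, counts are resampled from the fitted observation
    model and averaged within calendar month; the predictive band is the
    equal-tailed ``level`` interval of those monthly means across draws.
    """
    rng = np.random.default_rng(seed)
    lo_q = 0.5 * (1.0 - level)
    rows = []
    for j, stage in enumerate(STAGES):
        mask = result.design.stage_mask(j)
        months = result.design.month[mask]
        y_obs = result.design.counts[mask, j]
        eta = stage_eta_draws(result, j)
        if eta.shape[0] > max_draws:
            eta = eta[:max_draws]
        mu = np.exp(eta)
        phi = result.derived["phi"][:eta.shape[0], j:j + 1]
        lam = rng.gamma(np.broadcast_to(phi, mu.shape), mu / phi)
        y_rep = rng.poisson(lam)
        if "pi" in result.derived:
            pi = result.derived["pi"][:eta.shape[0], j:j + 1]
            y_rep = np.where(rng.random(mu.shape) < pi, 0, y_rep)
        for m in range(1, 13):
            sel = months == m
            if not sel.any():
                continue
            rep_means = y_rep[:, sel].mean(axis=1)
            rows.append((stage, m, float(y_obs[sel].mean()),
                         float(rep_means.mean()),
                         float(np.quantile(rep_means, lo_q)),
                         float(np.quantile(rep_means, 1.0 - lo_q)),
                         int(sel.sum())))
    return pd.DataFrame(rows, columns=["stage", "month", "observed_mean",
                                       "predicted_mean", "lo", "hi", "n"])


@dataclass
class ZeroProfile:
    """Zero-count proportions by habitat, month, and habitat x month."""

    by_habitat: pd.DataFrame          # index habitat, columns stages
    by_month: pd.DataFrame            # index month 1-12
    by_habitat_month: dict            # stage -> habitat x month table
    group_sizes: pd.DataFrame


def zero_profile(panel: pd.DataFrame) -> ZeroProfile:
    """Proportion of zero counts across habitat and season, per life stage."""
    if len(panel) == 0:
        raise ValueError("zero_profile: empty panel")
    iszero = pd.DataFrame({s: panel[s] == 0 for s in STAGES})
    iszero["habitat"] = panel["habitat"].to_numpy()
    iszero["month"] = panel["month"].to_numpy()
    by_habitat = iszero.groupby("habitat", observed=True)[list(STAGES)].mean()
    by_month = iszero.groupby("month")[list(STAGES)].mean()
    by_hm = {
        stage: iszero.pivot_table(values=stage, index="habitat",
                                  columns="month", aggfunc="mean",
                                  observed=True)
        for stage in STAGES
    }
    sizes = (iszero.groupby(["habitat", "month"], observed=True)
             .size().rename("n").reset_index())
    return ZeroProfile(by_habitat=by_habitat, by_month=by_month,
                       by_habitat_month=by_hm, group_sizes=sizes)


@dataclass
class ComparisonReport:
    """NB-vs-ZINB criteria differences with a calibration caveat."""

    delta_dic: float                 # NB - ZINB; positive favours ZINB on DIC
    delta_waic: float
    criteria_nb: FitCriteria
    criteria_zinb: FitCriteria
    note: str

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"NB": [self.criteria_nb.dic, self.criteria_nb.waic],
             "ZINB": [self.criteria_zinb.dic, self.criteria_zinb.waic],
             "delta (NB - ZINB)": [self.delta_dic, self.delta_waic]},
            index=["DIC", "WAIC"])


_COMPARISON_NOTE = (
    "Information criteria are one input to model choice; predictive "
    "calibration (randomised PIT) and the ecological interpretability of the "
    "estimated cross-stage dependencies should be weighed alongside small "
    "criteria differences. No model is auto-selected."
)


def compare_models(criteria_nb: FitCriteria,
                   criteria_zinb: FitCriteria) -> ComparisonReport:
    """Structured NB-vs-ZINB comparison on a common observation set."""
    if criteria_nb.n_obs != criteria_zinb.n_obs:
        raise ValueError("criteria were computed on different observation sets")
    return ComparisonReport(
        delta_dic=criteria_nb.dic - criteria_zinb.dic,
        delta_waic=criteria_nb.waic - criteria_zinb.waic,
        criteria_nb=criteria_nb, criteria_zinb=criteria_zinb,
        note=_COMPARISON_NOTE)
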