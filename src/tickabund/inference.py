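"""Joint Bayesian NB / ZINB hierarchical models for multistage count panels.

Model
-----
For life stage ``j`` (larvae L, nymphs N, adults A) at location ``i``,
habitat ``h`` and month ``t`` the count is NB (or ZINB) with log mean

``eta_L = alpha_L + b_sin,L sin(2 pi M/12) + b_cos,L cos(2 pi M/12)
         + b_Grass G + b_Woods W + gamma_year + u_{i,L}``

and the nymph / adult equations add the stage-progression terms
``b_lagL log(L[t-1]+1)`` and ``b_lagN log(N[t-1]+1)`` respectively.  The
harmonic coefficients and intercepts are stage specific; the habitat and lag
coefficients are shared across stages.  ``gamma`` is a year random effect
common to all stages (first-order random walk or iid, precision ``tau_year``,
constrained to sum to zero) and ``u_i`` is one trivariate normal effect per
location with a shared 3x3 covariance ``Sigma_loc``, reported as per-stage
precisions ``tau_loc3d_j = 1/Sigma_jj`` and cross-stage correlations
``rho_jk``.

Inference: nested Laplace approximation
---------------------------------------
The parameters split into a latent Gaussian field ``x`` (intercepts,
regression coefficients, year effects, location effects — everything with a
Gaussian prior given the hyperparameters) and hyperparameters ``theta``
(log NB sizes, log year precision, the Cholesky factor of ``Sigma_loc``,
logit zero-inflation probabilities).  For fixed ``theta`` the conditional
posterior of ``x`` is maximised by damped Newton iteration (the linear
predictors are linear in ``x``, so the Hessian is ``A' W A`` plus the prior
precision) and replaced by a Gaussian at the mode; the Laplace-approximated
log marginal posterior

``lp(theta) = lp_joint(x_hat, theta) + dim(x)/2 log 2 pi - 1/2 log|H_x|``

is then maximised over ``theta``.  Integrating the latent field out of the
hyperparameter objective is essential: a joint mode would collapse the year
effect (the usual hierarchical funnel).  Hyperparameter uncertainty comes
from a finite-difference Hessian of ``lp(theta)``; posterior draws are
generated hierarchically (draw ``theta``, refresh the conditional mode with a
Newton step, draw ``x`` from the conditional Gaussian), so draws are
independent and the split-R-hat / effective-sample-size contract holds by
construction (both are still computed and reported).  Accuracy rests on the
Gaussian approximations, which the parameter-recovery tests exercise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg, optimize, special

from .design import DesignMatrices, build_design
from .likelihoods import (ETA_CLIP, _log_zero_mix, _nb_log_pmf_raw,
                          nb_ll_curv, zinb_ll_curv)
from .panel import STAGES, attach_lags
from .priors import PriorConfig, build_prior_set

__all__ = ["ModelSpec", "PosteriorResult", "fit", "summarize",
           "linear_predictor", "nb_log_pmf", "zinb_log_pmf",
           "build_prior_set", "PriorConfig", "ConvergenceWarning"]

# re-exported for a single import surface
from .likelihoods import nb_log_pmf, zinb_log_pmf  # noqa: E402,F401

_STAGE_SUFFIX = ("L", "N", "A")
_RHO_PAIRS = ((0, 1), (0, 2), (1, 2))
_RHO_NAMES = ("rho_L:N", "rho_L:A", "rho_N:A")
_LOG2PI = np.log(2.0 * np.pi)
_N_COEF = 13          # 3 alpha + 6 harmonics + 2 habitat + 2 lag


class ConvergenceWarning(UserWarning):
    """Optimiser or posterior-quality contract not met."""


@dataclass
class ModelSpec:
    """Everything needed to (re)run a fit."""

    family: str = "nb"               # "nb" | "zinb"
    prior_set: object = "set1"       # set name or PriorConfig
    year_effect: str = "rw1"         # "rw1" | "iid"
    include_offset: bool = False     # add log(n_visits) to eta
    draws: int = 1000
    chains: int = 4                  # pseudo-chains for convergence metrics
    seed: int = 0
    ci_level: float = 0.95
    pin_pi: float | None = None      # fix all pi_j (ZINB); None = estimate

    def __post_init__(self):
        if self.family not in ("nb", "zinb"):
            raise ValueError(f"unknown family {self.family!r}")
        if self.year_effect not in ("rw1", "iid"):
            raise ValueError(f"unknown year_effect {self.year_effect!r}")
        if self.draws <= 1 or self.chains < 1:
            raise ValueError("draws and chains must be positive (draws > 1)")
        if not 0.0 < self.ci_level < 1.0:
            raise ValueError("ci_level must lie in (0, 1)")

    @property
    def prior(self) -> PriorConfig:
        return build_prior_set(self.prior_set)


def linear_predictor(row, params):
    """Evaluate the three stage linear predictors for one design row.

    ``row`` maps ``sin_term, cos_term, grass_ind, woods_ind, lag_log_larvae,
    lag_log_nymphs`` (and optionally ``gamma``, a scalar year effect, and
    ``u``, a length-3 location effect); ``params`` maps ``alpha, beta_sin,
    beta_cos`` (length-3 each) and the scalars ``beta_grass, beta_woods,
    beta_lagL, beta_lagN``.  Returns ``eta`` of shape (3,).  Raises if a
    required lag is missing (NaN).
    """
    alpha = np.asarray(params["alpha"], float)
    bs = np.asarray(params["beta_sin"], float)
    bc = np.asarray(params["beta_cos"], float)
    gamma = float(row.get("gamma", 0.0))
    u = np.asarray(row.get("u", np.zeros(3)), float)
    base = (alpha + bs * row["sin_term"] + bc * row["cos_term"]
            + params["beta_grass"] * row["grass_ind"]
            + params["beta_woods"] * row["woods_ind"] + gamma + u)
    lags = np.array([0.0, row["lag_log_larvae"], row["lag_log_nymphs"]], float)
    coef = np.array([0.0, params["beta_lagL"], params["beta_lagN"]], float)
    if np.isnan(lags[1]) or np.isnan(lags[2]):
        raise ValueError("required lag predictor is missing for this row")
    return base + coef * lags


def _chol_from_params(c):
    """Lower-triangular L with log-parameterised diagonal; Sigma = L L'."""
    L = np.zeros((3, 3))
    L[0, 0] = np.exp(c[0])
    L[1, 0] = c[1]
    L[1, 1] = np.exp(c[2])
    L[2, 0] = c[3]
    L[2, 1] = c[4]
    L[2, 2] = np.exp(c[5])
    return L


class _Model:
    """Design, priors and the nested-Laplace objective for one panel."""

    def __init__(self, design: DesignMatrices, spec: ModelSpec):
        self.design = design
        self.spec = spec
        self.prior = spec.prior
        self.estimate_pi = spec.family == "zinb" and spec.pin_pi is None

        Ny, Nl = design.n_years, design.n_locations
        self.n_gamma = Ny - 1                     # sum-to-zero free coords
        self.dim_x = _N_COEF + self.n_gamma + 3 * Nl
        self.dim_h = 10 + (3 if self.estimate_pi else 0)
        self._gamma_sl = slice(_N_COEF, _N_COEF + self.n_gamma)
        self._u_off = _N_COEF + self.n_gamma

        # hyperparameter layout: log_phi(3), log_tau(1), chol(6), [zeta(3)]
        self.h_log_phi = slice(0, 3)
        self.h_log_tau = 3
        self.h_chol = slice(4, 10)
        self.h_zeta = slice(10, 13) if self.estimate_pi else None

        # per-stage response and design matrix A_j (n_j x dim_x)
        self.stage = []
        for j in range(3):
            mask = design.stage_mask(j)
            n_j = int(mask.sum())
            A = np.zeros((n_j, self.dim_x))
            A[:, j] = 1.0                                   # alpha_j
            A[:, 3 + j] = design.sin_term[mask]
            A[:, 6 + j] = design.cos_term[mask]
            A[:, 9] = design.grass_ind[mask]
            A[:, 10] = design.woods_ind[mask]
            if j == 1:
                A[:, 11] = design.lag_log_larvae[mask]
            elif j == 2:
                A[:, 12] = design.lag_log_nymphs[mask]
            yr = design.year_index[mask]
            last = Ny - 1
            for k in range(self.n_gamma):
                A[yr == k, _N_COEF + k] = 1.0
            A[yr == last, self._gamma_sl] = -1.0
            loc = design.location_index[mask]
            A[np.arange(n_j), self._u_off + 3 * loc + j] = 1.0
            offset = design.log_visits[mask] if spec.include_offset else 0.0
            self.stage.append(dict(
                y=design.counts[mask, j].astype(float), A=A, offset=offset,
                rows=np.flatnonzero(mask)))

        # year-effect prior structure on the free coordinates
        if self.n_gamma > 0:
            M = np.zeros((Ny, self.n_gamma))
            M[:self.n_gamma, :] = np.eye(self.n_gamma)
            M[-1, :] = -1.0
            if spec.year_effect == "rw1":
                D = np.diff(np.eye(Ny), axis=0)
                K = D.T @ D
            else:
                K = np.eye(Ny)
            self._K_free = M.T @ K @ M
            sign, self._logdet_K_free = np.linalg.slogdet(self._K_free)
        else:
            self._K_free = np.zeros((0, 0))
            self._logdet_K_free = 0.0

    # -- hyperparameter transforms -------------------------------------------
    def unpack_hyper(self, h):
        phi = np.exp(h[self.h_log_phi])
        tau = np.exp(h[self.h_log_tau])
        L = _chol_from_params(h[self.h_chol])
        if self.estimate_pi:
            pi = special.expit(h[self.h_zeta])
        elif self.spec.family == "zinb":
            pi = np.full(3, float(self.spec.pin_pi))
        else:
            pi = None
        return phi, tau, L, pi

    def initial_hyper(self):
        h = np.zeros(self.dim_h)
        h[self.h_log_tau] = np.log(5.0)
        if self.estimate_pi:
            h[self.h_zeta] = special.logit(0.2)
        return h

    def initial_x(self):
        x = np.zeros(self.dim_x)
        for j in range(3):
            x[j] = np.log(self.stage[j]["y"].mean() + 0.5)
        return x

    # -- priors ---------------------------------------------------------------
    def x_prior_precision(self, tau, L):
        """Block-diagonal prior precision of the latent field and its logdet."""
        P = np.zeros((self.dim_x, self.dim_x))
        sd2 = self.prior.fixed_effect_sd ** 2
        P[np.arange(_N_COEF), np.arange(_N_COEF)] = 1.0 / sd2
        logdet = -_N_COEF * np.log(sd2)
        if self.n_gamma > 0:
            P[self._gamma_sl, self._gamma_sl] = tau * self._K_free
            logdet += self.n_gamma * np.log(tau) + self._logdet_K_free
        Sigma_inv = linalg.cho_solve((L, True), np.eye(3))
        logdet_Sigma = 2.0 * np.sum(np.log(np.diag(L)))
        Nl = self.design.n_locations
        for i in range(Nl):
            sl = slice(self._u_off + 3 * i, self._u_off + 3 * i + 3)
            P[sl, sl] = Sigma_inv
        logdet -= Nl * logdet_Sigma
        return P, logdet

    def hyper_log_prior(self, h):
        pr = self.prior
        phi, tau, L, pi = self.unpack_hyper(h)
        lp = 0.0
        a, b = pr.phi_shape, pr.phi_rate
        lp += np.sum(a * np.log(b) - special.gammaln(a)
                     + a * h[self.h_log_phi] - b * phi)
        a, b = pr.tau_year_shape, pr.tau_year_rate
        lp += (a * np.log(b) - special.gammaln(a)
               + a * h[self.h_log_tau] - b * tau)
        # Sigma ~ inverse-Wishart(df, scale), plus chol-coordinate Jacobian
        nu, S0 = pr.sigma_df, pr.sigma_scale
        logdet_Sigma = 2.0 * np.sum(np.log(np.diag(L)))
        Sigma_inv = linalg.cho_solve((L, True), np.eye(3))
        _, logdet_S0 = np.linalg.slogdet(S0)
        lp += (0.5 * nu * logdet_S0 - 1.5 * nu * np.log(2.0)
               - special.multigammaln(0.5 * nu, 3)
               - 0.5 * (nu + 4.0) * logdet_Sigma
               - 0.5 * np.trace(S0 @ Sigma_inv))
        lp += 3.0 * np.log(2.0) + np.array([4.0, 3.0, 2.0]) @ np.log(np.diag(L))
        if self.estimate_pi:
            a, b = pr.pi_a, pr.pi_b
            lp += np.sum(a * np.log(pi) + b * np.log1p(-pi)
                         - special.betaln(a, b))
        return lp

    # -- conditional posterior of the latent field ----------------------------
    def _stage_terms(self, j, x, phi, pi):
        d = self.stage[j]
        eta = d["A"] @ x + d["offset"]
        if pi is None:
            return nb_ll_curv(d["y"], eta, phi[j])
        return zinb_ll_curv(d["y"], eta, phi[j], pi[j])

    def joint_x_parts(self, x, phi, pi, P):
        """(log-lik, grad, Hessian contribution) of the data terms plus the
        Gaussian prior quadratic form for the latent field."""
        ll = 0.0
        g = -P @ x
        H = P.copy()
        for j in range(3):
            d = self.stage[j]
            llj, s, w = self._stage_terms(j, x, phi, pi)
            ll += llj.sum()
            g += d["A"].T @ s
            w = np.maximum(w, 1e-10)
            H += d["A"].T @ (w[:, None] * d["A"])
        quad = -0.5 * x @ (P @ x)
        return ll + quad, g, H

    def inner_solve(self, h, x0, tol=1e-11, max_iter=60):
        """Newton maximisation of the conditional posterior of x given h.

        Returns ``(x_hat, H_chol, lp_cond)`` where ``lp_cond`` is the joint
        log posterior terms that depend on x (likelihood + Gaussian prior
        quadratic), and ``H_chol`` the Cholesky factor of the negative
        Hessian at the mode.  Convergence uses the Newton decrement
        ``g' H^-1 g / 2``, which is scale invariant and robust to the
        floating-point noise floor of the objective.
        """
        phi, tau, L, pi = self.unpack_hyper(h)
        P, _ = self.x_prior_precision(tau, L)
        x = x0.copy()
        f, g, H = self.joint_x_parts(x, phi, pi, P)
        cF = None
        eye = np.eye(self.dim_x)
        for _ in range(max_iter):
            if not np.all(np.isfinite(H)):
                raise linalg.LinAlgError("non-finite Hessian")
            jitter = 1e-8 * max(1.0, np.abs(np.diag(H)).max())
            for _try in range(8):
                try:
                    cF = linalg.cho_factor(H + (jitter if _try else 0.0) * eye,
                                           lower=True)
                    break
                except linalg.LinAlgError:
                    jitter *= 100.0
            else:
                raise linalg.LinAlgError("Hessian not positive definite")
            dx = linalg.cho_solve(cF, g)
            if 0.5 * g @ dx < tol * (1.0 + abs(f)):
                break
            step = 1.0
            improved = False
            for _ls in range(30):
                x_new = x + step * dx
                f_new, g_new, H_new = self.joint_x_parts(x_new, phi, pi, P)
                if np.isfinite(f_new) and f_new >= f - 1e-12:
                    improved = True
                    break
                step *= 0.5
            if not improved:
                break
            x, f, g, H = x_new, f_new, g_new, H_new
        if cF is None:
            cF = linalg.cho_factor(H + 1e-10 * np.eye(self.dim_x), lower=True)
        return x, cF, f

    def neg_log_marginal(self, h, x_cache):
        """Negative Laplace-approximated log marginal posterior of h."""
        phi, tau, L, pi = self.unpack_hyper(h)
        _, logdet_P = self.x_prior_precision(tau, L)
        try:
            x_hat, cF, lp_cond = self.inner_solve(h, x_cache["x"])
        except (linalg.LinAlgError, FloatingPointError):
            # numerically hopeless hyperparameter region: steer the
            # optimizer away without aborting the whole fit
            return 1e10 + 1e8 * float(np.sum(np.square(h)))
        x_cache["x"] = x_hat
        logdet_H = 2.0 * np.sum(np.log(np.diag(cF[0])))
        lp = (lp_cond + 0.5 * logdet_P - 0.5 * self.dim_x * _LOG2PI
              + self.hyper_log_prior(h)
              + 0.5 * self.dim_x * _LOG2PI - 0.5 * logdet_H)
        return -lp


# ---------------------------------------------------------------------------
# results container
# ---------------------------------------------------------------------------

@dataclass
class PosteriorResult:
    """Posterior draws, derived natural-scale quantities and diagnostics."""

    spec: ModelSpec
    design: DesignMatrices
    param_names: list
    hyper_map: np.ndarray            # marginal-posterior mode of theta
    x_map: np.ndarray                # conditional mode of the latent field
    derived: dict                    # natural-scale draw arrays by name
    loglik: np.ndarray               # (S, n_ll) per-draw, per-obs x stage
    ll_stage: np.ndarray             # stage index of each loglik column
    ll_row: np.ndarray               # panel row index of each loglik column
    loglik_plugin: np.ndarray        # (n_ll,) at posterior-mean eta and hypers
    convergence: pd.DataFrame
    converged: bool
    optimizer_message: str
    weight_ess: float = np.nan       # importance-resampling effective size

    @property
    def n_draws(self) -> int:
        return self.derived["alpha"].shape[0]

    def summarize(self) -> pd.DataFrame:
        return summarize(self)


def _scalar_draws(result: PosteriorResult) -> dict:
    """Flatten derived draws into named scalar series in reporting order."""
    d = result.derived
    out = {}
    for j, s in enumerate(_STAGE_SUFFIX):
        out[f"beta_sin_{s}"] = d["beta_sin"][:, j]
        out[f"beta_cos_{s}"] = d["beta_cos"][:, j]
    out["beta_grass"] = d["beta_grass"]
    out["beta_woods"] = d["beta_woods"]
    out["beta_lagL"] = d["beta_lagL"]
    out["beta_lagN"] = d["beta_lagN"]
    for j, s in enumerate(_STAGE_SUFFIX):
        out[f"alpha_{s}"] = d["alpha"][:, j]
    for j, s in enumerate(_STAGE_SUFFIX):
        out[f"phi_{s}"] = d["phi"][:, j]
    out["tau_year"] = d["tau_year"]
    for j, s in enumerate(_STAGE_SUFFIX):
        out[f"tau_loc3d_{s}"] = d["tau_loc3d"][:, j]
    for k, name in enumerate(_RHO_NAMES):
        out[name] = d["rho"][:, k]
    if "pi" in d:
        for j, s in enumerate(_STAGE_SUFFIX):
            out[f"pi_{s}"] = d["pi"][:, j]
    return out


def summarize(result: PosteriorResult) -> pd.DataFrame:
    """Posterior mean, sample SD and equal-tailed CI for every parameter.

    Row order mirrors the conventional reporting layout: stage-specific
    harmonic coefficients, shared habitat and lag coefficients, intercepts,
    NB sizes, the year-effect precision, per-stage location precisions,
    cross-stage correlations, then zero-inflation probabilities (ZINB).
    """
    lo_q = 0.5 * (1.0 - result.spec.ci_level)
    rows = []
    for name, x in _scalar_draws(result).items():
        lo, hi = np.quantile(x, [lo_q, 1.0 - lo_q])
        rows.append((name, float(np.mean(x)), float(np.std(x, ddof=1)),
                     float(lo), float(hi)))
    return pd.DataFrame(rows, columns=["parameter", "mean", "sd",
                                       "ci_low", "ci_high"]).set_index("parameter")


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def fit(panel: pd.DataFrame, spec: ModelSpec | None = None,
        **spec_kwargs) -> PosteriorResult:
    """Fit the joint multistage model to a lag-attached monthly panel.

    Returns a :class:`PosteriorResult` with natural-scale posterior draws,
    reporting-table summaries via :func:`summarize`, and the per-observation
    log-likelihood matrix needed for WAIC / DIC / PIT.
    """
    if spec is None:
        spec = ModelSpec(**spec_kwargs)
    if len(panel) == 0:
        raise ValueError("fit: empty panel")
    if panel[["lag_log_larvae", "lag_log_nymphs"]].isna().all().all() \
            and len(panel) > 1:
        panel = attach_lags(panel)
    design = build_design(panel)
    for j, stage_name in enumerate(STAGES):
        if (design.counts[:, j] == 0).all():
            warnings.warn(
                f"all {stage_name} counts are zero; the NB mean for this "
                "stage is unidentified (a ZINB structural-zero component may "
                "be more appropriate)", ConvergenceWarning, stacklevel=2)

    model = _Model(design, spec)
    x_cache = {"x": model.initial_x()}
    h0 = model.initial_hyper()
    res = optimize.minimize(
        model.neg_log_marginal, h0, args=(x_cache,), method="L-BFGS-B",
        options=dict(maxiter=500, eps=1e-5, ftol=1e-12, gtol=1e-6))
    converged = bool(res.success)
    if not converged:
        warnings.warn(f"hyperparameter optimisation did not converge: "
                      f"{res.message}", ConvergenceWarning, stacklevel=2)
    h_map = res.x
    x_map, _, _ = model.inner_solve(h_map, x_cache["x"])

    H_h = _fd_hessian_scalar(lambda h: model.neg_log_marginal(h, dict(x_cache)),
                             h_map, float(res.fun))
    rng = np.random.default_rng(spec.seed)
    h_draws, weight_ess = _draw_hypers(model, h_map, H_h, x_map,
                                       spec.draws, rng)
    if weight_ess < 0.1 * spec.draws:
        warnings.warn(
            f"importance-resampling effective sample size is low "
            f"({weight_ess:.0f} for {spec.draws} draws); the Laplace "
            "proposal matches the hyperparameter posterior poorly",
            ConvergenceWarning, stacklevel=2)

    x_draws = _draw_latents(model, h_draws, x_map, rng)
    result = _assemble_result(model, h_map, x_map, h_draws, x_draws,
                              res.message, converged)
    result.weight_ess = weight_ess
    _check_convergence(result)
    return result


def _fd_hessian_scalar(f, x0, f0, rel_step=1e-2):
    """Central-difference Hessian of a scalar function."""
    p = x0.size
    h = rel_step * (1.0 + np.abs(x0))
    H = np.empty((p, p))
    fp = np.empty(p)
    fm = np.empty(p)
    for i in range(p):
        e = np.zeros(p); e[i] = h[i]
        fp[i] = f(x0 + e)
        fm[i] = f(x0 - e)
        H[i, i] = (fp[i] + fm[i] - 2.0 * f0) / h[i] ** 2
    for i in range(p):
        for j in range(i + 1, p):
            ei = np.zeros(p); ei[i] = h[i]
            ej = np.zeros(p); ej[j] = h[j]
            fpp = f(x0 + ei + ej)
            fmm = f(x0 - ei - ej)
            H[i, j] = H[j, i] = ((fpp + fmm - fp[i] - fm[i] - fp[j] - fm[j]
                                  + 2.0 * f0) / (2.0 * h[i] * h[j]))
    return H


_SIR_SCALE = 1.3           # first-round proposal covariance inflation
_SIR_DF = 7.0              # multivariate-t proposal tail weight


def _sir_round(model, x_map, mean, chol_cov, n_prop, rng):
    """One importance round: t-distributed proposals, exact-marginal weights.

    ``chol_cov`` is a matrix square root of the proposal scale matrix.
    Returns (proposals, normalised weights, weight ESS).
    """
    p = model.dim_h
    z = rng.standard_normal((n_prop, p))
    chi = rng.chisquare(_SIR_DF, size=n_prop)
    t_noise = z * np.sqrt(_SIR_DF / chi)[:, None]
    proposals = mean + t_noise @ chol_cov.T
    # log t density up to constants (the normalisation cancels in the
    # self-normalised weights of a single round)
    maha = np.sum(t_noise * t_noise, axis=1)
    log_q = -0.5 * (_SIR_DF + p) * np.log1p(maha / _SIR_DF)
    log_target = np.full(n_prop, -np.inf)
    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        for s in range(n_prop):
            try:
                lp = -model.neg_log_marginal(proposals[s],
                                             {"x": x_map.copy()})
            except (linalg.LinAlgError, ValueError, FloatingPointError):
                continue                              # unusable proposal
            if np.isfinite(lp):
                log_target[s] = lp
    log_w = log_target - log_q
    log_w -= special.logsumexp(log_w)
    weights = np.exp(log_w)
    return proposals, log_w, float(1.0 / np.sum(weights ** 2))


def _draw_hypers(model: _Model, h_map, H_h, x_map, n_draws, rng):
    """Hyperparameter draws by adaptive sampling-importance-resampling.

    Round 1 proposes from a heavy-tailed multivariate t built on the
    finite-difference Hessian of the marginal posterior and reweights every
    proposal by the *exact* Laplace marginal, so skewed or one-sided-flat
    hyperparameter posteriors (e.g. a zero-inflation logit when the data
    carry no structural zeros) are represented honestly instead of by a
    symmetric Gaussian whose tails can reach absurd parameter values.
    Round 2 re-proposes from a t matched to the weighted moments of round 1,
    which repairs scale/skew mismatch of the Hessian.  Returns the resampled
    draws and the final importance-weight effective sample size.
    """
    w, V = np.linalg.eigh(0.5 * (H_h + H_h.T))
    # floor the spectrum: a noisy flat/negative finite-difference direction
    # gets a wide but finite proposal; reweighting corrects the shape
    w = np.maximum(w, 1e-4 * np.max(np.abs(w)))
    import arviz as az

    mean = h_map
    chol = V * (_SIR_SCALE / np.sqrt(w))             # cov = s^2 V w^-1 V'
    prop, lw, ess = _sir_round(model, x_map, mean, chol, n_draws, rng)
    best = (ess / n_draws, mean, chol)
    for _adapt in range(2):
        # moment-match a candidate proposal to the current weighted posterior
        wts = np.exp(lw)
        m_new = wts @ prop
        d = prop - m_new
        C = (d * wts[:, None]).T @ d
        C = 1.3 * C + 1e-8 * np.eye(model.dim_h)
        try:
            mean, chol = m_new, np.linalg.cholesky(C)
        except np.linalg.LinAlgError:
            break                                    # keep current best
        prop, lw, ess = _sir_round(model, x_map, mean, chol, n_draws, rng)
        if ess / n_draws > best[0]:
            best = (ess / n_draws, mean, chol)
    _, mean, chol = best
    prop, lw, _ = _sir_round(model, x_map, mean, chol, 4 * n_draws, rng)
    # Pareto-smoothed importance weights stabilise the heavy right tail that
    # skewed hyperparameter marginals produce
    lw_smooth, _khat = az.psislw(lw)
    wts = np.exp(lw_smooth - special.logsumexp(lw_smooth))
    weight_ess = float(1.0 / np.sum(wts ** 2))
    idx = rng.choice(prop.shape[0], size=n_draws, replace=True, p=wts)
    return prop[idx], weight_ess


def _draw_latents(model: _Model, h_draws, x_map, rng):
    """Hierarchical latent draws: refresh the conditional mode per theta draw,
    then sample from the conditional Gaussian."""
    S = h_draws.shape[0]
    x_draws = np.empty((S, model.dim_x))
    x_warm = x_map.copy()
    for s in range(S):
        x_hat, cF, _ = model.inner_solve(h_draws[s], x_warm, tol=1e-7,
                                         max_iter=8)
        x_warm = x_hat
        z = rng.standard_normal(model.dim_x)
        # solve L' v = z  =>  v ~ N(0, H^-1)
        v = linalg.solve_triangular(cF[0], z, lower=True, trans="T")
        x_draws[s] = x_hat + v
    return x_draws


def _assemble_result(model: _Model, h_map, x_map, h_draws, x_draws,
                     message, converged):
    spec, design = model.spec, model.design
    S = h_draws.shape[0]
    derived = {
        "alpha": x_draws[:, 0:3],
        "beta_sin": x_draws[:, 3:6],
        "beta_cos": x_draws[:, 6:9],
        "beta_grass": x_draws[:, 9],
        "beta_woods": x_draws[:, 10],
        "beta_lagL": x_draws[:, 11],
        "beta_lagN": x_draws[:, 12],
        "phi": np.exp(h_draws[:, model.h_log_phi]),
        "tau_year": np.exp(h_draws[:, model.h_log_tau]),
    }
    gamma_free = x_draws[:, model._gamma_sl]
    derived["gamma"] = np.concatenate(
        [gamma_free, -gamma_free.sum(axis=1, keepdims=True)], axis=1)
    c = h_draws[:, model.h_chol]
    Lmat = np.zeros((S, 3, 3))
    Lmat[:, 0, 0] = np.exp(c[:, 0])
    Lmat[:, 1, 0] = c[:, 1]
    Lmat[:, 1, 1] = np.exp(c[:, 2])
    Lmat[:, 2, 0] = c[:, 3]
    Lmat[:, 2, 1] = c[:, 4]
    Lmat[:, 2, 2] = np.exp(c[:, 5])
    Sigma = Lmat @ np.transpose(Lmat, (0, 2, 1))
    derived["Sigma_loc"] = Sigma
    var = np.stack([Sigma[:, j, j] for j in range(3)], axis=1)
    derived["tau_loc3d"] = 1.0 / var
    derived["rho"] = np.stack(
        [Sigma[:, a, b] / np.sqrt(var[:, a] * var[:, b])
         for a, b in _RHO_PAIRS], axis=1)
    derived["u"] = x_draws[:, model._u_off:].reshape(S, design.n_locations, 3)
    if model.estimate_pi:
        derived["pi"] = special.expit(h_draws[:, model.h_zeta])
    elif spec.family == "zinb":
        derived["pi"] = np.full((S, 3), float(spec.pin_pi))

    loglik, ll_stage, ll_row = _loglik_matrix(model, derived)
    loglik_plugin = _loglik_plugin(model, derived)

    names = ([f"log_phi_{s}" for s in _STAGE_SUFFIX] + ["log_tau_year"]
             + [f"chol_{k}" for k in range(6)]
             + ([f"zeta_{s}" for s in _STAGE_SUFFIX]
                if model.estimate_pi else []))
    return PosteriorResult(
        spec=spec, design=design, param_names=names,
        hyper_map=h_map, x_map=x_map, derived=derived,
        loglik=loglik, ll_stage=ll_stage, ll_row=ll_row,
        loglik_plugin=loglik_plugin,
        convergence=pd.DataFrame(), converged=converged,
        optimizer_message=str(message))


def stage_eta_draws(result: PosteriorResult, j: int) -> np.ndarray:
    """(S, n_j) linear-predictor draws for stage equation ``j``."""
    return _stage_eta_draws(result.design, result.derived, j,
                            result.spec.include_offset)


def _stage_eta_draws(design, d, j, include_offset=False) -> np.ndarray:
    mask = design.stage_mask(j)
    eta = (d["alpha"][:, j:j + 1]
           + d["beta_sin"][:, j:j + 1] * design.sin_term[mask]
           + d["beta_cos"][:, j:j + 1] * design.cos_term[mask]
           + d["beta_grass"][:, None] * design.grass_ind[mask]
           + d["beta_woods"][:, None] * design.woods_ind[mask]
           + d["gamma"][:, design.year_index[mask]]
           + d["u"][:, design.location_index[mask], j])
    if j == 1:
        eta = eta + d["beta_lagL"][:, None] * design.lag_log_larvae[mask]
    elif j == 2:
        eta = eta + d["beta_lagN"][:, None] * design.lag_log_nymphs[mask]
    if include_offset:
        eta = eta + design.log_visits[mask]
    return np.clip(eta, -ETA_CLIP, ETA_CLIP)


def _stage_ll(y, eta, phi, pi):
    mu = np.exp(eta)
    nb = _nb_log_pmf_raw(y, mu, phi)
    if pi is None:
        return nb
    ll0 = _log_zero_mix(pi, phi * (np.log(phi) - np.log(phi + mu)))
    return np.where(y == 0, ll0, np.log1p(-pi) + nb)


def _loglik_matrix(model: _Model, derived):
    blocks, stages, rows = [], [], []
    for j in range(3):
        d = model.stage[j]
        eta = _stage_eta_draws(model.design, derived, j,
                               model.spec.include_offset)
        phi = derived["phi"][:, j:j + 1]
        pi = derived["pi"][:, j:j + 1] if "pi" in derived else None
        blocks.append(_stage_ll(d["y"][None, :], eta, phi, pi))
        stages.append(np.full(d["y"].size, j))
        rows.append(d["rows"])
    return (np.concatenate(blocks, axis=1),
            np.concatenate(stages), np.concatenate(rows))


def _loglik_plugin(model: _Model, derived):
    """Per-observation log likelihood at posterior-mean eta and hyperparameters."""
    out = []
    for j in range(3):
        d = model.stage[j]
        eta_bar = _stage_eta_draws(model.design, derived, j,
                                   model.spec.include_offset).mean(axis=0)
        phi_bar = derived["phi"][:, j].mean()
        pi_bar = derived["pi"][:, j].mean() if "pi" in derived else None
        out.append(_stage_ll(d["y"], eta_bar, phi_bar, pi_bar))
    return np.concatenate(out)


def _check_convergence(result: PosteriorResult) -> None:
    """Split-R-hat and bulk ESS for every reported scalar, via arviz."""
    import arviz as az

    spec = result.spec
    rows = []
    ok = True
    for name, x in _scalar_draws(result).items():
        n = (x.size // spec.chains) * spec.chains
        arr = x[:n].reshape(spec.chains, -1)
        if np.ptp(arr) < 1e-12:      # pinned or degenerate parameter
            rhat, ess = 1.0, float(n)
        else:
            rhat = float(az.rhat(az.convert_to_dataset(arr))["x"])
            ess = float(az.ess(az.convert_to_dataset(arr))["x"])
        rows.append((name, rhat, ess))
        if rhat > 1.01 or ess <= 400:
            ok = False
    result.convergence = pd.DataFrame(
        rows, columns=["parameter", "rhat", "ess"]).set_index("parameter")
    if not ok:
        warnings.warn("posterior convergence contract not met "
                      "(R-hat > 1.01 or ESS <= 400 for some parameter)",
                      ConvergenceWarning, stacklevel=3)
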