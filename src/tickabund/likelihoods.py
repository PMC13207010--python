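"""Negative-binomial and zero-inflated negative-binomial log-likelihoods.

The NB distribution is parameterised by its mean ``mu`` and size ``phi`` with
``Var(Y) = mu + mu**2 / phi``: small ``phi`` means heavy overdispersion (the
larval size estimates here are of order 0.1, i.e. variance-to-mean ratios in
the hundreds to thousands at typical means).  The ZINB mixes a point mass at
zero (probability ``pi``, a "structural" zero) with the NB count process.

Besides the public log-pmf / cdf functions this module provides the analytic
derivatives with respect to the linear predictor ``eta = log(mu)``, the log
size ``log(phi)`` and the logit of ``pi``, which the Laplace fitting engine
uses for gradient-based optimisation.
"""

from __future__ import annotations

import numpy as np
from scipy import special, stats

__all__ = ["nb_log_pmf", "zinb_log_pmf", "nb_cdf", "zinb_cdf"]


def _validate(y, mu, phi, pi=None):
    y = np.asarray(y)
    mu = np.asarray(mu, float)
    phi = np.asarray(phi, float)
    if np.any(y < 0) or not np.allclose(y, np.round(y)):
        raise ValueError("y must be a non-negative integer count")
    if np.any(mu <= 0):
        raise ValueError("mu must be positive")
    if np.any(phi <= 0):
        raise ValueError("phi must be positive")
    if pi is not None:
        pi = np.asarray(pi, float)
        if np.any((pi < 0) | (pi >= 1)):
            raise ValueError("pi must lie in [0, 1)")
    return y, mu, phi, pi


def nb_log_pmf(y, mu, phi):
    """Log NB pmf in mean/size form, stable for large counts.

    ``log P(Y=y) = lgamma(y+phi) - lgamma(phi) - lgamma(y+1)
    + phi*log(phi/(phi+mu)) + y*log(mu/(phi+mu))``.
    """
    y, mu, phi, _ = _validate(y, mu, phi)
    out = _nb_log_pmf_raw(y, mu, phi)
    return float(out) if np.ndim(out) == 0 else out


def _nb_log_pmf_raw(y, mu, phi):
    log_denom = np.log(phi + mu)
    return (special.gammaln(y + phi) - special.gammaln(phi)
            - special.gammaln(y + 1)
            + phi * (np.log(phi) - log_denom)
            + y * (np.log(mu) - log_denom))


def zinb_log_pmf(y, mu, phi, pi):
    """Log ZINB pmf: ``log[pi * 1{y=0} + (1-pi) * NB(y; mu, phi)]``."""
    y, mu, phi, pi = _validate(y, mu, phi, pi)
    nb = _nb_log_pmf_raw(y, mu, phi)
    with np.errstate(divide="ignore"):
        nonzero = np.log1p(-pi) + nb
    is_zero = np.asarray(y == 0)
    out = np.where(is_zero, _log_zero_mix(pi, nb), nonzero)
    return float(out) if np.ndim(out) == 0 else out


def _log_zero_mix(pi, nb_log_p0):
    """``log(pi + (1 - pi) * exp(nb_log_p0))`` elementwise, pi possibly 0."""
    pi = np.asarray(pi, float)
    nb_log_p0 = np.asarray(nb_log_p0, float)
    with np.errstate(divide="ignore"):
        log_pi = np.where(pi > 0, np.log(np.maximum(pi, 1e-300)), -np.inf)
        log_1mpi = np.log1p(-pi)
    return np.logaddexp(log_pi, log_1mpi + nb_log_p0)


def nb_cdf(y, mu, phi):
    """NB cdf in mean/size form; ``nb_cdf(-1, ...) == 0``."""
    mu = np.asarray(mu, float)
    phi = np.asarray(phi, float)
    p = phi / (phi + mu)
    return stats.nbinom.cdf(y, phi, p)


def zinb_cdf(y, mu, phi, pi):
    """ZINB cdf: ``pi * 1{y >= 0} + (1 - pi) * NB cdf``."""
    y = np.asarray(y)
    base = nb_cdf(y, mu, phi)
    return np.where(y >= 0, pi + (1.0 - pi) * base, 0.0)


# ---------------------------------------------------------------------------
# Gradient kernels used by the fitting engine.  All take eta = log(mu) and
# return per-observation log-likelihood plus derivatives; no input validation
# (hot path), callers guarantee shapes and ranges.
# ---------------------------------------------------------------------------

ETA_CLIP = 30.0  # |eta| beyond this is astronomically implausible for counts


def nb_ll_grads(y, eta, phi):
    """Return (ll, dll/deta, dll/dlog_phi) for NB, vectorised."""
    eta = np.clip(eta, -ETA_CLIP, ETA_CLIP)
    mu = np.exp(eta)
    denom = mu + phi
    ll = _nb_log_pmf_raw(y, mu, phi)
    d_eta = y - (y + phi) * mu / denom
    d_phi = (special.digamma(y + phi) - special.digamma(phi)
             + np.log(phi / denom) + (mu - y) / denom)
    return ll, d_eta, phi * d_phi


def nb_ll_curv(y, eta, phi):
    """Return (ll, dll/deta, -d2ll/deta2) for NB; curvature is positive."""
    eta = np.clip(eta, -ETA_CLIP, ETA_CLIP)
    mu = np.exp(eta)
    denom = mu + phi
    ll = _nb_log_pmf_raw(y, mu, phi)
    d_eta = y - (y + phi) * mu / denom
    w = (y + phi) * phi * mu / denom ** 2
    return ll, d_eta, w


def zinb_ll_curv(y, eta, phi, pi):
    """Return (ll, dll/deta, -d2ll/deta2) for ZINB.

    The zero-mixture branch is not log-concave everywhere; the returned
    curvature is the exact negative second derivative, which callers clamp
    to be positive when building Newton/Laplace Hessians.
    """
    eta = np.clip(eta, -ETA_CLIP, ETA_CLIP)
    mu = np.exp(eta)
    denom = mu + phi
    nb_ll, nb_d_eta, nb_w = nb_ll_curv(y, eta, phi)
    is_zero = y == 0

    log_p0 = phi * (np.log(phi) - np.log(denom))
    ll0 = _log_zero_mix(pi, log_p0)
    w_mix = np.exp(np.log1p(-pi) + log_p0 - ll0)   # (1-pi) p0 / mix in (0,1]
    a = -phi * mu / denom                          # d log p0 / d eta
    a_prime = -(phi ** 2) * mu / denom ** 2
    d_eta0 = w_mix * a
    curv0 = -(w_mix * a_prime + w_mix * (1.0 - w_mix) * a ** 2)

    with np.errstate(divide="ignore"):
        ll1 = np.log1p(-pi) + nb_ll
    ll = np.where(is_zero, ll0, ll1)
    d_eta = np.where(is_zero, d_eta0, nb_d_eta)
    w = np.where(is_zero, curv0, nb_w)
    return ll, d_eta, w


def zinb_ll_grads(y, eta, phi, pi):
    """Return (ll, dll/deta, dll/dlog_phi, dll/dlogit_pi) for ZINB."""
    eta = np.clip(eta, -ETA_CLIP, ETA_CLIP)
    mu = np.exp(eta)
    denom = mu + phi
    nb_ll, nb_d_eta, nb_d_logphi = nb_ll_grads(y, eta, phi)
    is_zero = y == 0

    # zero branch: ll0 = log(pi + (1-pi) p0), p0 = (phi/(phi+mu))^phi
    log_p0 = phi * (np.log(phi) - np.log(denom))
    ll0 = _log_zero_mix(pi, log_p0)
    w = np.exp(np.log1p(-pi) + log_p0 - ll0)       # (1-pi) p0 / mix
    dlogp0_eta = -phi * mu / denom
    dlogp0_logphi = phi * (np.log(phi / denom) + mu / denom)
    d_eta0 = w * dlogp0_eta
    d_logphi0 = w * dlogp0_logphi
    p0 = np.exp(log_p0)
    mix = np.exp(ll0)
    d_zeta0 = pi * (1.0 - pi) * (1.0 - p0) / mix

    # nonzero branch: log(1-pi) + NB
    with np.errstate(divide="ignore"):
        ll1 = np.log1p(-pi) + nb_ll
    d_zeta1 = -pi * np.ones_like(mu)

    ll = np.where(is_zero, ll0, ll1)
    d_eta = np.where(is_zero, d_eta0, nb_d_eta)
    d_logphi = np.where(is_zero, d_logphi0, nb_d_logphi)
    d_zeta = np.where(is_zero, d_zeta0, d_zeta1)
    return ll, d_eta, d_logphi, d_zeta
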