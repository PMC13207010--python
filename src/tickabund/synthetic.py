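"""Synthetic monthly multistage tick count panels.

The generator draws panels from exactly the generative structure the models
in :mod:`tickabund.inference` assume: stage-specific annual harmonics, shared
habitat effects (edge reference), lagged log-abundance coupling between
successive stages, a shared year effect, one correlated trivariate location
effect per site, and an NB (optionally zero-inflated) observation layer.

The default truth (:func:`default_truth`) uses empirically realistic
magnitudes for a lone-star-tick surveillance programme in the mid-Atlantic:
heavy larval overdispersion (NB size ~0.08, variance-to-mean ratios in the
hundreds to thousands), winter-dominated zero proportions of 0.6-0.85, adult
activity peaking in early summer and larvae peaking in August, woods more
abundant than edge and grass less so.  The default design mimics the same
surveillance setting: six locations, up to three habitats each (two sites
miss one habitat), monthly sampling May 2009 - December 2018 with roughly 30%
of site-months unsampled, giving ~1300 aggregated records.

Lag propagation is self-consistent: the lag predictor a simulated month sees
is the log of the count simulated (after any structural zeroing) in the
previous calendar month of the same series; where that month was not sampled
the lag term contributes zero and the panel's lag field is left missing, so
downstream fitting excludes the row from the nymph/adult equations exactly as
it would for real data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .panel import HABITATS, PANEL_COLUMNS, STAGES

__all__ = ["TrueParameters", "GeneratorConfig", "default_truth",
           "default_config", "simulate_panel", "true_means"]


def _sigma_from_precisions_correlations(tau: Sequence[float],
                                        rho: Sequence[float]) -> np.ndarray:
    """Build Sigma_loc from per-stage precisions and (L:N, L:A, N:A) correlations."""
    sd = 1.0 / np.sqrt(np.asarray(tau, float))
    r_ln, r_la, r_na = rho
    corr = np.array([[1.0, r_ln, r_la],
                     [r_ln, 1.0, r_na],
                     [r_la, r_na, 1.0]])
    return corr * np.outer(sd, sd)


@dataclass
class TrueParameters:
    """Generative parameter values; see :func:`default_truth` for defaults."""

    alpha: np.ndarray                      # stage intercepts (L, N, A)
    beta_sin: np.ndarray
    beta_cos: np.ndarray
    beta_grass: float
    beta_woods: float
    beta_lagL: float
    beta_lagN: float
    phi: np.ndarray                        # NB sizes, Var = mu + mu^2/phi
    tau_year: float
    Sigma_loc: np.ndarray                  # 3x3 SPD covariance of u_i
    pi: np.ndarray = field(default_factory=lambda: np.zeros(3))
    year_effect_mode: str = "linear_decline"   # rw1 | linear_decline | fixed_vector
    year_effect_values: np.ndarray | None = None

    def __post_init__(self):
        for name in ("alpha", "beta_sin", "beta_cos", "phi", "pi"):
            setattr(self, name, np.asarray(getattr(self, name), float))
        self.Sigma_loc = np.asarray(self.Sigma_loc, float)
        if np.any(self.phi <= 0):
            raise ValueError("phi must be positive")
        if np.any((self.pi < 0) | (self.pi >= 1)):
            raise ValueError("pi must lie in [0, 1)")
        if self.tau_year <= 0:
            raise ValueError("tau_year must be positive")
        w = np.linalg.eigvalsh(self.Sigma_loc)
        if w.min() <= 0:
            raise ValueError("Sigma_loc must be positive definite")
        if self.year_effect_mode not in ("rw1", "linear_decline",
                                         "fixed_vector"):
            raise ValueError(f"unknown year_effect_mode "
                             f"{self.year_effect_mode!r}")


def default_truth() -> TrueParameters:
    """Default simulation truth for a realistic surveillance regime.

    Coefficients correspond to adult activity peaking in June, nymphs in
    June-July and larvae in August, lower abundance in grass and higher in
    woods than at habitat edges, positive lag coupling between successive
    stages, severe larval overdispersion, and moderate interannual and
    between-location variation with strongly positively correlated location
    effects across stages.  Intercepts set typical monthly aggregate scales
    (tens of larvae, a few nymphs/adults at seasonal peak conditions).
    """
    return TrueParameters(
        alpha=(2.0, 0.5, 0.0),
        beta_sin=(-5.285, -0.430, 1.154),
        beta_cos=(-2.483, -3.624, -5.093),
        beta_grass=-1.298,
        beta_woods=0.496,
        beta_lagL=0.212,
        beta_lagN=0.107,
        phi=(0.077, 0.467, 1.061),
        tau_year=6.912,
        Sigma_loc=_sigma_from_precisions_correlations(
            tau=(1.601, 1.749, 0.263), rho=(0.667, 0.456, 0.787)),
    )


_DEFAULT_HABITATS: Mapping[str, tuple] = {
    "BB": ("edge", "grass"),          # woods never sampled at this refuge
    "BW": ("grass", "woods"),         # no edge transect at this preserve
    "CA": HABITATS,
    "KP": HABITATS,
    "LA": HABITATS,
    "OD": HABITATS,
}


@dataclass
class GeneratorConfig:
    """Study design of a simulated panel; the seed fully determines output."""

    truth: TrueParameters = field(default_factory=default_truth)
    habitats_per_location: Mapping[str, Sequence[str]] = field(
        default_factory=lambda: dict(_DEFAULT_HABITATS))
    years: tuple = (2009, 2018)
    start_month: int = 5              # sampling begins May of the first year
    month_missing_prob: float = 0.3   # site-months without any visit
    family: str = "nb"                # "nb" | "zinb"
    seed: int = 0
    max_visits: int = 4               # visits per sampled month ~ U{1..max}

    def __post_init__(self):
        if not self.habitats_per_location:
            raise ValueError("at least one location is required")
        for loc, habs in self.habitats_per_location.items():
            if len(habs) == 0:
                raise ValueError(f"location {loc!r} has no habitats")
            unknown = set(habs) - set(HABITATS)
            if unknown:
                raise ValueError(f"unknown habitats {unknown} at {loc!r}")
        if self.family not in ("nb", "zinb"):
            raise ValueError(f"unknown family {self.family!r}")
        if not 0.0 <= self.month_missing_prob < 1.0:
            raise ValueError("month_missing_prob must lie in [0, 1)")
        if not 1 <= self.start_month <= 12:
            raise ValueError("start_month must lie in 1..12")

    @property
    def n_locations(self) -> int:
        return len(self.habitats_per_location)


def default_config(seed: int = 0, family: str = "nb",
                   truth: TrueParameters | None = None,
                   years: tuple = (2009, 2018),
                   **kwargs) -> GeneratorConfig:
    """Convenience constructor for the default study design."""
    return GeneratorConfig(truth=truth or default_truth(), years=years,
                           family=family, seed=seed, **kwargs)


def _year_effects(truth: TrueParameters, years: np.ndarray,
                  rng: np.random.Generator) -> np.ndarray:
    n = len(years)
    if truth.year_effect_mode == "fixed_vector":
        g = np.asarray(truth.year_effect_values, float)
        if g.shape != (n,):
            raise ValueError("year_effect_values must have one entry per year")
    elif truth.year_effect_mode == "linear_decline":
        g = np.linspace(0.4, -0.4, n)
    else:  # rw1 with precision tau_year
        steps = rng.normal(0.0, 1.0 / math.sqrt(truth.tau_year), n - 1)
        g = np.concatenate([[0.0], np.cumsum(steps)])
    return g - g.mean()


def simulate_panel(config: GeneratorConfig):
    """Simulate one panel; returns ``(panel, latents)``.

    ``panel`` is a lag-attached DataFrame in the standard panel layout.
    ``latents`` records the realised year effects, location effects, and (for
    ZINB) the structural-zero draws, plus which observations used a zero lag
    predictor because the preceding month was unsampled (burn-in/gap months).
    """
    truth = config.truth
    rng = np.random.default_rng(config.seed)
    locations = sorted(config.habitats_per_location)
    y0, y1 = config.years
    years = np.arange(y0, y1 + 1)

    gamma = _year_effects(truth, years, rng)
    u = rng.multivariate_normal(np.zeros(3), truth.Sigma_loc,
                                size=len(locations))

    serial0 = y0 * 12 + (config.start_month - 1)
    serial1 = y1 * 12 + 11
    n_months = serial1 - serial0 + 1

    rows = []
    structural_zero = []
    burn_in = []
    for li, loc in enumerate(locations):
        for hab in sorted(config.habitats_per_location[loc],
                          key=HABITATS.index):
            sampled = rng.random(n_months) >= config.month_missing_prob
            grass = float(hab == "grass")
            woods = float(hab == "woods")
            prev_counts = None           # counts of previous calendar month
            prev_serial = None
            for k in range(n_months):
                serial = serial0 + k
                if not sampled[k]:
                    continue
                year = serial // 12
                month = serial % 12 + 1
                ang = 2.0 * math.pi * month / 12.0
                s, c = math.sin(ang), math.cos(ang)
                has_lag = prev_serial == serial - 1
                lagL = math.log1p(prev_counts[0]) if has_lag else np.nan
                lagN = math.log1p(prev_counts[1]) if has_lag else np.nan
                g_year = gamma[year - y0]
                counts = np.empty(3, int)
                for j in range(3):
                    eta = (truth.alpha[j] + truth.beta_sin[j] * s
                           + truth.beta_cos[j] * c
                           + truth.beta_grass * grass
                           + truth.beta_woods * woods
                           + g_year + u[li, j])
                    if j == 1:
                        eta += truth.beta_lagL * (0.0 if not has_lag else lagL)
                    elif j == 2:
                        eta += truth.beta_lagN * (0.0 if not has_lag else lagN)
                    mu = math.exp(min(eta, 30.0))
                    lam = rng.gamma(truth.phi[j], mu / truth.phi[j])
                    y_count = int(rng.poisson(lam))
                    if config.family == "zinb" and truth.pi[j] > 0:
                        if rng.random() < truth.pi[j]:
                            structural_zero.append((loc, hab, int(year),
                                                    int(month), STAGES[j]))
                            y_count = 0
                    counts[j] = y_count
                if not has_lag:
                    burn_in.append((loc, hab, int(year), int(month)))
                rows.append((loc, hab, int(year), int(month),
                             int(rng.integers(1, config.max_visits + 1)),
                             counts[0], counts[1], counts[2], lagL, lagN))
                prev_counts = counts[:2].copy()
                prev_serial = serial

    panel = pd.DataFrame(rows, columns=PANEL_COLUMNS)
    panel = panel.sort_values(["location", "habitat", "year", "month"],
                              kind="mergesort").reset_index(drop=True)
    latents = {
        "years": years,
        "gamma_year": gamma,
        "locations": np.asarray(locations),
        "u_location": u,
        "burn_in": burn_in,
        "structural_zero": structural_zero,
    }
    return panel, latents


def true_means(panel: pd.DataFrame, truth: TrueParameters,
               latents: Mapping) -> np.ndarray:
    """NB means ``mu`` (n_obs, 3) under the generating parameters.

    Reconstructs exactly the linear predictors :func:`simulate_panel` used,
    including the convention that a missing lag (burn-in or gap month)
    contributes zero to the nymph and adult equations.  Together with
    ``truth.phi`` (and ``truth.pi`` for ZINB) this defines the true
    predictive distribution of every panel entry, e.g. for calibration
    checks of the randomized PIT under the true model.
    """
    years = np.asarray(latents["years"])
    gamma = np.asarray(latents["gamma_year"], float)
    locations = list(latents["locations"])
    u = np.asarray(latents["u_location"], float)
    g_year = gamma[np.searchsorted(years, panel["year"].to_numpy())]
    loc_idx = np.array([locations.index(l) for l in panel["location"]])
    ang = 2.0 * np.pi * panel["month"].to_numpy() / 12.0
    s, c = np.sin(ang), np.cos(ang)
    grass = (panel["habitat"] == "grass").to_numpy(float)
    woods = (panel["habitat"] == "woods").to_numpy(float)
    lagL = np.nan_to_num(panel["lag_log_larvae"].to_numpy(float))
    lagN = np.nan_to_num(panel["lag_log_nymphs"].to_numpy(float))
    mu = np.empty((len(panel), 3))
    for j in range(3):
        eta = (truth.alpha[j] + truth.beta_sin[j] * s + truth.beta_cos[j] * c
               + truth.beta_grass * grass + truth.beta_woods * woods
               + g_year + u[loc_idx, j])
        if j == 1:
            eta = eta + truth.beta_lagL * lagL
        elif j == 2:
            eta = eta + truth.beta_lagN * lagN
        mu[:, j] = np.exp(np.minimum(eta, 30.0))
    return mu
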