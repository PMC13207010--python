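"""Covariate construction for the multistage abundance models.

Annual seasonality is encoded with a single harmonic pair
``sin(2*pi*M/12), cos(2*pi*M/12)`` of the calendar month ``M`` (January = 1);
habitat enters as treatment-coded indicators with *edge* as the reference
level; stage progression enters through the lagged log-abundance predictors
computed in :mod:`tickabund.panel`.

:func:`build_design` packs a lag-attached panel into the dense arrays the
likelihood consumes.  The nymph equation needs ``log(L[t-1]+1)`` and the
adult equation needs ``log(N[t-1]+1)``; rows lacking the required lag are
excluded from those stage equations (but larvae, which carry no lag term,
always contribute).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .panel import HABITATS, STAGES

__all__ = ["encode_harmonics", "encode_habitat", "build_design", "DesignMatrices"]


def encode_harmonics(month) -> tuple:
    """Return ``(sin(2*pi*M/12), cos(2*pi*M/12))`` for calendar month(s) M."""
    m = np.asarray(month)
    if np.any((m < 1) | (m > 12)):
        raise ValueError(f"month out of range 1-12: {month!r}")
    ang = 2.0 * np.pi * m / 12.0
    s, c = np.sin(ang), np.cos(ang)
    if np.ndim(month) == 0:
        return float(s), float(c)
    return s, c


def encode_habitat(habitat) -> tuple:
    """Treatment-code habitat: edge -> (0,0), grass -> (1,0), woods -> (0,1)."""
    if isinstance(habitat, str):
        if habitat not in HABITATS:
            raise ValueError(f"unknown habitat level {habitat!r}")
        return float(habitat == "grass"), float(habitat == "woods")
    h = pd.Series(habitat)
    bad = ~h.isin(HABITATS)
    if bad.any():
        raise ValueError(f"unknown habitat level {h[bad].iloc[0]!r}")
    return (h == "grass").to_numpy(float), (h == "woods").to_numpy(float)


@dataclass
class DesignMatrices:
    """Dense design arrays for one panel, shared across the three stages.

    All per-observation arrays have length ``n_obs`` (one aggregated monthly
    record each).  ``include_nymphs`` / ``include_adults`` mask the rows that
    enter those stage equations (lag available).
    """

    sin_term: np.ndarray
    cos_term: np.ndarray
    grass_ind: np.ndarray
    woods_ind: np.ndarray
    lag_log_larvae: np.ndarray      # NaN where missing
    lag_log_nymphs: np.ndarray
    year_index: np.ndarray          # 0-based, dense encoding of panel years
    location_index: np.ndarray      # 0-based, dense encoding of locations
    years: np.ndarray               # sorted distinct years, len n_years
    locations: np.ndarray           # sorted distinct location codes
    counts: np.ndarray              # (n_obs, 3) stage counts, STAGES order
    include_nymphs: np.ndarray      # bool
    include_adults: np.ndarray      # bool
    month: np.ndarray
    log_visits: np.ndarray = field(default=None)

    @property
    def n_obs(self) -> int:
        return len(self.sin_term)

    @property
    def n_years(self) -> int:
        return len(self.years)

    @property
    def n_locations(self) -> int:
        return len(self.locations)

    def stage_mask(self, j: int) -> np.ndarray:
        """Boolean inclusion mask for stage equation j (0=L, 1=N, 2=A)."""
        if j == 0:
            return np.ones(self.n_obs, bool)
        return self.include_nymphs if j == 1 else self.include_adults

    def to_frame(self) -> pd.DataFrame:
        """Long-format dump (one row per observation x stage) for debugging."""
        rows = []
        for j, stage in enumerate(STAGES):
            mask = self.stage_mask(j)
            rows.append(pd.DataFrame({
                "stage": stage,
                "sin_term": self.sin_term,
                "cos_term": self.cos_term,
                "grass_ind": self.grass_ind,
                "woods_ind": self.woods_ind,
                "lag_log_larvae": self.lag_log_larvae,
                "lag_log_nymphs": self.lag_log_nymphs,
                "year_index": self.year_index,
                "location_index": self.location_index,
                "count": self.counts[:, j],
                "excluded": ~mask,
            }))
        return pd.concat(rows, ignore_index=True)


def build_design(panel: pd.DataFrame) -> DesignMatrices:
    """Build :class:`DesignMatrices` from a lag-attached panel."""
    if len(panel) == 0:
        raise ValueError("build_design: empty panel")
    sin_t, cos_t = encode_harmonics(panel["month"].to_numpy())
    grass, woods = encode_habitat(panel["habitat"])
    years, year_idx = np.unique(panel["year"].to_numpy(), return_inverse=True)
    locs, loc_idx = np.unique(panel["location"].to_numpy(), return_inverse=True)
    lagL = panel["lag_log_larvae"].to_numpy(float)
    lagN = panel["lag_log_nymphs"].to_numpy(float)
    counts = panel[list(STAGES)].to_numpy(int)
    return DesignMatrices(
        sin_term=sin_t, cos_term=cos_t,
        grass_ind=grass, woods_ind=woods,
        lag_log_larvae=lagL, lag_log_nymphs=lagN,
        year_index=year_idx, location_index=loc_idx,
        years=years, locations=locs, counts=counts,
        include_nymphs=~np.isnan(lagL), include_adults=~np.isnan(lagN),
        month=panel["month"].to_numpy(int),
        log_visits=np.log(panel["n_visits"].to_numpy(float)),
    )
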