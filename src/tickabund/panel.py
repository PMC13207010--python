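"""Survey-record I/O and construction of the monthly location x habitat panel.

Field surveys record, per sampling visit, the numbers of questing larvae,
nymphs and adults collected by flagging at a location/habitat.  The models in
:mod:`tickabund.inference` consume a *panel*: one row per
(location, habitat, year, month) with counts summed over visits, plus the
lagged log-abundance predictors ``log(L[t-1]+1)`` and ``log(N[t-1]+1)`` that
encode stage progression (larvae feed nymphs, nymphs feed adults).

Both visit records and panels are plain :class:`pandas.DataFrame` objects in
a fixed column layout; helpers here validate, aggregate, filter and write
them.
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd

__all__ = [
    "HABITATS",
    "STAGES",
    "PANEL_COLUMNS",
    "SurveyFormatError",
    "read_survey_csv",
    "aggregate_monthly",
    "filter_well_sampled",
    "attach_lags",
    "write_panel_csv",
    "read_panel_csv",
]

logger = logging.getLogger(__name__)

#: Habitat levels; ``edge`` is the reference category in the design matrix.
HABITATS = ("edge", "grass", "woods")

#: Life stages in developmental order.
STAGES = ("larvae", "nymphs", "adults")

SURVEY_COLUMNS = ["location", "habitat", "year", "month", *STAGES]
PANEL_COLUMNS = SURVEY_COLUMNS[:4] + ["n_visits", *STAGES,
                                      "lag_log_larvae", "lag_log_nymphs"]

#: Default minimum total visits for a location to be considered well sampled.
DEFAULT_MIN_VISITS = 104


class SurveyFormatError(ValueError):
    """A survey CSV row violates the record contract."""


def _check_survey_frame(df: pd.DataFrame, source: str = "<records>") -> pd.DataFrame:
    """Validate and normalise a frame of visit records in place-safe copy."""
    missing = [c for c in SURVEY_COLUMNS if c not in df.columns]
    if missing:
        raise SurveyFormatError(f"{source}: missing columns {missing}")
    df = df.copy()
    df["habitat"] = df["habitat"].astype(str).str.strip().str.lower()
    bad = ~df["habitat"].isin(HABITATS)
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise SurveyFormatError(
            f"{source}: row {row + 1}: unknown habitat level "
            f"{df['habitat'].iloc[row]!r} (expected one of {HABITATS})"
        )
    for col in ("year", "month", *STAGES):
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any():
            row = int(np.flatnonzero(vals.isna().to_numpy())[0])
            raise SurveyFormatError(
                f"{source}: row {row + 1}: non-numeric value in column {col!r}"
            )
        if not np.allclose(vals, np.round(vals)):
            row = int(np.flatnonzero(~np.isclose(vals, np.round(vals)))[0])
            raise SurveyFormatError(
                f"{source}: row {row + 1}: column {col!r} must be an integer"
            )
        df[col] = vals.astype(int)
    for col in STAGES:
        if (df[col] < 0).any():
            row = int(np.flatnonzero((df[col] < 0).to_numpy())[0])
            raise SurveyFormatError(
                f"{source}: row {row + 1}: negative count in column {col!r}"
            )
    if not df["month"].between(1, 12).all():
        row = int(np.flatnonzero(~df["month"].between(1, 12).to_numpy())[0])
        raise SurveyFormatError(f"{source}: row {row + 1}: month out of range 1-12")
    df["location"] = df["location"].astype(str).str.strip()
    return df


def read_survey_csv(path) -> pd.DataFrame:
    """Read visit-level survey records.

    The file must have a header naming ``location, habitat, year, month,
    larvae, nymphs, adults``.  Habitat strings are normalised
    case-insensitively to the three levels; malformed rows raise
    :class:`SurveyFormatError` naming the offending row.
    """
    df = pd.read_csv(path)
    return _check_survey_frame(df, source=str(path))[SURVEY_COLUMNS]


def aggregate_monthly(records: pd.DataFrame) -> pd.DataFrame:
    """Sum visit counts into one row per (location, habitat, year, month).

    ``n_visits`` records how many visits contributed, so that a log-offset
    can be added downstream if desired (none is used by default).  Output is
    sorted by location, habitat, year, month; lag columns are initialised to
    missing.
    """
    if len(records) == 0:
        raise ValueError("aggregate_monthly: no survey records")
    records = _check_survey_frame(records)
    keys = ["location", "habitat", "year", "month"]
    agg = (
        records.groupby(keys, as_index=False, sort=True)
        .agg(n_visits=("larvae", "size"), larvae=("larvae", "sum"),
             nymphs=("nymphs", "sum"), adults=("adults", "sum"))
        .sort_values(keys, kind="mergesort")
        .reset_index(drop=True)
    )
    agg["lag_log_larvae"] = np.nan
    agg["lag_log_nymphs"] = np.nan
    return agg[PANEL_COLUMNS]


def filter_well_sampled(panel: pd.DataFrame,
                        min_visits: int = DEFAULT_MIN_VISITS) -> pd.DataFrame:
    """Keep locations with at least ``min_visits`` total visits.

    Totals are summed over habitats, years and months within a location.
    Dropped locations are logged; an empty survivor set logs a warning.
    """
    if min_visits < 1:
        raise ValueError("min_visits must be >= 1")
    totals = panel.groupby("location")["n_visits"].sum()
    keep = set(totals.index[totals >= min_visits])
    dropped = sorted(set(totals.index) - keep)
    if dropped:
        logger.info("filter_well_sampled: dropping %s (< %d visits)",
                    dropped, min_visits)
    if not keep:
        logger.warning("filter_well_sampled: no location reaches %d visits",
                       min_visits)
    out = panel[panel["location"].isin(keep)].reset_index(drop=True)
    return out


def _month_serial(year: np.ndarray, month: np.ndarray) -> np.ndarray:
    return year * 12 + (month - 1)


def attach_lags(panel: pd.DataFrame) -> pd.DataFrame:
    """Attach ``log(count+1)`` of the previous calendar month's larvae/nymphs.

    Within each (location, habitat) series the lag is defined only when the
    immediately preceding calendar month was sampled; December feeds the next
    January.  Gaps leave the lag missing.  Idempotent: lags are recomputed
    from the counts each call.
    """
    panel = panel.sort_values(["location", "habitat", "year", "month"],
                              kind="mergesort").reset_index(drop=True)
    out = panel.copy()
    serial = _month_serial(out["year"].to_numpy(), out["month"].to_numpy())
    lagL = np.full(len(out), np.nan)
    lagN = np.full(len(out), np.nan)
    for _, idx in out.groupby(["location", "habitat"], observed=True).groups.items():
        idx = np.asarray(idx)
        s = serial[idx]
        prev_pos = {m: k for k, m in enumerate(s)}
        for k, m in enumerate(s):
            j = prev_pos.get(m - 1)
            if j is not None:
                lagL[idx[k]] = math.log1p(out["larvae"].iloc[idx[j]])
                lagN[idx[k]] = math.log1p(out["nymphs"].iloc[idx[j]])
    out["lag_log_larvae"] = lagL
    out["lag_log_nymphs"] = lagN
    return out


def write_panel_csv(panel: pd.DataFrame, path) -> None:
    """Write a panel as UTF-8 CSV; missing lags become empty fields."""
    panel.to_csv(path, index=False, float_format="%.12g", encoding="utf-8")


def read_panel_csv(path) -> pd.DataFrame:
    """Read a panel written by :func:`write_panel_csv`."""
    df = pd.read_csv(path)
    missing = [c for c in PANEL_COLUMNS if c not in df.columns]
    if missing:
        raise SurveyFormatError(f"{path}: missing panel columns {missing}")
    for col in ("year", "month", "n_visits", *STAGES):
        df[col] = df[col].astype(int)
    return df[PANEL_COLUMNS]
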