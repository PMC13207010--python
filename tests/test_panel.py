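import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from tickabund.panel import (DEFAULT_MIN_VISITS, PANEL_COLUMNS,
                             SurveyFormatError, aggregate_monthly, attach_lags,
                             filter_well_sampled, read_panel_csv,
                             read_survey_csv, write_panel_csv)


def test_read_survey_csv_normalises_habitat(tmp_path, toy_records):
    path = tmp_path / "visits.csv"
    toy_records.to_csv(path, index=False)
    df = read_survey_csv(path)
    assert set(df["habitat"]) <= {"edge", "grass", "woods"}
    assert len(df) == len(toy_records)


@pytest.mark.parametrize("mutate, fragment", [
    (lambda d: d.drop(columns=["month"]), "missing columns"),
    (lambda d: d.assign(habitat=["edge"] * 5 + ["swamp"]), "row 6"),
    (lambda d: d.assign(larvae=[1, 2, 3, 4, 5, -1]), "row 6"),
    (lambda d: d.assign(month=[4, 4, 5, 4, 5, 13]), "month out of range"),
    (lambda d: d.assign(nymphs=[1, 0, 2, 5, 0, 2.5]), "integer"),
])
def test_read_survey_csv_errors(tmp_path, toy_records, mutate, fragment):
    path = tmp_path / "visits.csv"
    mutate(toy_records).to_csv(path, index=False)
    with pytest.raises(SurveyFormatError, match=fragment):
        read_survey_csv(path)


def test_aggregate_monthly_sums_and_counts(toy_records):
    panel = aggregate_monthly(toy_records)
    assert list(panel.columns) == PANEL_COLUMNS
    row = panel[(panel["location"] == "A") & (panel["month"] == 4)]
    assert len(row) == 1
    assert int(row["larvae"].iloc[0]) == 5          # 3 + 2
    assert int(row["n_visits"].iloc[0]) == 2
    assert panel["lag_log_larvae"].isna().all()
    # sorted by location, habitat, year, month
    keys = panel[["location", "habitat", "year", "month"]]
    assert keys.equals(keys.sort_values(list(keys.columns),
                                        kind="mergesort").reset_index(drop=True))


def test_aggregate_monthly_empty_errors():
    with pytest.raises(ValueError):
        aggregate_monthly(pd.DataFrame(columns=["location", "habitat", "year",
                                                "month", "larvae", "nymphs",
                                                "adults"]))


def test_filter_well_sampled(toy_records):
    panel = aggregate_monthly(toy_records)
    assert set(filter_well_sampled(panel, min_visits=3)["location"]) == {"A", "B"}
    assert set(filter_well_sampled(panel, min_visits=4)["location"]) == set()
    with pytest.raises(ValueError):
        filter_well_sampled(panel, min_visits=0)
    assert DEFAULT_MIN_VISITS == 104


def _panel_row(loc, hab, year, month, larvae, nymphs, adults=0):
    return dict(location=loc, habitat=hab, year=year, month=month,
                n_visits=1, larvae=larvae, nymphs=nymphs, adults=adults,
                lag_log_larvae=np.nan, lag_log_nymphs=np.nan)


def test_attach_lags_consecutive_and_gap():
    panel = pd.DataFrame([
        _panel_row("A", "edge", 2010, 3, 10, 2),
        _panel_row("A", "edge", 2010, 4, 5, 1),
        _panel_row("A", "edge", 2010, 6, 7, 3),   # gap: May unsampled
    ])
    out = attach_lags(panel)
    assert np.isnan(out.loc[0, "lag_log_larvae"])
    assert out.loc[1, "lag_log_larvae"] == pytest.approx(math.log1p(10))
    assert out.loc[1, "lag_log_nymphs"] == pytest.approx(math.log1p(2))
    assert np.isnan(out.loc[2, "lag_log_larvae"])


def test_attach_lags_arithmetic_example():
    """Nov-Dec-Jan series with larvae (2, 0, 5): lags are
    (missing, log 3, log 1 = 0)."""
    panel = pd.DataFrame([
        _panel_row("A", "edge", 2009, 11, 2, 0),
        _panel_row("A", "edge", 2009, 12, 0, 0),
        _panel_row("A", "edge", 2010, 1, 5, 0),
    ])
    out = attach_lags(panel)
    lags = out["lag_log_larvae"].tolist()
    assert np.isnan(lags[0])
    assert lags[1] == pytest.approx(math.log(3), abs=1e-12)
    assert lags[2] == pytest.approx(0.0, abs=1e-12)


def test_attach_lags_december_to_january():
    panel = pd.DataFrame([
        _panel_row("A", "grass", 2010, 12, 4, 9),
        _panel_row("A", "grass", 2011, 1, 2, 2),
    ])
    out = attach_lags(panel)
    jan = out[(out["year"] == 2011)].iloc[0]
    assert jan["lag_log_larvae"] == pytest.approx(math.log1p(4))
    assert jan["lag_log_nymphs"] == pytest.approx(math.log1p(9))


def test_attach_lags_does_not_cross_series():
    panel = pd.DataFrame([
        _panel_row("A", "edge", 2010, 3, 10, 2),
        _panel_row("A", "grass", 2010, 4, 5, 1),
    ])
    out = attach_lags(panel)
    assert out["lag_log_larvae"].isna().all()


def test_attach_lags_idempotent(small_panel):
    panel, _ = small_panel
    again = attach_lags(panel)
    pd.testing.assert_frame_equal(again, attach_lags(again))


@given(st.lists(st.tuples(st.integers(2009, 2012), st.integers(1, 12),
                          st.integers(0, 50), st.integers(0, 20)),
                min_size=1, max_size=40, unique_by=lambda t: (t[0], t[1])))
def test_attach_lags_property(series):
    """Lag is defined iff the previous calendar month exists in the series,
    and then equals log1p of that month's count."""
    panel = pd.DataFrame([_panel_row("X", "woods", y, m, l, n)
                          for y, m, l, n in series])
    out = attach_lags(panel)
    serial = out["year"].to_numpy() * 12 + out["month"].to_numpy() - 1
    by_serial = {s: i for i, s in enumerate(serial)}
    for i, s in enumerate(serial):
        j = by_serial.get(s - 1)
        if j is None:
            assert np.isnan(out.loc[i, "lag_log_larvae"])
        else:
            assert out.loc[i, "lag_log_larvae"] == pytest.approx(
                math.log1p(out.loc[j, "larvae"]))
            assert out.loc[i, "lag_log_nymphs"] == pytest.approx(
                math.log1p(out.loc[j, "nymphs"]))


def test_panel_csv_round_trip(tmp_path, small_panel):
    panel, _ = small_panel
    path = tmp_path / "panel.csv"
    write_panel_csv(panel, path)
    back = read_panel_csv(path)
    pd.testing.assert_frame_equal(back, panel[PANEL_COLUMNS],
                                  check_exact=False, atol=1e-9)


def test_read_panel_csv_missing_columns(tmp_path):
    path = tmp_path / "bad.csv"
    pd.DataFrame({"location": ["A"]}).to_csv(path, index=False)
    with pytest.raises(SurveyFormatError):
        read_panel_csv(path)
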