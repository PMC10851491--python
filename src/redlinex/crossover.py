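"""Time-stratified bidirectional case-crossover strata.

Each death is compared with itself on referent days: every other day in
the same calendar month falling on the same day of the week (3 or 4 of
them, before and/or after the case).  Matching on month and weekday
controls anything fixed or slowly varying on the month scale as well as
weekly cycles, and drawing referents on both sides of the case removes
exposure time-trend bias.  The redlined flag is constant within a
stratum, so its main effect is absorbed by the design and only its
interaction with time-varying exposure is estimable.

Records pass through a sequential exclusion cascade before strata are
built; each step's count is tallied in a ledger.
"""

from __future__ import annotations

import calendar as _cal
import datetime as dt
import logging
from typing import Sequence

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

#: study window: the Jan 5 start leaves room for lag 4 to reach Jan 1 2001
DEFAULT_STUDY_START = dt.date(2001, 1, 5)
DEFAULT_STUDY_END = dt.date(2016, 12, 31)

#: exposure columns a stratum row must carry without gaps
CORE_COLUMNS = ("pm25", "tmean", "vp", "extreme")

EXCLUSION_STEPS = (
    "external_cause",
    "age_under_18",
    "geocode_missing_or_coarse",
    "out_of_state",
    "outside_study_window",
    "zero_population_block_group",
    "leap_year_lag_window",
)


def referent_dates(case_date) -> list[dt.date]:
    """All other same-weekday dates in the case's calendar month, sorted.

    Calendar months hold 4 or 5 of each weekday, so the referent set has
    3 or 4 members, on both sides of the case when the calendar allows.
    """
    d = pd.Timestamp(case_date).date()
    n_days = _cal.monthrange(d.year, d.month)[1]
    return [
        dt.date(d.year, d.month, dom)
        for dom in range(1, n_days + 1)
        if dom != d.day and (dom - d.day) % 7 == 0
    ]


def _is_internal_cause(codes: pd.Series) -> pd.Series:
    """ICD-10 A00-R99 (deaths from internal causes)."""
    return codes.astype(str).str.match(r"^[A-R]\d{2}")


def _touches_leap_dec31(dates: pd.Series, max_lag: int = 4) -> pd.Series:
    """True when any lag 0..max_lag falls on December 31 of a leap year,
    a day absent from the 365-day meteorology calendar."""
    out = np.zeros(len(dates), dtype=bool)
    ts = pd.to_datetime(dates)
    for lag in range(max_lag + 1):
        lagged = ts - pd.Timedelta(days=lag)
        out |= (
            (lagged.dt.month == 12)
            & (lagged.dt.day == 31)
            & lagged.dt.is_leap_year
        ).to_numpy()
    return pd.Series(out, index=dates.index)


def apply_exclusions(
    records: pd.DataFrame,
    bg_population: pd.Series,
    study_start: dt.date = DEFAULT_STUDY_START,
    study_end: dt.date = DEFAULT_STUDY_END,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Sequential record-exclusion cascade with an accounting ledger.

    Steps, in order: deaths from external causes (outside ICD A00-R99);
    age under 18; geocode missing or coarser than block group; home block
    group outside the reporting state; death outside the study window;
    home block group with zero decennial population; and death dates
    whose lag 0-4 window touches a leap-year December 31.

    Returns ``(kept_records, ledger)`` where the ledger has one row per
    step with the count excluded there and the count remaining.
    """
    df = records.copy()
    df["death_date"] = pd.to_datetime(df["death_date"])
    geoid = df["geoid12"].astype(str)
    geoid_ok = geoid.str.len().eq(12) & geoid.str.isdigit()
    pop = pd.Series(bg_population)

    masks = {
        "external_cause": ~_is_internal_cause(df["cause_code"]),
        "age_under_18": df["age"] < 18,
        "geocode_missing_or_coarse": df["geoid12"].isna() | ~geoid_ok,
        "out_of_state": geoid.str[:2] != df["state"].astype(str),
        "outside_study_window": (
            df["death_date"] < pd.Timestamp(study_start)
        )
        | (df["death_date"] > pd.Timestamp(study_end)),
        "zero_population_block_group": ~geoid.isin(
            pop[pop > 0].index.astype(str)
        ),
        "leap_year_lag_window": _touches_leap_dec31(df["death_date"]),
    }

    ledger_rows = []
    keep = pd.Series(True, index=df.index)
    for step in EXCLUSION_STEPS:
        hit = keep & masks[step]
        n_excluded = int(hit.sum())
        keep &= ~masks[step]
        ledger_rows.append(
            {
                "step": step,
                "n_excluded": n_excluded,
                "n_remaining": int(keep.sum()),
            }
        )
    ledger = pd.DataFrame(ledger_rows)
    return df.loc[keep].copy(), ledger


def build_strata(
    records: pd.DataFrame,
    panel: pd.DataFrame,
    heat_calendar: pd.DataFrame,
    crosswalk: pd.DataFrame,
    required: Sequence[str] = CORE_COLUMNS,
) -> tuple[pd.DataFrame, dict]:
    """Materialise one case-crossover stratum per surviving record.

    Each stratum holds the case day plus its 3-4 referent days, with the
    exposure row (PM2.5 and its moving averages, tmean, vapor pressure,
    extreme-heat indicators) looked up from the panel and heat calendar
    and the block group's redlined flag attached.  A stratum whose case
    or any referent day lacks an exposure row, or has a gap in one of
    ``required``, is dropped whole and counted.

    Returns ``(strata, report)``: a long frame with record_id, date,
    is_case and covariates, plus a dict of drop counts.
    """
    recs = records.copy()
    recs["death_date"] = pd.to_datetime(recs["death_date"])

    cand = []
    for rid, d, gid in zip(
        recs["record_id"], recs["death_date"], recs["geoid12"].astype(str)
    ):
        dates = [d.date()] + referent_dates(d)
        for day in dates:
            cand.append((rid, gid, pd.Timestamp(day), day == d.date()))
    long = pd.DataFrame(
        cand, columns=["record_id", "geoid12", "date", "is_case"]
    )
    expected = long.groupby("record_id").size()

    panel_cols = [
        c for c in panel.columns if c not in ("geoid12", "date")
    ]
    merged = long.merge(panel, on=["geoid12", "date"], how="left")
    merged = merged.merge(
        heat_calendar, on=["geoid12", "date"], how="left"
    )
    redlined = crosswalk["redlined"]
    merged["redlined"] = (
        merged["geoid12"].map(redlined).astype("boolean")
    )

    n_before = recs["record_id"].nunique()
    bad_geoid = merged["redlined"].isna() | merged[panel_cols[0]].isna()
    has_row = ~bad_geoid
    good_counts = (
        merged.loc[has_row]
        .groupby("record_id")
        .size()
        .reindex(expected.index, fill_value=0)
    )
    complete = good_counts == expected
    ok_ids = set(complete[complete].index)
    gaps = merged[list(required)].isna().any(axis=1)
    gap_ids = set(merged.loc[gaps, "record_id"])
    ok_ids -= gap_ids

    strata = merged[merged["record_id"].isin(ok_ids)].copy()
    strata["redlined"] = strata["redlined"].astype(bool)
    strata = strata.sort_values(["record_id", "date"]).reset_index(drop=True)

    report = {
        "n_records": n_before,
        "n_strata": len(ok_ids),
        "n_dropped_missing_exposure": n_before - len(ok_ids),
    }
    if report["n_dropped_missing_exposure"]:
        log.info(
            "dropped %d strata with missing exposure rows",
            report["n_dropped_missing_exposure"],
        )
    return strata, report
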