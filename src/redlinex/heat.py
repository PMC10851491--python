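"""Locally-defined extreme heat and heat-wave day numbering.

"Extreme" is spatiotemporally local: the cutoff is a percentile (default
95th) of daily minimum temperature computed separately for each block
group and each calendar year, which absorbs regional and temporal
adaptation.  A day is extreme when its tmin meets or exceeds the cutoff.
Runs of two or more consecutive extreme days are heat waves, numbered
1, 2, 3, ... from the run start; isolated extreme days are singletons.

Run detection works on the continuous daily calendar — a wave may cross
Dec 31 -> Jan 1, each day judged against its own year's cutoff — but a
calendar gap (the Daymet-style missing leap-year Dec 31) breaks a run.
"""

from __future__ import annotations

from typing import Iterable

import numpy as np
import pandas as pd

from .exposure import NoDataError

#: percentile choices exercised in sensitivity analyses
SUPPORTED_PERCENTILES: tuple[int, ...] = (85, 90, 95, 99)
#: wave-day positions modelled as separate indicator exposures
WAVE_DAY_INDICATORS: tuple[int, ...] = (1, 2, 3, 4)


def percentile_cutoff(tmin_year: Iterable[float], p: float) -> float:
    """The p-th percentile of one block group-year of daily tmin.

    Linear interpolation between closest order statistics (the numpy
    default), fixed here so indicator construction is reproducible.
    """
    x = np.asarray(list(tmin_year), dtype=float)
    x = x[~np.isnan(x)]
    if x.size == 0:
        raise NoDataError("cannot take a percentile of an empty tmin series")
    return float(np.percentile(x, p))


def extreme_indicators(tmin: Iterable[float], cutoff: float) -> np.ndarray:
    """Boolean per-day indicator: tmin met or exceeded the cutoff (>=)."""
    if not np.isfinite(cutoff):
        raise ValueError(f"cutoff must be finite, got {cutoff}")
    return np.asarray(list(tmin), dtype=float) >= cutoff


def wave_days(extreme: Iterable[bool]) -> tuple[np.ndarray, np.ndarray]:
    """Number heat-wave days within runs of consecutive extreme days.

    Returns ``(wave_day, singleton)``: ``wave_day`` is NaN off-wave and
    1..L within each run of length L >= 2; ``singleton`` flags isolated
    extreme days (run length 1), which carry no wave-day number.
    """
    e = np.asarray(list(extreme), dtype=bool)
    n = e.size
    wave = np.full(n, np.nan)
    singleton = np.zeros(n, dtype=bool)
    if n == 0:
        return wave, singleton
    # run starts: extreme day not preceded by an extreme day
    starts = np.flatnonzero(e & ~np.r_[False, e[:-1]])
    ends = np.flatnonzero(e & ~np.r_[e[1:], False])
    for s, t in zip(starts, ends):
        length = t - s + 1
        if length >= 2:
            wave[s : t + 1] = np.arange(1, length + 1)
        else:
            singleton[s] = True
    return wave, singleton


def build_heat_calendar(
    panel: pd.DataFrame, p: float = 95
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-(block group, day) extreme-heat indicators and wave numbering.

    ``panel`` is the long exposure panel with columns geoid12, date, tmin.
    Returns ``(calendar, cutoffs)``: the calendar frame has columns
    geoid12, date, extreme, wave_day, singleton; the cutoff table has one
    row per (geoid12, year).
    """
    rows = []
    cuts = []
    for gid, grp in panel.sort_values("date").groupby("geoid12", sort=False):
        dates = pd.DatetimeIndex(grp["date"])
        tmin = grp["tmin"].to_numpy(float)
        years = dates.year.to_numpy()
        cutoff_by_year = {
            int(y): percentile_cutoff(tmin[years == y], p)
            for y in np.unique(years)
        }
        cutoffs = np.array([cutoff_by_year[int(y)] for y in years])
        ext = tmin >= cutoffs
        # a calendar gap (missing leap-year Dec 31) breaks consecutiveness
        gap = np.r_[False, np.diff(dates.to_numpy()) != np.timedelta64(1, "D")]
        wave = np.full(ext.size, np.nan)
        singleton = np.zeros(ext.size, dtype=bool)
        seg_start = 0
        for i in range(1, ext.size + 1):
            if i == ext.size or gap[i]:
                w, s = wave_days(ext[seg_start:i])
                wave[seg_start:i] = w
                singleton[seg_start:i] = s
                seg_start = i
        rows.append(
            pd.DataFrame(
                {
                    "geoid12": gid,
                    "date": dates,
                    "extreme": ext,
                    "wave_day": wave,
                    "singleton": singleton,
                }
            )
        )
        cuts.extend(
            {"geoid12": gid, "year": y, "p": p, "cutoff": c}
            for y, c in cutoff_by_year.items()
        )
    calendar = pd.concat(rows, ignore_index=True)
    return calendar, pd.DataFrame(cuts)
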