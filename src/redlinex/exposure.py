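"""Daily gridded exposures assigned to Census block groups.

Three aggregation rules, each convex in its inputs:

* PM2.5 follows the block route: a block's value is the mean over the
  1-km grid-cell centroids its polygon contains; a block containing no
  centroid takes the Euclidean-nearest centroid's value; block-group
  values are the population-weighted mean of member blocks.
* Meteorology (tmin, tmax, vapor pressure) follows the areal route: the
  block-group value is the average of intersecting grid cells weighted by
  intersection area, cells modelled as squares centred on their centroid
  with side equal to the grid pitch.
* Daily mean temperature is (tmin + tmax) / 2.

The daily calendar mirrors the Daymet convention of 365-day years:
December 31 does not exist in leap years.  Moving averages over lags
0..k-1 are therefore missing whenever the window touches a dropped day.
"""

from __future__ import annotations

import datetime as dt
import logging
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd
import shapely
from shapely.strtree import STRtree

from .geography import ZeroPopulationError

log = logging.getLogger(__name__)

MOVING_AVERAGE_WINDOWS: tuple[int, ...] = (2, 3, 4, 5)


class NoDataError(ValueError):
    """Raised when an aggregation has no grid data to aggregate."""


def daymet_calendar(start_year: int, end_year: int) -> pd.DatetimeIndex:
    """All days from Jan 1 ``start_year`` to Dec 31 ``end_year``, minus
    December 31 of leap years (365-day Daymet-style years)."""
    days = pd.date_range(
        dt.date(start_year, 1, 1), dt.date(end_year, 12, 31), freq="D"
    )
    drop = (days.month == 12) & (days.day == 31) & days.is_leap_year
    return days[~drop]


@dataclass
class Grid:
    """Gridded daily values on a square lattice of cells.

    ``cells`` is indexed by cell_id with columns x, y (planar centroid
    coordinates); each entry of ``values`` maps a variable name to a
    (date x cell_id) frame sharing the cells' column order.
    """

    cells: pd.DataFrame
    pitch: float
    values: dict[str, pd.DataFrame] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.cells) == 0:
            raise NoDataError("grid has no cells")
        for var, frame in self.values.items():
            if list(frame.columns) != list(self.cells.index):
                self.values[var] = frame.reindex(columns=self.cells.index)

    def footprints(self) -> np.ndarray:
        """Square cell footprints (side = pitch) centred on centroids."""
        h = self.pitch / 2.0
        x = self.cells["x"].to_numpy(float)
        y = self.cells["y"].to_numpy(float)
        return shapely.box(x - h, y - h, x + h, y + h)

    def centroid_points(self) -> np.ndarray:
        return shapely.points(
            self.cells["x"].to_numpy(float), self.cells["y"].to_numpy(float)
        )


def assign_grid_to_blocks(
    grid: Grid,
    block_polygons: pd.Series,
    block_centroids: pd.DataFrame,
    variable: str,
) -> pd.DataFrame:
    """Daily block values: mean over grid centroids inside each block
    polygon, falling back to the nearest centroid for empty blocks.

    ``block_polygons`` is a Series of shapely polygons indexed by geoid15;
    ``block_centroids`` has columns x, y on the same index.  Returns a
    (date x geoid15) frame.
    """
    if variable not in grid.values:
        raise NoDataError(f"grid has no values for variable {variable!r}")
    pts = grid.centroid_points()
    tree = STRtree(pts)
    vals = grid.values[variable].to_numpy(float)  # (n_dates, n_cells)

    out = np.empty((vals.shape[0], len(block_polygons)))
    polys = block_polygons.to_numpy()
    poly_i, pt_i = tree.query(polys, predicate="covers")  # boundary counts
    members: list[list[int]] = [[] for _ in range(len(polys))]
    for bi, ci in zip(poly_i, pt_i):
        members[bi].append(ci)
    n_fallback = 0
    for bi, cells in enumerate(members):
        if cells:
            out[:, bi] = vals[:, cells].mean(axis=1)
        else:
            gid = block_polygons.index[bi]
            p = shapely.Point(
                float(block_centroids.loc[gid, "x"]),
                float(block_centroids.loc[gid, "y"]),
            )
            out[:, bi] = vals[:, int(tree.nearest(p))]
            n_fallback += 1
    if n_fallback:
        log.info(
            "%d blocks contained no grid centroid; used nearest-centroid fallback",
            n_fallback,
        )
    return pd.DataFrame(
        out, index=grid.values[variable].index, columns=block_polygons.index
    )


def blocks_to_bg_popweighted(
    block_values: pd.DataFrame, block_populations: pd.Series
) -> pd.DataFrame:
    """Population-weighted mean of block values per block group.

    Columns of ``block_values`` are 15-digit block GEOIDs; the parent
    block group is their 12-character prefix.  Raises
    :class:`ZeroPopulationError` if any block group has zero total weight.
    """
    pops = block_populations.reindex(block_values.columns)
    if pops.isna().any():
        raise ValueError("every block column needs a population")
    geoid12 = block_values.columns.astype(str).str[:12]
    totals = pops.groupby(geoid12).sum()
    empty = totals[totals <= 0]
    if len(empty):
        raise ZeroPopulationError(
            f"block groups with zero population: {list(empty.index)[:5]}"
        )
    weighted = block_values.mul(pops.to_numpy(), axis=1)
    num = weighted.T.groupby(geoid12).sum().T
    return num.div(totals, axis=1)


def grid_to_bg_areaweighted(
    grid: Grid, bg_polygons: pd.Series, variable: str
) -> pd.DataFrame:
    """Areal-weighted mean of grid-cell values per block-group polygon.

    Weights are the areas of intersection between each square cell
    footprint and the block-group polygon.  Returns (date x geoid12).
    """
    if variable not in grid.values:
        raise NoDataError(f"grid has no values for variable {variable!r}")
    boxes = grid.footprints()
    tree = STRtree(boxes)
    vals = grid.values[variable].to_numpy(float)
    out = np.empty((vals.shape[0], len(bg_polygons)))
    for bi, (gid, poly) in enumerate(bg_polygons.items()):
        cand = tree.query(poly, predicate="intersects")
        if len(cand) == 0:
            raise NoDataError(f"block group {gid} intersects no grid cell")
        areas = shapely.area(shapely.intersection(boxes[cand], poly))
        w = areas / areas.sum()
        if areas.sum() <= 0:
            raise NoDataError(f"block group {gid} has zero intersection area")
        out[:, bi] = vals[:, cand] @ w
    return pd.DataFrame(
        out, index=grid.values[variable].index, columns=bg_polygons.index
    )


def moving_average(series: pd.Series, date, k: int) -> float:
    """Unweighted mean of the values at lags 0..k-1 before ``date``.

    Returns NaN when any lagged day is absent from the series — in
    particular when a lag falls on a leap-year December 31 under the
    365-day calendar.
    """
    if not 1 <= k <= 5:
        raise ValueError(f"window k must be in 1..5, got {k}")
    date = pd.Timestamp(date)
    wanted = pd.date_range(end=date, periods=k, freq="D")
    vals = series.reindex(wanted)
    if vals.isna().any():
        return float("nan")
    return float(vals.mean())


def add_moving_averages(
    panel: pd.DataFrame,
    column: str = "pm25",
    windows: Iterable[int] = MOVING_AVERAGE_WINDOWS,
) -> pd.DataFrame:
    """Append ``<column>_ma_k`` moving averages to a (geoid12, date) panel.

    The panel's calendar may already be missing leap-year Dec 31; the
    rolling mean is computed over the continuous daily calendar so any
    absent lag propagates as missing.
    """
    panel = panel.sort_values(["geoid12", "date"])
    out = []
    for gid, grp in panel.groupby("geoid12", sort=False):
        s = grp.set_index("date")[column]
        full = s.reindex(pd.date_range(s.index.min(), s.index.max(), freq="D"))
        g = grp.copy()
        for k in windows:
            ma = full.rolling(window=k, min_periods=k).mean()
            g[f"{column}_ma_{k}"] = ma.reindex(g["date"]).to_numpy()
        out.append(g)
    return pd.concat(out, ignore_index=True)


def build_panel(
    grid: Grid,
    block_polygons: pd.Series,
    block_centroids: pd.DataFrame,
    block_populations: pd.Series,
    bg_polygons: pd.Series,
) -> pd.DataFrame:
    """Assemble the block-group daily exposure panel.

    PM2.5 travels grid -> blocks (centroid containment with nearest
    fallback) -> block groups (population-weighted); tmin/tmax/vapor
    pressure travel grid -> block groups (areal-weighted).  Output is a
    long frame keyed by (geoid12, date) with pm25, tmin, tmax, tmean, vp
    and pm25 moving averages for 2..5-day windows.
    """
    pm_blocks = assign_grid_to_blocks(grid, block_polygons, block_centroids, "pm25")
    pm_bg = blocks_to_bg_popweighted(pm_blocks, block_populations)

    met = {
        var: grid_to_bg_areaweighted(grid, bg_polygons, var)
        for var in ("tmin", "tmax", "vp")
    }
    frames = {"pm25": pm_bg, **met}
    long = pd.concat(
        {k: v.stack() for k, v in frames.items()}, axis=1
    ).reset_index()
    long.columns = ["date", "geoid12", "pm25", "tmin", "tmax", "vp"]
    long["tmean"] = (long["tmin"] + long["tmax"]) / 2.0
    long = long[["geoid12", "date", "pm25", "tmin", "tmax", "tmean", "vp"]]
    return add_moving_averages(long)
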