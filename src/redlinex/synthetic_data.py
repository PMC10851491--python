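"""Synthetic city, exposures and mortality with known ground truth.

Everything the real pipeline consumes can be generated here with a known
generative model, so each stage — apportionment, exposure assignment,
heat calendars, strata, model fitting — is testable end-to-end without
restricted mortality data.

The city is a rectangular lattice of square block groups with an inner
HOLC-graded core (quadrants graded A-D plus a sliver of the undocumented
grade E) deliberately offset from the Census lattice so that grade
apportionment is non-trivial.  Daily weather is an annual sinusoid plus
AR(1) noise shared city-wide; vapor pressure tracks temperature; PM2.5
is log-normal AR(1) with an additive offset inside redlined polygons and
a warm-season urban-heat excess in redlined minimum temperature.

Mortality cases are drawn *within referent strata*: a block group and a
month/weekday stratum are chosen, and the death day is drawn among that
stratum's days with probability proportional to exp(eta), where eta is
the same linear predictor the conditional-logit models estimate.  The
estimator is therefore exactly correctly specified and parameter
recovery is a sharp test of the fitting code.  A per-day Bernoulli
hazard mode is available to demonstrate the (small) bias that
bidirectional sampling induces through post-death referents.

The true confounder effects of TMEAN and VP are linear; linear functions
lie in the span of any natural-spline basis plus intercept, so spline
adjustment in the fitted models introduces no approximation error.
"""

from __future__ import annotations

import datetime as dt
import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import shapely

from . import crossover, geography, heat
from .exposure import Grid, add_moving_averages, daymet_calendar
from .geography import HOLCPolygon

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class TrueEffects:
    """Ground-truth log-odds effects of the generative model.

    PM2.5 terms are per 10 ug/m3; heat terms per extreme-heat day; tmean
    and vp are linear nuisance effects per degree C and per kPa.  The
    interaction magnitudes default to the order of the published
    estimates (a calibration, not a reproduction).
    """

    pm25_per10: float = math.log(1.01)
    pm25_x_redlined_per10: float = math.log(1.01)
    heat: float = math.log(1.03)
    heat_x_redlined: float = math.log(1.02)
    tmean: float = -0.004
    vp: float = 0.03


@dataclass
class SimConfig:
    """Study conditions for one synthetic run; the seed fixes every draw."""

    seed: int = 0
    # --- city geometry (km, planar) ---
    n_bg_side: int = 8          # city is n x n block groups
    core_side: int = 4          # HOLC-graded core is core x core BGs
    blocks_per_bg_side: int = 2
    bg_size: float = 2.0
    grid_pitch: float = 1.0
    holc_offset: float = 0.3    # shift of HOLC patches off the Census lattice
    state_fips: str = "25"
    # --- study period and cases ---
    years: tuple[int, int] = (2001, 2004)
    n_cases: int = 5000
    # --- climate ---
    tmean_annual: float = 12.0
    seasonal_amp: float = 11.0
    diurnal_range: float = 8.0
    ar1_phi: float = 0.75
    temp_sd: float = 2.5
    # --- air pollution ---
    pm25_median: float = 9.0
    pm25_log_sd: float = 0.35
    pm25_ar1_phi: float = 0.6
    redlined_pm25_offset: float = 1.3   # ug/m3, echoing the observed contrast
    redlined_tmin_offset: float = 0.5   # deg C urban-heat-island excess
    # --- generative model ---
    beta_true: TrueEffects = field(default_factory=TrueEffects)
    generator_model: str = "both"          # "pm25" | "heat" | "both"
    case_sampling: str = "stratum_softmax"  # or "daily_bernoulli"
    heat_percentile: float = 95.0

    def rng(self, stage: int) -> np.random.Generator:
        return np.random.default_rng([self.seed, stage])


@dataclass
class Geography:
    """Synthetic city geometries and static attributes."""

    blocks: pd.DataFrame            # geoid15, x, y, population
    block_polygons: pd.Series       # geoid15 -> polygon
    bg_polygons: pd.Series          # geoid12 -> polygon
    holc: list[HOLCPolygon]
    bg_demographics: pd.DataFrame   # geoid12 -> prop_black, prop_white
    state_fips: str


# ---------------------------------------------------------------------------
# geography


def gen_geography(config: SimConfig) -> Geography:
    """Lay out the synthetic city; deterministic under the config seed."""
    rng = config.rng(0)
    s, b = config.n_bg_side, config.blocks_per_bg_side
    size = config.bg_size
    sub = size / b

    bg_ids, bg_polys = [], []
    blk_ids, blk_polys, xs, ys, pops = [], [], [], [], []
    for i in range(s):
        for j in range(s):
            idx = i * s + j
            geoid12 = f"{config.state_fips}025{idx:07d}"
            x0, y0 = j * size, i * size
            bg_ids.append(geoid12)
            bg_polys.append(shapely.box(x0, y0, x0 + size, y0 + size))
            for bi in range(b):
                for bj in range(b):
                    bx0, by0 = x0 + bj * sub, y0 + bi * sub
                    cx = bx0 + sub / 2 + rng.uniform(-0.2, 0.2) * sub
                    cy = by0 + sub / 2 + rng.uniform(-0.2, 0.2) * sub
                    blk_ids.append(f"{geoid12}{bi * b + bj:03d}")
                    blk_polys.append(shapely.box(bx0, by0, bx0 + sub, by0 + sub))
                    xs.append(cx)
                    ys.append(cy)
                    pops.append(max(1, int(rng.lognormal(math.log(250), 0.5))))

    blocks = pd.DataFrame(
        {"geoid15": blk_ids, "x": xs, "y": ys, "population": pops}
    )
    block_polygons = pd.Series(blk_polys, index=blk_ids, name="geometry")
    bg_polygons = pd.Series(bg_polys, index=bg_ids, name="geometry")

    # HOLC core: quadrants graded A/B/C/D, shifted off the Census lattice
    lo = (s - config.core_side) / 2 * size + config.holc_offset
    half = config.core_side / 2 * size
    hi = lo + 2 * half
    mid = lo + half
    quads = {
        "A": shapely.box(lo, mid, mid, hi),
        "B": shapely.box(mid, mid, hi, hi),
        "C": shapely.box(lo, lo, mid, mid),
        "D": shapely.box(mid, lo, hi, mid),
    }
    holc = [HOLCPolygon(grade=g, geometry=geom) for g, geom in quads.items()]
    # a sliver of the undocumented grade E along the core's west edge
    holc.append(
        HOLCPolygon(grade="E", geometry=shapely.box(lo - 0.4, lo, lo, mid))
    )

    d_poly = quads["D"]
    centers = shapely.centroid(np.asarray(bg_polys, dtype=object))
    in_d = shapely.intersects(centers, d_poly)
    prop_black = np.where(
        in_d,
        rng.uniform(0.5, 0.75, len(bg_ids)),
        rng.uniform(0.05, 0.25, len(bg_ids)),
    )
    bg_demographics = pd.DataFrame(
        {
            "prop_black": prop_black,
            "prop_white": np.clip(0.97 - prop_black, 0, 1),
        },
        index=pd.Index(bg_ids, name="geoid12"),
    )
    return Geography(
        blocks=blocks,
        block_polygons=block_polygons,
        bg_polygons=bg_polygons,
        holc=holc,
        bg_demographics=bg_demographics,
        state_fips=config.state_fips,
    )


# ---------------------------------------------------------------------------
# exposures


def _ar1(rng: np.random.Generator, n: int, phi: float, sd: float) -> np.ndarray:
    z = np.empty(n)
    z[0] = rng.normal(0, sd)
    eps = rng.normal(0, sd * math.sqrt(1 - phi**2), n)
    for t in range(1, n):
        z[t] = phi * z[t - 1] + eps[t]
    return z


def _daily_fields(
    config: SimConfig,
    rng: np.random.Generator,
    dates: pd.DatetimeIndex,
    redlined_unit: np.ndarray,
) -> dict[str, np.ndarray]:
    """Daily (date x unit) fields for tmin/tmax/vp/pm25.

    ``redlined_unit`` flags the spatial units (grid cells or block
    groups) receiving the planted redlined offsets.
    """
    n_d, n_u = len(dates), len(redlined_unit)
    doy = dates.day_of_year.to_numpy()
    seasonal = config.tmean_annual + config.seasonal_amp * np.sin(
        2 * np.pi * (doy - 105) / 365.25
    )
    city_t = _ar1(rng, n_d, config.ar1_phi, config.temp_sd)
    unit_t_offset = rng.normal(0, 0.3, n_u)
    local = rng.normal(0, 0.4, (n_d, n_u))

    tmean = seasonal[:, None] + city_t[:, None] + unit_t_offset[None, :] + local
    half_range = config.diurnal_range / 2 + rng.normal(0, 0.5, (n_d, n_u))
    tmin = tmean - np.abs(half_range)
    tmin = tmin + config.redlined_tmin_offset * redlined_unit[None, :]
    tmax = tmean + np.abs(half_range)

    rh = np.clip(0.55 + 0.08 * _ar1(rng, n_d, 0.7, 1.0), 0.2, 1.0)
    sat_vp = 0.611 * np.exp(17.27 * tmean / (tmean + 237.3))  # kPa
    vp = np.clip(sat_vp * rh[:, None] + rng.normal(0, 0.02, (n_d, n_u)), 0.01, None)

    city_pm = _ar1(rng, n_d, config.pm25_ar1_phi, 1.0)
    unit_pm = rng.normal(0, 0.1, n_u)
    pm = np.exp(
        math.log(config.pm25_median)
        + config.pm25_log_sd * (city_pm[:, None] + rng.normal(0, 0.5, (n_d, n_u)))
        + unit_pm[None, :]
    )
    pm = pm + config.redlined_pm25_offset * redlined_unit[None, :]
    return {
        "tmin": tmin,
        "tmax": tmax,
        "vp": vp,
        "pm25": np.clip(pm, 0.05, None),
    }


def gen_exposures(config: SimConfig, geo: Geography) -> Grid:
    """Gridded daily tmin/tmax/vp/PM2.5 on a 365-day-year calendar."""
    rng = config.rng(1)
    extent = config.n_bg_side * config.bg_size
    pitch = config.grid_pitch
    n = int(round(extent / pitch))
    cx, cy = np.meshgrid(
        (np.arange(n) + 0.5) * pitch, (np.arange(n) + 0.5) * pitch
    )
    cells = pd.DataFrame(
        {"x": cx.ravel(), "y": cy.ravel()},
        index=pd.Index(range(n * n), name="cell_id"),
    )
    d_polys = [h.geometry for h in geo.holc if h.grade == "D"]
    pts = shapely.points(cells["x"].to_numpy(), cells["y"].to_numpy())
    redlined_cell = np.zeros(len(cells), dtype=bool)
    for p in d_polys:
        redlined_cell |= shapely.intersects(pts, p)

    dates = daymet_calendar(*config.years)
    fields = _daily_fields(config, rng, dates, redlined_cell.astype(float))
    values = {
        var: pd.DataFrame(arr, index=dates, columns=cells.index)
        for var, arr in fields.items()
    }
    return Grid(cells=cells, pitch=pitch, values=values)


def redlined_flags(config: SimConfig, geo: Geography, threshold: float = 0.9) -> pd.Series:
    """Block-group redlined flags via the population-apportionment crosswalk."""
    bins = geography.bin_population(geo.blocks, geo.holc)
    xwalk = geography.assign_grades(bins, threshold)
    return xwalk["redlined"].reindex(geo.bg_polygons.index).fillna(False)


def gen_bg_panel(
    config: SimConfig, redlined: pd.Series, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Block-group exposure panel generated directly, skipping the grid.

    Statistical testbed shortcut for model-scale simulations: the same
    daily field model is drawn with one series per block group instead of
    per grid cell, so panels are cheap enough for replicated studies.
    """
    rng = config.rng(1) if rng is None else rng
    dates = daymet_calendar(*config.years)
    red = redlined.astype(bool)
    fields = _daily_fields(config, rng, dates, red.to_numpy(float))
    long = pd.DataFrame(
        {
            "geoid12": np.tile(red.index.to_numpy(), len(dates)),
            "date": np.repeat(dates.to_numpy(), len(red)),
            "pm25": fields["pm25"].ravel(),
            "tmin": fields["tmin"].ravel(),
            "tmax": fields["tmax"].ravel(),
            "vp": fields["vp"].ravel(),
        }
    )
    long["tmean"] = (long["tmin"] + long["tmax"]) / 2.0
    return add_moving_averages(long)


# ---------------------------------------------------------------------------
# cases


def _eta(
    config: SimConfig,
    pm25: np.ndarray,
    tmean: np.ndarray,
    vp: np.ndarray,
    extreme: np.ndarray,
    redlined: np.ndarray,
) -> np.ndarray:
    b = config.beta_true
    eta = b.vp * vp
    mode = config.generator_model
    if mode not in ("pm25", "heat", "both"):
        raise ValueError(f"unknown generator_model {mode!r}")
    if mode in ("pm25", "both"):
        eta = eta + (pm25 / 10.0) * (
            b.pm25_per10 + b.pm25_x_redlined_per10 * redlined
        )
        eta = eta + b.tmean * tmean
    if mode in ("heat", "both"):
        eta = eta + extreme * (b.heat + b.heat_x_redlined * redlined)
    return eta


_RACE = {
    False: (("White", 0.863), ("Black", 0.097), ("Other", 0.036), ("Unknown", 0.004)),
    True: (("White", 0.537), ("Black", 0.388), ("Other", 0.072), ("Unknown", 0.003)),
}
_EDUCATION = (("less_than_hs", 0.221), ("hs", 0.412), ("more_than_hs", 0.325),
              ("unknown", 0.042))
_CAUSES = ("I21", "I25", "I63", "C34", "C50", "J44", "E11", "G30", "N18", "R99")


def _demographics(
    rng: np.random.Generator, redlined: np.ndarray
) -> dict[str, np.ndarray]:
    n = redlined.size
    out: dict[str, np.ndarray] = {}
    out["age"] = np.clip(np.round(rng.normal(75.96, 14.68, n)), 18, 105).astype(int)
    out["sex"] = rng.choice(["M", "F"], n, p=[0.4865, 0.5135])
    race = np.empty(n, dtype=object)
    for flag in (False, True):
        idx = np.flatnonzero(redlined == flag)
        labels, probs = zip(*_RACE[flag])
        race[idx] = rng.choice(labels, idx.size, p=np.asarray(probs) / sum(probs))
    out["race"] = race
    labels, probs = zip(*_EDUCATION)
    out["education"] = rng.choice(labels, n, p=np.asarray(probs) / sum(probs))
    out["cause_code"] = rng.choice(_CAUSES, n)
    return out


def gen_cases(
    config: SimConfig,
    panel: pd.DataFrame,
    heat_calendar: pd.DataFrame,
    redlined: pd.Series,
    n_cases: int | None = None,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Draw mortality records whose death days follow the true model.

    In the default ``stratum_softmax`` mode each case draws a block group
    (population-proportional is unnecessary here: uniform over block
    groups), a month/weekday referent stratum, and then its death day
    among the stratum's available days with probability proportional to
    exp(eta).  The ``daily_bernoulli`` mode instead draws Poisson death
    counts per block group-day with hazard proportional to exp(eta).
    """
    rng = config.rng(2) if rng is None else rng
    n_cases = config.n_cases if n_cases is None else n_cases

    merged = panel.merge(
        heat_calendar[["geoid12", "date", "extreme"]], on=["geoid12", "date"]
    )
    bgs = redlined.index.to_numpy()
    red = redlined.astype(bool)

    piv = {
        var: merged.pivot(index="geoid12", columns="date", values=var)
        .reindex(bgs)
        for var in ("pm25", "tmean", "vp", "extreme")
    }
    dates = piv["pm25"].columns
    date_pos = {d: i for i, d in enumerate(dates)}
    arr = {k: v.to_numpy(float) for k, v in piv.items()}
    red_arr = red.reindex(bgs).to_numpy(float)

    if config.case_sampling == "daily_bernoulli":
        eta = _eta(
            config,
            arr["pm25"],
            arr["tmean"],
            arr["vp"],
            arr["extreme"],
            red_arr[:, None],
        )
        lam = np.exp(eta)
        lam *= n_cases / lam.sum()
        counts = rng.poisson(lam)
        bg_i, day_i = np.nonzero(counts)
        reps = counts[bg_i, day_i]
        bg_idx = np.repeat(bg_i, reps)
        death = np.repeat(dates.to_numpy()[day_i], reps)
    elif config.case_sampling == "stratum_softmax":
        # stratum = (year, month, weekday); candidates are that month's
        # same-weekday days present on the 365-day calendar
        strata_dates: dict[tuple[int, int, int], list] = {}
        for d in dates:
            ts = pd.Timestamp(d)
            strata_dates.setdefault(
                (ts.year, ts.month, ts.dayofweek), []
            ).append(d)
        keys = list(strata_dates)
        key_of_case = rng.integers(0, len(keys), n_cases)
        bg_idx = rng.integers(0, len(bgs), n_cases)
        death = np.empty(n_cases, dtype="datetime64[ns]")
        for ki in np.unique(key_of_case):
            cand = strata_dates[keys[ki]]
            cols = [date_pos[d] for d in cand]
            rows = np.flatnonzero(key_of_case == ki)
            b = bg_idx[rows]
            eta = _eta(
                config,
                arr["pm25"][np.ix_(b, cols)],
                arr["tmean"][np.ix_(b, cols)],
                arr["vp"][np.ix_(b, cols)],
                arr["extreme"][np.ix_(b, cols)],
                red_arr[b][:, None],
            )
            gumbel = rng.gumbel(size=eta.shape)
            pick = np.argmax(eta + gumbel, axis=1)
            death[rows] = np.asarray(cand)[pick]
    else:
        raise ValueError(f"unknown case_sampling {config.case_sampling!r}")

    geoid = bgs[bg_idx]
    demo = _demographics(rng, red.reindex(geoid).to_numpy())
    records = pd.DataFrame(
        {
            "record_id": [f"R{i:07d}" for i in range(len(geoid))],
            "death_date": pd.to_datetime(death),
            "geoid12": geoid,
            "age": demo["age"],
            "sex": demo["sex"],
            "race": demo["race"],
            "education": demo["education"],
            "state": pd.Series(geoid).str[:2].to_numpy(),
            "cause_code": demo["cause_code"],
        }
    )
    return records


# ---------------------------------------------------------------------------
# replicated simulation studies


def replicate_interaction_estimates(
    config: SimConfig,
    model_kind: str,
    n_strata: int,
    n_reps: int,
    seed: int,
) -> pd.DataFrame:
    """Repeatedly simulate a study and re-estimate the redlined interaction.

    Each replicate draws fresh exposures and ``n_strata`` cases from the
    generative model matching ``model_kind`` ("pm25" or "heat"), builds
    the case-crossover strata, and fits the corresponding conditional
    logistic model.  Returns one row per converged replicate with the
    interaction estimate, its standard error, and whether the Wald 95%
    interval covered the generative truth.
    """
    from . import model as _model

    cfg = replace(config, generator_model=model_kind, n_cases=n_strata)
    geo = gen_geography(cfg)
    red = redlined_flags(cfg, geo)
    xwalk = pd.DataFrame({"redlined": red.astype(bool)})
    truth = (
        cfg.beta_true.pm25_x_redlined_per10
        if model_kind == "pm25"
        else cfg.beta_true.heat_x_redlined
    )
    spec = (
        _model.ModelSpec.pm25() if model_kind == "pm25" else _model.ModelSpec.heat()
    )
    rows = []
    for r in range(n_reps):
        rng = np.random.default_rng([seed, r])
        panel = gen_bg_panel(cfg, red, rng=rng)
        cal, _ = heat.build_heat_calendar(panel, cfg.heat_percentile)
        records = gen_cases(cfg, panel, cal, red, rng=rng)
        strata, _ = crossover.build_strata(records, panel, cal, xwalk)
        fit = _model.fit_model(strata, spec)
        if not fit.converged:
            log.warning("replicate %d did not converge: %s", r, fit.message)
            continue
        b, se = fit.beta[-1], fit.se[-1]
        rows.append(
            {
                "rep": r,
                "beta_interaction": b,
                "se": se,
                "truth": truth,
                "covered": abs(b - truth) <= 1.959964 * se,
                "n_strata": fit.n_strata,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# file emission: exactly the formats the pipeline consumes


def write_inputs(config: SimConfig, outdir) -> dict[str, Path]:
    """Generate a full synthetic study and write the pipeline input files.

    Emits blocks.csv, holc.geojson, bg_polygons.geojson (as WKT CSV),
    grid_cells.csv, grid_values.parquet and records.csv so the pipeline
    cannot tell synthetic inputs from real ones.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    geo = gen_geography(config)
    grid = gen_exposures(config, geo)

    paths = {
        "blocks": outdir / "blocks.csv",
        "holc": outdir / "holc.geojson",
        "bg_polygons": outdir / "bg_polygons.csv",
        "block_polygons": outdir / "block_polygons.csv",
        "grid_cells": outdir / "grid_cells.csv",
        "grid_values": outdir / "grid_values.parquet",
        "records": outdir / "records.csv",
        "bg_demographics": outdir / "bg_demographics.csv",
    }
    geo.blocks.to_csv(paths["blocks"], index=False)
    geography.write_holc_geojson(geo.holc, paths["holc"])
    pd.DataFrame(
        {"geoid12": geo.bg_polygons.index, "wkt": shapely.to_wkt(geo.bg_polygons.to_numpy())}
    ).to_csv(paths["bg_polygons"], index=False)
    pd.DataFrame(
        {
            "geoid15": geo.block_polygons.index,
            "wkt": shapely.to_wkt(geo.block_polygons.to_numpy()),
        }
    ).to_csv(paths["block_polygons"], index=False)
    cells = grid.cells.reset_index()
    cells["pitch"] = grid.pitch
    cells.to_csv(paths["grid_cells"], index=False)
    long = pd.concat(
        [
            frame.stack().rename("value").reset_index().assign(variable=var)
            for var, frame in grid.values.items()
        ],
        ignore_index=True,
    )
    long.columns = ["date", "cell_id", "value", "variable"]
    long[["cell_id", "date", "variable", "value"]].to_parquet(paths["grid_values"])
    geo.bg_demographics.to_csv(paths["bg_demographics"])

    # the records need the assembled panel; reuse the pipeline building blocks
    from .pipeline import build_study_panel

    panel = build_study_panel(grid, geo)
    cal, _ = heat.build_heat_calendar(panel, config.heat_percentile)
    red = redlined_flags(config, geo)
    records = gen_cases(config, panel, cal, red)
    records.to_csv(paths["records"], index=False)
    return paths
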