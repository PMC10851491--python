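"""End-to-end orchestration: geography -> exposures -> heat -> strata -> fits.

One declarative config (YAML or an in-memory dict) drives everything, so
the run manifest fully determines the outputs; there are no
analysis-affecting command-line-only switches.  Every analysis cell of
the plan — exposure x sensitivity axis x subgroup — is fitted and
written; a cell that cannot be fitted (no strata, non-identifiable
design) is recorded explicitly, never silently skipped.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__, crossover, exposure, geography, heat, model
from .synthetic_data import Geography, SimConfig, TrueEffects, gen_cases, \
    gen_exposures, gen_geography, redlined_flags

log = logging.getLogger(__name__)

PM_EXPOSURES = list(model.PM_EXPOSURES)
HEAT_EXPOSURES = list(model.HEAT_EXPOSURES)


@dataclass
class AnalysisPlan:
    """Grid of analyses to run.

    ``thresholds`` are HOLC population-apportionment cutoffs;
    ``heat_percentiles`` are tmin percentile cutoffs; subgroup axes
    restrict strata by individual race, neighborhood majority, state or
    year.
    """

    thresholds: tuple[float, ...] = (0.9,)
    heat_percentiles: tuple[float, ...] = (95.0,)
    pm_exposures: tuple[str, ...] = tuple(PM_EXPOSURES)
    heat_exposures: tuple[str, ...] = tuple(HEAT_EXPOSURES)
    subgroups: tuple[str, ...] = ("all",)  # all, race:Black, race:White,
    #                                        neighborhood:Black, neighborhood:White,
    #                                        by_state, by_year


def plan_from_dict(d: dict) -> AnalysisPlan:
    kwargs = {k: tuple(v) if isinstance(v, list) else v for k, v in d.items()}
    return AnalysisPlan(**kwargs)


def sim_config_from_dict(d: dict) -> SimConfig:
    d = dict(d)
    if "beta_true" in d:
        d["beta_true"] = TrueEffects(**d["beta_true"])
    if "years" in d:
        d["years"] = tuple(d["years"])
    return SimConfig(**d)


def build_study_panel(grid: exposure.Grid, geo: Geography) -> pd.DataFrame:
    """Assemble the block-group exposure panel from gridded inputs."""
    return exposure.build_panel(
        grid,
        geo.block_polygons,
        geo.blocks.set_index("geoid15")[["x", "y"]],
        geo.blocks.set_index("geoid15")["population"],
        geo.bg_polygons,
    )


def _subgroup_record_mask(
    records: pd.DataFrame, sub: str, demographics: pd.DataFrame
) -> list[tuple[str, pd.Series]]:
    """Expand one subgroup axis into (cell name, record mask) pairs."""
    if sub == "all":
        return [("all", pd.Series(True, index=records.index))]
    if sub.startswith("race:"):
        race = sub.split(":", 1)[1]
        return [(sub, records["race"] == race)]
    if sub.startswith("neighborhood:"):
        race = sub.split(":", 1)[1]
        col = {"Black": "prop_black", "White": "prop_white"}[race]
        majority = demographics.index[demographics[col] >= 0.5]
        return [(sub, records["geoid12"].isin(majority))]
    if sub == "by_state":
        return [
            (f"state:{s}", records["state"] == s)
            for s in sorted(records["state"].unique())
        ]
    if sub == "by_year":
        years = pd.to_datetime(records["death_date"]).dt.year
        return [(f"year:{y}", years == y) for y in sorted(years.unique())]
    raise ValueError(f"unknown subgroup axis {sub!r}")


def _fit_cell(strata: pd.DataFrame, spec: model.ModelSpec) -> dict:
    if strata.empty:
        return {"status": "no_data", "n_strata": 0}
    try:
        res = model.fit_model(strata, spec)
    except (model.DegenerateCovariateError, ValueError) as err:
        return {"status": f"failed: {err}", "n_strata": 0}
    if not res.converged:
        return {"status": f"not_converged: {res.message}", "n_strata": res.n_strata}
    inter = res.interaction
    return {
        "status": "ok",
        "n_strata": res.n_strata,
        "beta_interaction": float(inter["beta"]),
        "se_interaction": float(inter["se"]),
        "or_interaction": float(inter["or"]),
        "ci_low": float(inter["ci_low"]),
        "ci_high": float(inter["ci_high"]),
        "pct_excess": float(inter["pct_excess"]),
    }


def run(config: dict, outdir) -> dict:
    """Execute the full pipeline and write results under ``outdir``.

    ``config`` has keys ``sim`` (SimConfig fields), ``plan``
    (AnalysisPlan fields) and optional ``study_window``
    {start, end}.  Returns the manifest dict (also written as JSON).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sim = sim_config_from_dict(config.get("sim", {}))
    plan = plan_from_dict(config.get("plan", {}))
    window = config.get("study_window", {})
    start = pd.Timestamp(window.get("start", f"{sim.years[0]}-01-05")).date()
    end = pd.Timestamp(window.get("end", f"{sim.years[1]}-12-31")).date()

    log.info("simulating city (seed=%d)", sim.seed)
    geo = gen_geography(sim)
    grid = gen_exposures(sim, geo)
    panel = build_study_panel(grid, geo)

    bins = geography.bin_population(geo.blocks, geo.holc)
    bg_pop = bins["total_population"]

    records = gen_cases(
        sim, panel, heat.build_heat_calendar(panel, sim.heat_percentile)[0],
        redlined_flags(sim, geo), n_cases=sim.n_cases,
    )
    kept, ledger = crossover.apply_exclusions(records, bg_pop, start, end)
    ledger.to_csv(outdir / "exclusion_ledger.csv", index=False)

    results = []
    for threshold in plan.thresholds:
        xwalk = geography.assign_grades(bins, threshold)
        xwalk.to_csv(outdir / f"crosswalk_t{int(threshold * 100)}.csv")
        for p in plan.heat_percentiles:
            cal, cutoffs = heat.build_heat_calendar(panel, p)
            strata, report = crossover.build_strata(kept, panel, cal, xwalk)
            specs = [model.ModelSpec.pm25(e) for e in plan.pm_exposures] + [
                model.ModelSpec.heat(e) for e in plan.heat_exposures
            ]
            for sub in plan.subgroups:
                for cell_name, mask in _subgroup_record_mask(
                    kept, sub, geo.bg_demographics
                ):
                    ids = set(kept.loc[mask, "record_id"])
                    sub_strata = strata[strata["record_id"].isin(ids)]
                    for spec in specs:
                        row = {
                            "threshold": threshold,
                            "heat_percentile": p,
                            "subgroup": cell_name,
                            "exposure": spec.exposure,
                        }
                        row.update(_fit_cell(sub_strata, spec))
                        results.append(row)

    results_df = pd.DataFrame(results)
    results_df.to_csv(outdir / "results.csv", index=False)

    manifest = {
        "package_version": __version__,
        "seed": sim.seed,
        "sim": dataclasses.asdict(sim),
        "plan": dataclasses.asdict(plan),
        "study_window": {"start": str(start), "end": str(end)},
        "n_records_simulated": int(len(records)),
        "n_records_kept": int(len(kept)),
        "n_cells": int(len(results_df)),
        "n_cells_ok": int((results_df["status"] == "ok").sum()),
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest


def load_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}
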