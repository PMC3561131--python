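"""End-to-end pipeline: simulate -> clean -> fit -> evaluate -> habitat ->
traveltime -> overlay -> report.

Each stage reads only files written by earlier stages into the run
directory, so stages can be re-run individually. A run manifest records
the config snapshot, seeds, and a checksum for every file written.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .adjacency import AdjacencyGraph
from .config import PipelineConfig, config_to_dict, load_config
from .disease_mapping import (
    COVARIATES,
    DistrictTable,
    McmcConfig,
    build_adjacency,
    compute_offsets,
    exceedance_probability,
    fit_car_poisson,
    incidence_ratio_summary,
    posterior_incidence,
)
from .geoio import read_feature_collection, write_feature_collection, write_points
from .raster import read_ascii_grid, write_ascii_grid
from .risk_overlay import (
    combine_risk,
    deduplicate_cases,
    habitat_suitability_raster,
    high_risk_districts,
    population_risk_summary,
)
from .smoothing_eval import calibrate_cutoff, compare_methods, raw_incidence, split_periods
from .synthetic_world import (
    CensusUnit,
    generate_district_lattice,
    generate_raster_world,
    sample_car_field,
    sample_case_records,
    sample_covariates,
    sample_yearly_counts,
)
from .travel_time import (
    accumulate_time,
    build_cost_surface,
    categorize_time,
    extract_mean_time,
    population_time_summary,
    rasterize_roads,
    total_time,
    unit_buffer_masks,
)

logger = logging.getLogger("snakerisk")

STAGES = ["simulate", "clean", "fit", "evaluate", "habitat", "traveltime",
          "overlay", "report"]

AGE_BANDS = ((0, 14), (15, 29), (30, 44), (45, 200))
AGE_BAND_LABELS = ("<15", "15–30", "30–45", ">45")


def stage_seed(global_seed: int, stage: str) -> np.random.SeedSequence:
    """Deterministic per-stage seed derived from the global seed."""
    return np.random.SeedSequence((global_seed, STAGES.index(stage)))


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format="%.10g")


# ---------------------------------------------------------------- stages


def run_simulate(cfg: PipelineConfig, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    world_cfg = dataclasses.replace(cfg.world, seed=cfg.seed)
    lattice, graph = generate_district_lattice(world_cfg)
    covariates = sample_covariates(lattice, world_cfg)
    u = sample_car_field(graph, world_cfg.sigma_u,
                         np.random.SeedSequence((cfg.seed, 10)))
    yearly = sample_yearly_counts(covariates, world_cfg.beta_true, u, world_cfg)
    records = sample_case_records(
        pd.Series(yearly.sum(axis=0).to_numpy(),
                  index=covariates["district_id"].to_numpy()),
        world_cfg,
    )
    world = generate_raster_world(world_cfg, covariates)

    _write_csv(covariates.assign(u_true=u), out / "districts.csv")
    write_feature_collection(
        out / "districts.geojson",
        lattice["geometry"],
        [{"district_id": int(d)} for d in lattice["district_id"]],
    )
    yearly_out = yearly.reset_index()
    _write_csv(yearly_out, out / "yearly_counts.csv")
    _write_csv(records, out / "cases.csv")
    for name, grid in (
        ("elevation", world.elevation), ("land_class", world.land_class),
        ("road_class", world.road_class), ("biotic", world.biotic),
    ):
        write_ascii_grid(grid, out / f"{name}.asc")
    write_points(out / "facilities.geojson", world.facilities,
                 [{"kind": "hospital_clinic"} for _ in world.facilities])
    write_points(out / "stations.geojson", world.stations,
                 [{"kind": "ambulance_station"} for _ in world.stations])
    write_points(out / "ebais.geojson", world.ebais,
                 [{"kind": "ebais"} for _ in world.ebais])
    write_points(
        out / "census_units.geojson",
        [(cu.x, cu.y) for cu in world.census_units],
        [{"unit_id": cu.unit_id, "population": cu.population,
          "urban": cu.urban, "district_id": cu.district_id}
         for cu in world.census_units],
    )
    from shapely.geometry import LineString

    write_feature_collection(
        out / "roads.geojson",
        [LineString([p0, p1]) for p0, p1, _ in world.road_segments],
        [{"road_class": cls} for _, _, cls in world.road_segments],
    )


def descriptive_stats(records: pd.DataFrame, total_population: float,
                      n_years: float) -> dict:
    """Totals, annual incidence per 100,000, sex and age-band fractions."""
    if len(records) == 0:
        raise ValueError("no case records")
    n = len(records)
    out = {
        "n_cases": int(n),
        "annual_rate_per_100k": float(1e5 * n / (total_population * n_years)),
        "male_fraction": float((records["sex"] == "M").mean()),
    }
    ages = records["age"].to_numpy()
    for (lo, hi), label in zip(AGE_BANDS, AGE_BAND_LABELS):
        out[f"age_{label}"] = float(((ages >= lo) & (ages <= hi)).mean())
    return out


def run_clean(cfg: PipelineConfig, out: Path) -> None:
    records = pd.read_csv(out / "cases.csv")
    cleaned, n_removed, rejected = deduplicate_cases(records)
    _write_csv(cleaned, out / "cases_clean.csv")
    _write_csv(rejected, out / "cases_rejected.csv")
    districts = pd.read_csv(out / "districts.csv")
    stats = descriptive_stats(
        cleaned, districts["population"].sum(), cfg.world.n_years
    )
    stats["n_duplicates_removed"] = int(n_removed)
    stats["n_rejected"] = int(len(rejected))
    with open(out / "descriptive_stats.json", "w") as fh:
        json.dump(stats, fh, indent=1, sort_keys=True)
        fh.write("\n")


def _load_table_window(cfg: PipelineConfig, out: Path) -> tuple[DistrictTable, AdjacencyGraph]:
    districts = pd.read_csv(out / "districts.csv")
    yearly = pd.read_csv(out / "yearly_counts.csv").set_index("year")
    yearly.columns = yearly.columns.astype(int)
    last = yearly.index.max()
    window = yearly.loc[yearly.index > last - cfg.fit_window_years]
    counts = window.sum(axis=0)
    table = DistrictTable(
        district_id=districts["district_id"].to_numpy(),
        Y=counts.loc[districts["district_id"]].to_numpy(),
        population=districts["population"].to_numpy(),
        covariates=districts[COVARIATES],
        n_years=cfg.fit_window_years,
    )
    table.E = compute_offsets(table)
    geoms, props = read_feature_collection(out / "districts.geojson")
    graph = build_adjacency(geoms, ids=[p["district_id"] for p in props])
    return table, graph


def run_fit(cfg: PipelineConfig, out: Path) -> None:
    table, graph = _load_table_window(cfg, out)
    mcmc = dataclasses.replace(cfg.mcmc, seed=cfg.seed + 2)
    samples = fit_car_poisson(table, graph, priors=cfg.priors, mcmc=mcmc)
    _write_csv(incidence_ratio_summary(samples), out / "posterior_summary.csv")
    rates = posterior_incidence(samples, table)
    probs = exceedance_probability(rates, cfg.incidence_threshold)
    per_district = pd.DataFrame(
        {
            "district_id": table.district_id,
            "raw_rate": raw_incidence(table.Y, table.population, table.n_years),
            "smoothed_rate_mean": rates.mean(axis=0),
            "exceedance_prob": probs,
        }
    )
    _write_csv(per_district, out / "district_rates.csv")
    _write_csv(samples.to_dataframe(), out / "posterior_draws.csv")


def run_evaluate(cfg: PipelineConfig, out: Path) -> None:
    districts = pd.read_csv(out / "districts.csv")
    yearly = pd.read_csv(out / "yearly_counts.csv").set_index("year")
    yearly.columns = yearly.columns.astype(int)
    geoms, props = read_feature_collection(out / "districts.geojson")
    graph = build_adjacency(geoms, ids=[p["district_id"] for p in props])
    mcmc = dataclasses.replace(cfg.eval_mcmc, seed=cfg.seed + 3)
    table2 = compare_methods(
        yearly, districts, graph, split_specs=cfg.splits, mcmc=mcmc,
        priors=cfg.priors, threshold=cfg.incidence_threshold, seed=cfg.seed + 4,
    )
    _write_csv(table2, out / "method_comparison.csv")
    per_pair = table2.attrs["per_pair"]
    _write_csv(per_pair, out / "method_comparison_pairs.csv")

    # calibrate the exceedance cutoff against future high-incidence labels
    pop = districts["population"].to_numpy(dtype=float)
    spec5 = cfg.splits.get(5) or next(iter(cfg.splits.values()))
    split = split_periods(yearly, spec5)
    probs_sets, label_sets = [], []
    for k in range(len(split.train_windows)):
        tw, sw = split.train_windows[k], split.test_windows[k]
        n_train = tw[1] - tw[0] + 1
        dtable = DistrictTable(
            district_id=districts["district_id"].to_numpy(),
            Y=split.train_counts[k], population=pop,
            covariates=districts[COVARIATES], n_years=n_train,
        )
        dtable.E = compute_offsets(dtable)
        s = fit_car_poisson(dtable, graph, priors=cfg.priors,
                            mcmc=dataclasses.replace(mcmc, seed=cfg.seed + 5 + k))
        probs = exceedance_probability(
            posterior_incidence(s, dtable), cfg.incidence_threshold
        )
        n_test = sw[1] - sw[0] + 1
        labels = raw_incidence(split.test_counts[k], pop, n_test) > cfg.incidence_threshold
        if labels.any() and not labels.all():
            probs_sets.append(probs)
            label_sets.append(labels)
    calib = {"target_sensitivity": 0.9, "n_pairs": len(probs_sets),
             "calibrated_cutoff": (
                 calibrate_cutoff(probs_sets, label_sets, 0.9)
                 if probs_sets else float("nan"))}
    _write_csv(pd.DataFrame([calib]), out / "calibration.csv")


def run_habitat(cfg: PipelineConfig, out: Path) -> None:
    elevation = read_ascii_grid(out / "elevation.asc")
    biotic = read_ascii_grid(out / "biotic.asc")
    suitable = habitat_suitability_raster(elevation, biotic, cfg.habitat)
    write_ascii_grid(suitable, out / "habitat_suitable.asc")


def run_traveltime(cfg: PipelineConfig, out: Path) -> None:
    elevation = read_ascii_grid(out / "elevation.asc")
    land = read_ascii_grid(out / "land_class.asc")
    geoms, props = read_feature_collection(out / "roads.geojson")
    segments = [
        (tuple(g.coords[0]), tuple(g.coords[-1]), p["road_class"])
        for g, p in zip(geoms, props)
    ]
    road = rasterize_roads(segments, elevation)
    write_ascii_grid(road, out / "road_rasterized.asc")
    cost = build_cost_surface(road, land, elevation, cfg.speed)
    write_ascii_grid(cost.time_s, out / "cell_cost_s.asc")
    write_ascii_grid(cost.slope_deg, out / "slope_deg.asc")
    stations = [tuple(g.coords[0]) for g in
                read_feature_collection(out / "stations.geojson")[0]]
    facilities = [tuple(g.coords[0]) for g in
                  read_feature_collection(out / "facilities.geojson")[0]]
    acc_s = accumulate_time(cost, stations, label="stations")
    acc_f = accumulate_time(cost, facilities, label="facilities")
    write_ascii_grid(acc_s.time_s, out / "time_from_stations_s.asc")
    write_ascii_grid(acc_f.time_s, out / "time_from_facilities_s.asc")
    write_ascii_grid(total_time(acc_s, acc_f), out / "total_time_h.asc")


def _read_census_units(out: Path) -> list[CensusUnit]:
    geoms, props = read_feature_collection(out / "census_units.geojson")
    return [
        CensusUnit(unit_id=p["unit_id"], x=g.x, y=g.y,
                   population=p["population"], urban=bool(p["urban"]),
                   district_id=p["district_id"])
        for g, p in zip(geoms, props)
    ]


def run_overlay(cfg: PipelineConfig, out: Path) -> None:
    rates = pd.read_csv(out / "district_rates.csv")
    flags = high_risk_districts(rates["exceedance_prob"].to_numpy(),
                                cfg.exceedance_cutoff)
    flagged_ids = set(rates.loc[flags, "district_id"].astype(int))
    suitable = read_ascii_grid(out / "habitat_suitable.asc")
    suitable.values = np.nan_to_num(suitable.values)
    units = _read_census_units(out)
    cls = combine_risk(units, suitable, flagged_ids,
                       buffer_radius=cfg.buffer_radius_m)
    write_ascii_grid(cls.mask, out / "risk_mask.asc")
    risk_summary = population_risk_summary(cls)
    with open(out / "population_risk_summary.json", "w") as fh:
        json.dump(risk_summary, fh, indent=1, sort_keys=True)
        fh.write("\n")

    total_h = read_ascii_grid(out / "total_time_h.asc")
    high_units = [u for u in units
                  if cls.units.set_index("unit_id").loc[u.unit_id, "high_risk"]]
    unit_df = cls.units.copy()
    if high_units:
        masks = unit_buffer_masks(high_units, total_h, radius=cfg.buffer_radius_m)
        means = extract_mean_time(total_h, masks).set_index("unit_id")
        unit_df["mean_hours"] = unit_df["unit_id"].map(means["mean_hours"])
        cat = unit_df["mean_hours"].map(
            lambda h: categorize_time(h, cfg.time_category_bounds)
            if pd.notna(h) else "unreachable"
        )
        unit_df["category"] = np.where(unit_df["high_risk"], cat, "")
    else:
        unit_df["mean_hours"] = np.nan
        unit_df["category"] = ""
    _write_csv(unit_df, out / "unit_risk.csv")

    high = unit_df[unit_df["high_risk"]]
    if len(high):
        summary = population_time_summary(
            high["category"].to_numpy(), high["population"].to_numpy(),
            cfg.time_category_bounds,
        )
    else:
        summary = {}
    with open(out / "population_time_summary.json", "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)
        fh.write("\n")


def run_report(cfg: PipelineConfig, out: Path) -> None:
    """Close-up data report per flagged district + the run manifest."""
    unit_df = pd.read_csv(out / "unit_risk.csv")
    flagged = unit_df[unit_df["reason"].isin(["district-incidence", "both"])]
    closeups = []
    for did, grp in flagged.groupby("district_id"):
        closeups.append(
            {
                "district_id": int(did),
                "n_units": int(len(grp)),
                "population": float(grp["population"].sum()),
                "mean_hours_max": float(grp["mean_hours"].max()),
                "worst_category": grp.sort_values("mean_hours")["category"].iloc[-1]
                if grp["mean_hours"].notna().any() else "unreachable",
            }
        )
    _write_csv(pd.DataFrame(
        closeups, columns=["district_id", "n_units", "population",
                           "mean_hours_max", "worst_category"]
    ), out / "closeup_report.csv")
    write_manifest(cfg, out)


def write_manifest(cfg: PipelineConfig, out: Path) -> None:
    files = sorted(
        p for p in out.rglob("*")
        if p.is_file() and p.name != "manifest.json"
        and p.suffix != ".log"  # the log keeps growing after the manifest
    )
    checksums = {
        str(p.relative_to(out)): hashlib.sha256(p.read_bytes()).hexdigest()
        for p in files
    }
    manifest = {
        "version": __version__,
        "seed": cfg.seed,
        "config": config_to_dict(cfg),
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "files": checksums,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True, default=str)
        fh.write("\n")


_STAGE_FUNCS = {
    "simulate": run_simulate,
    "clean": run_clean,
    "fit": run_fit,
    "evaluate": run_evaluate,
    "habitat": run_habitat,
    "traveltime": run_traveltime,
    "overlay": run_overlay,
    "report": run_report,
}


def run_pipeline(cfg: PipelineConfig, out, stages=None) -> Path:
    """Run all (or selected) stages in order into ``out``; returns it.

    Failures abort with the stage name attached; outputs of completed
    stages are retained.
    """
    out = Path(out)
    out.mkdir(parents=True, exist_ok=True)
    for stage in stages or STAGES:
        t0 = time.time()
        logger.info("stage %s: starting", stage)
        try:
            _STAGE_FUNCS[stage](cfg, out)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc
        logger.info("stage %s: done in %.1fs", stage, time.time() - t0)
    return out


def run_from_manifest(manifest_path, out) -> Path:
    """Re-run the full pipeline from a manifest's config snapshot."""
    with open(manifest_path) as fh:
        manifest = json.load(fh)
    import tempfile

    with tempfile.NamedTemporaryFile("w", suffix=".json", delete=False) as fh:
        json.dump(manifest["config"], fh)
        tmp = fh.name
    cfg = load_config(tmp)
    return run_pipeline(cfg, out)
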