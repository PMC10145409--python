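"""File-to-file pipeline stages.

Each stage reads only the documented files of the previous stage and
writes its own, so any stage can be re-run independently.  A run manifest
(config echo, package versions, seed, per-stage wall time) is written by
the CLI wrapper around these functions.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import tables
from .concentrations import generate_concentrations
from .config import PipelineConfig
from .covariates import build_covariate_table
from .geoio import AsciiGrid, Feature, read_geojson, write_geojson
from .mapping import krige_surface, make_grid, predict_grid
from .partition import PartitionParams
from .predictors import default_registry, registry_from_yaml, registry_to_yaml
from .projection import LocalCRS
from .selection import LURModel, SelectionConfig
from .species import PAHSpecies
from .regression import OLSFit
from .validation import kruskal_wallis, loocv, run_batch
from .world import (
    GISWorld,
    SyntheticScenario,
    TrueModel,
    generate_world,
)

# ---------------------------------------------------------------- scenario IO


def scenario_to_dict(s: SyntheticScenario) -> dict:
    return {
        "seed": s.seed,
        "extent": list(s.extent),
        "species": [
            {
                "name": sp.name,
                "ring_count": sp.ring_count,
                "log_kow": sp.log_kow,
                "gaseous_detectable": dict(sp.gaseous_detectable),
            }
            for sp in s.species
        ],
        "true_models": [
            {
                "species": tm.species,
                "season": tm.season,
                "intercept": tm.intercept,
                "coefficients": dict(tm.coefficients),
                "noise_sd": tm.noise_sd,
                "detection_limit": tm.detection_limit,
            }
            for tm in s.true_models.values()
        ],
        "partition": dataclasses.asdict(s.partition),
        "season_temperatures": dict(s.season_temperatures),
        "n_urban": s.n_urban,
        "n_rural": s.n_rural,
        "n_background": s.n_background,
        "n_point_sources": s.n_point_sources,
        "n_met_stations": s.n_met_stations,
        "n_land_cover_seeds": s.n_land_cover_seeds,
        "n_land_use_seeds": s.n_land_use_seeds,
        "elevation_cellsize": s.elevation_cellsize,
        "crs": dataclasses.asdict(s.crs),
        "calibration_targets": [
            {"species": k[0], "season": k[1], "phase": k[2], "mean": v}
            for k, v in s.calibration_targets.items()
        ],
    }


def scenario_from_dict(d: dict) -> SyntheticScenario:
    return SyntheticScenario(
        seed=d["seed"],
        extent=tuple(d["extent"]),
        species=[
            PAHSpecies(
                sp["name"], sp["ring_count"], sp["log_kow"],
                dict(sp["gaseous_detectable"]),
            )
            for sp in d["species"]
        ],
        true_models={
            (tm["species"], tm["season"]): TrueModel(
                tm["species"], tm["season"], tm["intercept"],
                dict(tm["coefficients"]), tm["noise_sd"], tm["detection_limit"],
            )
            for tm in d["true_models"]
        },
        partition=PartitionParams(**d["partition"]),
        season_temperatures=dict(d["season_temperatures"]),
        n_urban=d["n_urban"],
        n_rural=d["n_rural"],
        n_background=d["n_background"],
        n_point_sources=d["n_point_sources"],
        n_met_stations=d["n_met_stations"],
        n_land_cover_seeds=d["n_land_cover_seeds"],
        n_land_use_seeds=d["n_land_use_seeds"],
        elevation_cellsize=d["elevation_cellsize"],
        crs=LocalCRS(**d["crs"]),
        calibration_targets={
            (t["species"], t["season"], t["phase"]): t["mean"]
            for t in d["calibration_targets"]
        },
    )


# ------------------------------------------------------------------ world IO


def write_world(world: GISWorld, outdir: Path) -> None:
    write_geojson(world.land_cover, outdir / "land_cover.geojson")
    write_geojson(world.land_use, outdir / "land_use.geojson")
    write_geojson(world.roads, outdir / "roads.geojson")
    write_geojson(world.point_sources, outdir / "point_sources.geojson")
    write_geojson(world.met_stations, outdir / "met_stations.geojson")
    world.elevation.write(outdir / "elevation.asc")
    write_geojson([Feature(world.boundary, {})], outdir / "boundary.geojson")


def read_world(indir: Path, crs: LocalCRS | None = None) -> GISWorld:
    boundary = read_geojson(indir / "boundary.geojson")[0].geometry
    return GISWorld(
        land_cover=read_geojson(indir / "land_cover.geojson"),
        land_use=read_geojson(indir / "land_use.geojson"),
        roads=read_geojson(indir / "roads.geojson"),
        point_sources=read_geojson(indir / "point_sources.geojson"),
        met_stations=read_geojson(indir / "met_stations.geojson"),
        elevation=AsciiGrid.read(indir / "elevation.asc"),
        boundary=boundary,
        crs=crs or LocalCRS(),
    )


# ------------------------------------------------------------------- stages


def stage_simulate(
    config: PipelineConfig, outdir: Path,
    scenario: SyntheticScenario | None = None,
) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    scenario = scenario or SyntheticScenario(seed=config.seed)
    world, network = generate_world(scenario)
    records = generate_concentrations(world, network, scenario)
    write_world(world, outdir)
    tables.write_sites(network, outdir / "sites.csv")
    tables.write_concentrations(records, outdir / "concentrations.csv")
    with open(outdir / "scenario.yaml", "w") as fh:
        yaml.safe_dump(scenario_to_dict(scenario), fh, sort_keys=False)


def stage_extract(config: PipelineConfig, workdir: Path) -> None:
    scenario = _load_scenario(workdir)
    world = read_world(workdir, scenario.crs if scenario else None)
    network = tables.read_sites(workdir / "sites.csv")
    registry = default_registry(config.buffer_sizes, include_met=True)
    table = build_covariate_table(
        world,
        [(s[0], s[1], s[2]) for s in network.sites],
        registry,
        config.buffer_sizes,
    )
    tables.write_covariates(table, workdir / "covariates.csv")
    registry_to_yaml(registry, workdir / "registry.yaml")


def _load_scenario(workdir: Path) -> SyntheticScenario | None:
    p = workdir / "scenario.yaml"
    if not p.exists():
        return None
    with open(p) as fh:
        return scenario_from_dict(yaml.safe_load(fh))


def _selection_config(config: PipelineConfig) -> SelectionConfig:
    return SelectionConfig(
        gain_threshold=config.gain_threshold,
        gain_mode=config.gain_mode,
        alpha=config.alpha,
        vif_threshold=config.vif_threshold,
        moran_permutations=config.moran_permutations,
    )


def _filter_records(records, config: PipelineConfig):
    out = records
    if config.species is not None:
        out = [r for r in out if r.species in config.species]
    if config.seasons is not None:
        out = [r for r in out if r.season in config.seasons]
    if config.phases is not None:
        out = [r for r in out if r.phase in config.phases]
    return out


def _model_registry(config: PipelineConfig, workdir: Path):
    registry = registry_from_yaml(workdir / "registry.yaml")
    if not config.include_met:
        registry = {c: s for c, s in registry.items() if s.category != "met"}
    return registry


def stage_fit(config: PipelineConfig, workdir: Path) -> None:
    records = _filter_records(
        tables.read_concentrations(workdir / "concentrations.csv"), config
    )
    table = tables.read_covariates(workdir / "covariates.csv")
    registry = _model_registry(config, workdir)
    network = tables.read_sites(workdir / "sites.csv")
    scenario = _load_scenario(workdir)
    limits = (
        {k: tm.detection_limit for k, tm in scenario.true_models.items()}
        if scenario
        else 0.0
    )
    report = run_batch(
        records, table, registry,
        coords=network.coords(),
        config=_selection_config(config),
        detection_threshold=config.detection_threshold,
        detection_limits=limits,
        nondetect_rule=config.nondetect_rule,
        seed=config.seed,
    )
    payload = {
        "models": [
            {
                "species": r.species,
                "season": r.season,
                "phase": r.phase,
                "intercept": r.model.fit.intercept,
                "coefficients": r.model.fit.coefficients,
                "std_errors": r.model.fit.std_errors,
                "p_values": r.model.fit.p_values,
                "equation": r.model.equation(),
                "r2": r.r2,
                "adj_r2": r.adj_r2,
                "rmse": r.rmse,
                "loocv_r": None if not np.isfinite(r.loocv_r) else r.loocv_r,
                "detection_rate": r.detection_rate,
                "n": r.n,
                "cooks_flags": r.cooks_flags,
                "moran_i": r.moran_i,
                "moran_p": r.moran_p,
                "trace": [dataclasses.asdict(t) for t in r.model.trace],
            }
            for r in report.rows
        ],
        "skipped": [dataclasses.asdict(s) for s in report.skipped],
    }
    with open(workdir / "models.json", "w") as fh:
        json.dump(_jsonable(payload), fh, indent=1, sort_keys=True,
                  allow_nan=False)


def _jsonable(obj):
    """Recursively replace non-finite floats with None."""
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, float) and not np.isfinite(obj):
        return None
    return obj


def _load_models(workdir: Path) -> dict:
    with open(workdir / "models.json") as fh:
        return json.load(fh)


def _records_frame(workdir: Path, config: PipelineConfig) -> pd.DataFrame:
    records = _filter_records(
        tables.read_concentrations(workdir / "concentrations.csv"), config
    )
    return pd.DataFrame(
        [(r.site_id, r.species, r.season, r.phase, r.value, r.detected)
         for r in records],
        columns=tables.CONC_COLUMNS,
    )


def stage_validate(config: PipelineConfig, workdir: Path) -> None:
    """LOOCV scatter per fitted model plus the seasonal-difference test for
    the light compounds (gaseous Ace and Flo, heating vs non-heating)."""
    payload = _load_models(workdir)
    table = tables.read_covariates(workdir / "covariates.csv")
    conc = _records_frame(workdir, config)
    scatter_rows = []
    for m in payload["models"]:
        x = table.for_season(m["season"])
        sub = conc[
            (conc.species == m["species"])
            & (conc.season == m["season"])
            & (conc.phase == m["phase"])
        ].set_index("site_id")
        y = sub.loc[x.index, "value_ng_m3"].to_numpy(dtype=float)
        res = loocv(y, x, list(m["coefficients"]))
        for sid, pred, obs in zip(x.index, res.predictions, res.observed):
            scatter_rows.append(
                (m["species"], m["season"], m["phase"], sid, pred, obs)
            )
    pd.DataFrame(
        scatter_rows,
        columns=["species", "season", "phase", "site_id", "predicted", "observed"],
    ).to_csv(workdir / "loocv_scatter.csv", index=False)

    kw = {}
    for species in ("Ace", "Flo"):
        sub = conc[(conc.species == species) & (conc.phase == "gaseous")]
        groups = [
            sub[sub.season == s]["value_ng_m3"].to_numpy()
            for s in ("heating", "non-heating")
        ]
        if all(len(g) for g in groups):
            h, p = kruskal_wallis(*groups)
            kw[species] = {"H": h, "p": p}
    with open(workdir / "validation.json", "w") as fh:
        json.dump({"kruskal_wallis_heating_vs_nonheating_gaseous": kw},
                  fh, indent=1, sort_keys=True)


def stage_map(config: PipelineConfig, workdir: Path) -> None:
    payload = _load_models(workdir)
    scenario = _load_scenario(workdir)
    world = read_world(workdir, scenario.crs if scenario else None)
    models = payload["models"]
    if config.map_strata is not None:
        wanted = {tuple(t) for t in config.map_strata}
        models = [
            m for m in models
            if (m["species"], m["season"], m["phase"]) in wanted
        ]
    grid = make_grid(world.boundary, config.cell_size)
    ids = [f"C{i:04d}" for i in range(len(grid.centroids))]
    codes = sorted({c for m in models for c in m["coefficients"]})
    if codes:
        from .predictors import make_spec

        table = build_covariate_table(
            world,
            [(cid, x, y) for cid, (x, y) in zip(ids, grid.centroids)],
            {c: make_spec(c) for c in codes},
            config.buffer_sizes,
        )
    surf_dir = workdir / "surfaces"
    surf_dir.mkdir(exist_ok=True)
    pred_rows = []
    variograms = {}
    for m in models:
        season = m["season"]
        cov = table.for_season(season) if codes else pd.DataFrame(index=ids)
        lur = LURModel(
            m["species"], season, m["phase"],
            _fit_from_payload(m, cov, ids),
        )
        pg = predict_grid(lur, grid, world, config.buffer_sizes, covariates=cov)
        tag = f"{m['species']}_{season}_{m['phase']}".replace(" ", "")
        surface = krige_surface(
            pg, world.boundary, config.surface_resolution,
            model=config.variogram_model,
        )
        surface.raster.write(surf_dir / f"surface_{tag}.asc")
        variograms[tag] = dataclasses.asdict(surface.variogram)
        for cid, (x, y), v in zip(ids, grid.centroids, pg.values):
            pred_rows.append((m["species"], season, m["phase"], cid, x, y, v))
    pd.DataFrame(
        pred_rows,
        columns=["species", "season", "phase", "cell_id", "x", "y",
                 "predicted_ng_m3"],
    ).to_csv(surf_dir / "centroid_predictions.csv", index=False)
    with open(surf_dir / "variograms.json", "w") as fh:
        json.dump(variograms, fh, indent=1, sort_keys=True)


def _fit_from_payload(m: dict, cov: pd.DataFrame, ids) -> OLSFit:
    """Reconstruct a minimal OLSFit carrying the stored equation."""
    n = len(ids)
    return OLSFit(
        intercept=m["intercept"],
        coefficients=dict(m["coefficients"]),
        std_errors=dict(m["std_errors"]),
        p_values=dict(m["p_values"]),
        intercept_se=0.0,
        intercept_p=0.0,
        r2=m["r2"],
        adj_r2=m["adj_r2"],
        residuals=np.zeros(n),
        fitted=np.zeros(n),
        n=m["n"],
        p=len(m["coefficients"]),
        sigma2=0.0,
    )


def stage_report(config: PipelineConfig, workdir: Path) -> None:
    """Flat model table (one row per stratum) plus the skip list."""
    payload = _load_models(workdir)
    rows = [
        {
            "PAH": m["species"],
            "Season": m["season"],
            "Phase": m["phase"],
            "LUR Model": m["equation"],
            "R2": round(m["r2"], 4),
            "adj_R2": round(m["adj_r2"], 4),
            "RMSE": round(m["rmse"], 4),
            "LOOCV_r": ("" if m["loocv_r"] is None
                        else round(m["loocv_r"], 4)),
            "detection_rate": round(m["detection_rate"], 4),
            "n": m["n"],
        }
        for m in payload["models"]
    ]
    pd.DataFrame(
        rows,
        columns=["PAH", "Season", "Phase", "LUR Model", "R2", "adj_R2",
                 "RMSE", "LOOCV_r", "detection_rate", "n"],
    ).to_csv(workdir / "report.csv", index=False)
    pd.DataFrame(payload["skipped"]).to_csv(workdir / "skipped.csv", index=False)


STAGES = {
    "simulate": stage_simulate,
    "extract": stage_extract,
    "fit": stage_fit,
    "validate": stage_validate,
    "map": stage_map,
    "report": stage_report,
}
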