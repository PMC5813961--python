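"""End-to-end pipeline orchestration: simulate, delineate, trend.

These functions are the library-level entry points behind the CLI; each
writes standard-format outputs (CSV tables, GeoJSON polygons, a JSON run
report) plus the resolved configuration, so any run is reproducible from
its emitted config and seed.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import filters, io, trend
from .config import PipelineConfig
from .corridor import CorridorModel, select_window_height
from .projection import EquidistantConic, project_to_conic
from .simulate import SyntheticScenario, simulate_sightings, simulate_telemetry, write_fixtures
from .windows import WindowGrid, assign_windows

log = logging.getLogger(__name__)

__all__ = ["ingest", "run_simulate", "run_delineate", "run_trend"]


def _season(dates: pd.Series) -> pd.Series:
    m = dates.dt.month
    return pd.Series(np.select([m.between(3, 5), m.between(9, 11)], ["spring", "autumn"], "unknown"), index=dates.index)


def ingest(config: PipelineConfig) -> dict:
    """Read, screen, project and QC both datasets into analysis locations."""
    proj = EquidistantConic.from_proj_string(config.projection)
    counts: dict[str, int] = {}
    logs: dict[str, pd.DataFrame] = {}

    raw_s = io.read_sightings(config.sightings)
    counts["sightings_raw"] = len(raw_s)
    kept, rej = filters.screen_sightings(raw_s)
    logs["sightings_rejections"] = rej
    counts["sightings_screened"] = len(kept)
    opp, rej_proj = project_to_conic(kept, proj, on_invalid="reject")
    if len(rej_proj):
        logs["sightings_rejections"] = pd.concat([rej, rej_proj], ignore_index=True)
    counts["sightings_projected"] = len(opp)
    opp = opp.copy()
    opp["year"] = opp["date"].dt.year
    opp["season"] = _season(opp["date"])
    opp["source"] = "opportunistic"

    raw_t = io.read_telemetry(config.telemetry)
    counts["telemetry_raw"] = len(raw_t)
    tel_fix, rej_t_proj = project_to_conic(raw_t, proj, on_invalid="reject")
    thr = filters.QCThresholds(
        flight_velocity_ms=config.flight_velocity_ms,
        max_speed_kmh=config.max_speed_kmh,
        min_turn_angle_deg=config.min_turn_angle_deg,
        turn_leg_km=config.turn_leg_km,
        stopover_break_km=config.stopover_break_km,
    )
    retained, rej_qc = filters.qc_telemetry(tel_fix, thr)
    if len(rej_t_proj):
        rej_qc = pd.concat([rej_qc, rej_t_proj], ignore_index=True)
    logs["telemetry_rejections"] = rej_qc
    counts["telemetry_retained"] = len(retained)
    kind = filters.classify_flight(retained["velocity_ms"].to_numpy(), thr.flight_velocity_ms)
    ground = retained[kind == "ground"]
    flight = retained[kind == "flight"]
    counts["telemetry_ground"] = len(ground)
    counts["telemetry_flight"] = len(flight)
    sites = filters.cluster_stopovers(ground, thr.stopover_break_km)
    counts["stopover_sites"] = len(sites)
    tel = filters.assemble_migration_locations(sites, flight)
    counts["telemetry_locations"] = len(tel)
    return {"opportunistic": opp, "telemetry": tel, "counts": counts, "logs": logs, "projection": proj}


def _grid_for(config: PipelineConfig, data: dict, seed) -> tuple[WindowGrid, pd.DataFrame | None]:
    ys = np.concatenate([data["opportunistic"]["y"].to_numpy(), data["telemetry"]["y"].to_numpy()])
    if isinstance(config.window_height_km, str) and config.window_height_km == "auto":
        height, diag = select_window_height(
            data["opportunistic"],
            data["telemetry"],
            heights=tuple(h * 1e3 for h in config.auto_height_candidates_km),
            bootstrap=config.bootstrap,
            seed=seed,
        )
        return WindowGrid.from_span(ys.min(), ys.max(), height), diag
    return WindowGrid.from_span(ys.min(), ys.max(), float(config.window_height_km) * 1e3), None


def _check_nonempty(data: dict) -> None:
    if len(data["opportunistic"]) == 0 and len(data["telemetry"]) == 0:
        raise ValueError(f"no locations survive filtering; attrition: {data['counts']}")


def run_simulate(config: PipelineConfig, scenario: SyntheticScenario | None = None) -> dict:
    """Generate fixture sightings/telemetry CSVs plus the truth sidecar."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    scenario = scenario or SyntheticScenario()
    rng = np.random.default_rng(config.seed)
    sightings, s_truth = simulate_sightings(scenario, seed=rng)
    fixes, t_truth = simulate_telemetry(scenario, seed=rng)
    paths = write_fixtures(outdir, sightings, fixes, {"sightings": s_truth, "telemetry": t_truth, "seed": config.seed})
    config.to_yaml(outdir / "resolved_config.yaml")
    io.write_run_report(outdir / "simulate_report.json", {"seed": config.seed, "n_sightings": len(sightings), "n_fixes": len(fixes)})
    return {k: str(v) for k, v in paths.items()}


def run_delineate(config: PipelineConfig) -> dict:
    """Delineate 50/75/95% corridors with bootstrap confidence bands."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    data = ingest(config)
    _check_nonempty(data)
    rng = np.random.default_rng(config.seed)
    grid, diag = _grid_for(config, data, rng)
    model = CorridorModel(
        data["opportunistic"], data["telemetry"], grid=grid, levels=tuple(config.core_levels)
    )
    results = model.fit(bootstrap=config.bootstrap, seed=rng)
    io.corridors_to_geojson(results, outdir / "corridors.geojson", data["projection"])
    for level in config.core_levels:
        results.edge_table(level).to_csv(outdir / f"edges_{level}.csv", index=False)
    summary = results.summary()
    summary.to_csv(outdir / "corridor_summary.csv")
    if diag is not None:
        diag.to_csv(outdir / "window_selection.csv", index=False)
    for name, frame in data["logs"].items():
        frame.to_csv(outdir / f"{name}.csv", index=False)
    config.to_yaml(outdir / "resolved_config.yaml")
    report = {
        "seed": config.seed,
        "counts": data["counts"],
        "grid": {"y0": grid.y0, "height": grid.height, "count": grid.count},
        "summary": summary.reset_index().to_dict(orient="records"),
    }
    io.write_run_report(outdir / "delineate_report.json", report)
    return {"results": results, "grid": grid, "report": report, "selection": diag}


def run_trend(config: PipelineConfig) -> dict:
    """Median comparison, two-stage positional trend, and width trends."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    data = ingest(config)
    _check_nonempty(data)
    rng = np.random.default_rng(config.seed)
    grid, _ = _grid_for(config, data, rng)
    opp = assign_windows(data["opportunistic"], grid)
    tel = assign_windows(data["telemetry"], grid)

    y0, y1 = config.overlap_years
    med_diff = trend.median_difference_bootstrap(
        opp[opp["year"].between(y0, y1)],
        tel[tel["year"].between(y0, y1)],
        grid,
        B=config.bootstrap,
        min_n=config.median_min_sightings,
        seed=rng,
    )
    med_diff.to_csv(outdir / "median_differences.csv")

    pos = trend.TwoStageTrendModel(opp, tel, grid, response="x").fit(
        burn=config.mcmc_burn, keep=config.mcmc_keep, seed=rng
    )
    pos.slope_table().to_csv(outdir / "slopes_position.csv")
    preds = pos.predict(years=(1980, 2014))
    preds.to_csv(outdir / "predictions_1980_2014.csv")

    combined = pd.concat([opp, tel], ignore_index=True)
    centerline = trend.median_by_window(combined, grid)
    offsets = trend.centerline_offsets(combined, centerline)
    width_results = {}
    for subset in ("all_abs", "west", "east"):
        try:
            res = trend.width_trend(offsets, subset, grid, burn=config.mcmc_burn, keep=config.mcmc_keep, seed=rng)
            res.slope_table().to_csv(outdir / f"slopes_{subset}.csv")
            width_results[subset] = res
        except ValueError as exc:  # insufficient data: partial output with flag
            log.warning("width trend %s skipped: %s", subset, exc)
            width_results[subset] = None
    config.to_yaml(outdir / "resolved_config.yaml")
    report = {
        "seed": config.seed,
        "counts": data["counts"],
        "grid": {"y0": grid.y0, "height": grid.height, "count": grid.count},
        "median_differences": med_diff.reset_index().to_dict(orient="records"),
        "subsets_fitted": [k for k, v in width_results.items() if v is not None],
    }
    io.write_run_report(outdir / "trend_report.json", report)
    return {
        "median_differences": med_diff,
        "position": pos,
        "predictions": preds,
        "width": width_results,
        "centerline": centerline,
        "grid": grid,
        "report": report,
    }
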