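"""Pipeline orchestration: run configured stages and emit a run report.

Every stage consumes the single config seed through
``SimulationConfig.rng`` salts, so a run is fully reproducible from the
RunConfig alone. Outputs are plain CSV/JSON; warnings raised by stages are
collected into the report rather than dropped.
"""

from __future__ import annotations

import json
import time
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from . import cdk2, clonogenic, foci, fucci, section2d, spheroid3d, synthetic
from .config import RunConfig, SimulationConfig

KNOWN_STAGES = ("cfa", "foci", "fucci", "cdk2", "section", "spheroid3d")


def validate_config(config: RunConfig) -> list[str]:
    """Return a list of validation errors (empty when the config is valid)."""
    errors = []
    for stage in config.stages:
        if stage not in KNOWN_STAGES:
            errors.append(f"unknown stage: {stage!r}")
    for field in ("pixel_size_um", "frame_interval_h", "z_step_um",
                  "zone_width_um", "band_width_um"):
        if getattr(config, field) <= 0:
            errors.append(f"{field} must be > 0")
    for key, path in config.inputs.items():
        if not Path(path).exists():
            errors.append(f"input path for {key!r} does not exist: {path}")
    return errors


def _stage_cfa(config: RunConfig, out: Path, caught: list[str]) -> dict:
    cfg = config.simulation()
    table = synthetic.simulate_cfa_counts(
        alpha=0.2, beta=0.02, doses=[0, 2, 4, 6, 8],
        plating_efficiency=0.5, cfg=cfg,
    )
    table.to_csv(out / "cfa_counts.csv", index=False)
    data = clonogenic.SurvivalDataset("demo", table)
    fit = clonogenic.fit_lq(clonogenic.per_well_points(data))
    summary = {
        "alpha": fit.alpha, "beta": fit.beta, "rss": fit.rss, "df": fit.df,
        "dose_sf10_gy": clonogenic.dose_for_sf(fit, 0.1),
    }
    pd.DataFrame([summary]).to_csv(out / "cfa_fit.csv", index=False)
    return summary


def _stage_foci(config: RunConfig, out: Path, caught: list[str]) -> dict:
    cfg = SimulationConfig(seed=config.seed, pixel_size_um=0.2,
                           frame_interval_h=config.frame_interval_h)
    image, truth = synthetic.generate_foci_image(n_nuclei=12, foci_mean=8, cfg=cfg)
    table = foci.count_foci(
        image.channels["foci"], image.labels, image.pixel_size_um
    )
    merged = table.merge(truth, on="label")
    merged.to_csv(out / "foci_counts.csv", index=False)
    return {"n_nuclei": len(table), "total_foci": int(table["focus_count"].sum())}


def _stage_fucci(config: RunConfig, out: Path, caught: list[str]) -> dict:
    cfg = config.simulation()
    traces_df, truth = synthetic.generate_fucci_traces(
        n_cells=60, noncycling_fraction=0.3, cfg=cfg
    )
    traces_df.to_csv(out / "fucci_traces.csv", index=False)
    gates = fucci.calibrate_gates(
        traces_df["red"].to_numpy(), traces_df["green"].to_numpy()
    )
    results = [
        fucci.trace_durations(t, gates, noncycling_hours=config.noncycling_hours)
        for t in fucci.traces_from_frame(traces_df, cfg.frame_interval_h)
    ]
    table = pd.DataFrame(
        [
            {"cell_id": r.cell_id, "status": r.status.value,
             "total_h": r.total_h, **{f"{k}_h": v for k, v in r.durations_h.items()}}
            for r in results
        ]
    )
    table.to_csv(out / "fucci_durations.csv", index=False)
    cycling = [r for r in results if r.status is fucci.CyclingStatus.CYCLING]
    return {
        "n_cells": len(results),
        "n_cycling": len(cycling),
        "mean_total_h": float(np.mean([r.total_h for r in cycling]))
        if cycling else float("nan"),
    }


def _stage_cdk2(config: RunConfig, out: Path, caught: list[str]) -> dict:
    cfg = SimulationConfig(seed=config.seed, pixel_size_um=1.0,
                           frame_interval_h=config.frame_interval_h)
    image, truth = synthetic.generate_reporter_image(ratio=0.5, n_cells=25, cfg=cfg)
    corrected = cdk2.subtract_background(
        image.channels["reporter"], config.cdk2_rollball_um, image.pixel_size_um
    )
    bands = cdk2.cytoplasm_band(
        image.labels, config.band_width_um, image.pixel_size_um
    )
    measurements = cdk2.measure_ratio(corrected, image.labels, bands)
    cdk2.measurements_to_frame(measurements).to_csv(
        out / "cdk2_ratios.csv", index=False
    )
    frac, count = cdk2.quiescent_fraction(
        measurements, threshold=config.quiescence_threshold
    )
    return {"quiescent_fraction": frac, "quiescent_count": count}


def _stage_section(config: RunConfig, out: Path, caught: list[str]) -> dict:
    cfg = SimulationConfig(seed=config.seed, pixel_size_um=1.3,
                           frame_interval_h=config.frame_interval_h)
    brdu_rgb, pimo_rgb, truth = synthetic.generate_section_image(cfg=cfg)
    section = section2d.outline_section(pimo_rgb)
    _, pimo_aec = section2d.deconvolve_haec(pimo_rgb)
    _, brdu_aec = section2d.deconvolve_haec(brdu_rgb)
    pimo_pos = section2d.hypoxia_mask(pimo_aec, section, seed=config.seed)
    brdu_pos = section2d.hypoxia_mask(brdu_aec, section, seed=config.seed)
    zones = section2d.distance_zones(
        section, cfg.pixel_size_um, config.zone_width_um
    )
    profile = section2d.zonal_profile(
        {"pimonidazole": pimo_pos, "brdu": brdu_pos}, zones,
        od_rasters={"pimonidazole": pimo_aec, "brdu": brdu_aec},
        zone_width_um=config.zone_width_um,
    )
    profile.to_csv(out / "section_zonal_profile.csv", index=False)
    hypoxic = profile[profile["pimonidazole_fraction"] > 0.5]
    return {
        "n_zones": len(profile),
        "first_hypoxic_zone": int(hypoxic["zone"].min()) if len(hypoxic) else -1,
    }


def _stage_spheroid3d(config: RunConfig, out: Path, caught: list[str]) -> dict:
    cfg = SimulationConfig(seed=config.seed, pixel_size_um=2.0,
                           frame_interval_h=config.frame_interval_h)
    stack, truth = synthetic.generate_spheroid_stack(
        z_step_um=config.z_step_um, cfg=cfg
    )
    cells, hist, geom = spheroid3d.analyze_stack(
        stack,
        rollball_um=config.spheroid_rollball_um,
        green_threshold=config.green_threshold,
    )
    cells.to_csv(out / "spheroid_cells.csv", index=False)
    hist.to_csv(out / "spheroid_histogram.csv", index=False)
    return {
        "n_cells": len(cells),
        "fitted_radius_um": geom.radius_um,
        "n_bins": len(hist),
    }


_STAGE_FNS = {
    "cfa": _stage_cfa,
    "foci": _stage_foci,
    "fucci": _stage_fucci,
    "cdk2": _stage_cdk2,
    "section": _stage_section,
    "spheroid3d": _stage_spheroid3d,
}


def run(config: RunConfig, out_dir: str | Path) -> dict:
    """Execute the configured stages and write a JSON run report."""
    errors = validate_config(config)
    if errors:
        raise ValueError("invalid config: " + "; ".join(errors))
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stages = config.stages or list(KNOWN_STAGES)

    report: dict = {
        "seed": config.seed,
        "parameters": config.to_dict(),
        "stages": {},
        "warnings": [],
    }
    for stage in stages:
        start = time.perf_counter()
        caught: list[str] = []
        with warnings.catch_warnings(record=True) as wlist:
            warnings.simplefilter("always")
            result = _STAGE_FNS[stage](config, out, caught)
            caught.extend(str(w.message) for w in wlist)
        report["stages"][stage] = {
            "result": result,
            "elapsed_s": round(time.perf_counter() - start, 3),
            "warnings": caught,
        }
        report["warnings"].extend(f"{stage}: {msg}" for msg in caught)
    with open(out / "run_report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return report
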