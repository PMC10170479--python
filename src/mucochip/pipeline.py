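"""Reproducible end-to-end runs and condition-level comparison reports.

A run executes a selected list of stages on synthetic (or user-provided)
inputs with a single master seed, writes versioned outputs and a
machine-readable JSON report, and is bit-identical under a fixed seed and
configuration. ``compare_conditions`` aggregates several run reports into
group means +/- SD per metric, with hypothesis testing delegated to
standard routines (one-way ANOVA or Kruskal-Wallis) as a pass-through
reporting step.
"""

from __future__ import annotations

import copy
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as scipy_stats
from skimage import measure as _skmeasure

from . import synthetic_data as synth
from . import particle_tracking as tracking
from . import microrheology as rheo
from . import impedance_fit as imp
from . import chip_fluidics as fluidics
from . import cilia_cbf as cbf_mod
from . import fluorescence_morphometry as morpho
from .constants import CP_PER_PA_S, ROOM_TEMPERATURE_K

logger = logging.getLogger("mucochip")

#: Stage execution order (dependency order of the experimental workflow).
STAGE_ORDER = ["fluidics", "rheology", "impedance", "cbf", "thickness", "morphometry"]

#: Fixed per-stage seed offsets so stages decouple under one master seed.
_SEED_OFFSETS = {name: 1000 * (k + 1) for k, name in enumerate(STAGE_ORDER)}

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "stages": ["rheology", "impedance", "cbf", "thickness"],
    "rheology": {
        "viscosity_cp": 18.0,          # CF-like mucus
        "elastic_modulus_pa": None,    # None -> purely viscous medium
        "n_regions": 8,
        "n_particles": 50,
        "n_frames": 100,
        "frame_rate_hz": 20.0,
        "particle_radius_nm": 100.0,
        "temperature_k": ROOM_TEMPERATURE_K,
        "localization_noise_nm": 20.0,
        "track_from_video": False,     # True: render video, detect and link
    },
    "impedance": {
        # barrier maturation: R_teer rises to a day-3 peak, then falls as
        # the epithelium polarizes; capacitance grows with membrane extent
        "days": [1, 3, 7, 14],
        "r_teer_ohm": {1: 900.0, 3: 2000.0, 7: 1400.0, 14: 1100.0},
        "c_membrane_nf": {1: 60.0, 3: 80.0, 7: 110.0, 14: 150.0},
        "r_sol_ohm": 150.0,
        "c_electrode_uf": 1.0,
        "noise_fraction": 0.02,
    },
    "fluidics": {"nx": 364, "nz": 24},
    "cbf": {"cbf_hz": 8.0, "frame_rate_hz": 100.0, "duration_s": 2.0,
            "noise_sd": 0.1},
    "thickness": {"gap_um": 39.4, "z_spacing_um": 0.25},
    "morphometry": {"n_nuclei": 10, "marker_coverage": 0.3,
                    "pixel_size_um": 1.0, "field_px": 100},
}


def _merged_config(config: dict | None) -> dict:
    merged = copy.deepcopy(DEFAULT_CONFIG)
    for key, value in (config or {}).items():
        if isinstance(value, dict) and isinstance(merged.get(key), dict):
            merged[key].update(value)
        else:
            merged[key] = value
    return merged


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


def _stage_rheology(cfg: dict, seed: int, outdir: Path | None) -> dict:
    viscosities = []
    moduli = []
    regions = []
    for region in range(cfg["n_regions"]):
        truth = synth.RheoGroundTruth(
            viscosity_pa_s=cfg["viscosity_cp"] / CP_PER_PA_S,
            elastic_modulus_pa=cfg["elastic_modulus_pa"],
            particle_radius_m=cfg["particle_radius_nm"] * 1e-9,
            temperature_k=cfg["temperature_k"],
            frame_rate_hz=cfg["frame_rate_hz"],
            n_particles=cfg["n_particles"],
            n_frames=cfg["n_frames"],
            localization_noise_sd_m=cfg["localization_noise_nm"] * 1e-9,
            seed=seed + region,
        )
        if truth.elastic_modulus_pa is None:
            traj = synth.simulate_brownian_trajectories(truth, region_id=region)
        else:
            traj = synth.simulate_viscoelastic_trajectories(truth, region_id=region)
        if cfg["track_from_video"]:
            video, _ = synth.render_spot_video(
                traj, image_shape=(256, 256), pixel_size_um=0.5,
                snr=20.0, seed=seed + 500 + region,
            )
            traj = tracking.track_video(video, max_displacement_um=5.0,
                                        region_id=region)
            traj = tracking.filter_min_length(traj)
        curve = rheo.compute_msd(traj)
        result = rheo.analyze_msd(curve, truth.particle_radius_m,
                                  truth.temperature_k)
        regions.append({"region": region, **result.to_dict()})
        viscosities.append(result.viscosity_cp)
        if result.elastic_modulus_pa is not None:
            moduli.append(result.elastic_modulus_pa)
        if outdir is not None:
            curve.to_csv(outdir / f"msd_region{region}.csv")
            traj.to_csv(outdir / f"trajectories_region{region}.csv")
    out = {
        "viscosity_cp_mean": float(np.mean(viscosities)),
        "viscosity_cp_sd": float(np.std(viscosities, ddof=1)) if len(viscosities) > 1 else None,
        "regions": regions,
    }
    if moduli:
        out["elastic_modulus_pa_mean"] = float(np.mean(moduli))
    return out


def _stage_impedance(cfg: dict, seed: int, outdir: Path | None) -> dict:
    fits: dict[int, imp.CircuitFit] = {}
    bode = {}
    for k, day in enumerate(cfg["days"]):
        params = imp.CircuitParams(
            r_sol=cfg["r_sol_ohm"],
            r_teer=cfg["r_teer_ohm"][day],
            c_membrane=cfg["c_membrane_nf"][day] * 1e-9,
            c_electrode=cfg["c_electrode_uf"] * 1e-6,
        )
        spectrum = synth.simulate_impedance_spectrum(
            params, noise_fraction=cfg["noise_fraction"], seed=seed + k, day=day,
        )
        if outdir is not None:
            spectrum.to_csv(outdir / f"impedance_day{day}.csv")
        fits[day] = imp.fit_circuit(spectrum)
        bode[str(day)] = imp.bode_modulus_at(spectrum)
    course = imp.teer_timecourse(fits)
    peak_day = course.loc[course["is_peak"], "day"]
    return {
        "timecourse": course.to_dict(orient="records"),
        "peak_day": int(peak_day.iloc[0]) if len(peak_day) else None,
        "bode_modulus_12hz_ohm": bode,
    }


def _stage_fluidics(cfg: dict, seed: int, outdir: Path | None) -> dict:
    geom = fluidics.ChipGeometry(**cfg.get("geometry", {}))
    params = fluidics.TransportParams(**cfg.get("transport", {}))
    sol = fluidics.solve_flow(geom, params, nx=cfg["nx"], nz=cfg["nz"])
    shear = fluidics.wall_shear_profile(sol, "membrane")
    footprint = geom.insert_footprint_x_m
    oxygen = fluidics.solve_oxygen(sol)
    budget = fluidics.oxygen_budget(sol)
    result = {
        "membrane_shear_dyn_cm2_mean": float(
            np.mean(shear.restrict(footprint).tau_dyn_cm2)),
        "shear_cv_footprint": fluidics.shear_uniformity(shear, footprint),
        "membrane_velocity_m_s": fluidics.membrane_velocity(sol),
        "min_oxygen_mol_m3": float(np.min(oxygen)),
        "reynolds_number": fluidics.reynolds_number(sol),
        "oxygen_budget": budget,
    }
    if outdir is not None:
        pd.DataFrame({"x_m": shear.x_m, "tau_pa": shear.tau_pa}).to_csv(
            outdir / "membrane_shear.csv", index=False)
    return result


def _stage_cbf(cfg: dict, seed: int, outdir: Path | None) -> dict:
    trace = synth.simulate_cilia_trace(
        cfg["cbf_hz"], cfg["frame_rate_hz"], cfg["duration_s"],
        noise_sd=cfg["noise_sd"], seed=seed,
    )
    result = cbf_mod.count_peaks_cbf(trace, cfg["frame_rate_hz"])
    if outdir is not None:
        np.savetxt(outdir / "cilia_trace.csv", trace, delimiter=",")
    return result.to_dict()


def _stage_thickness(cfg: dict, seed: int, outdir: Path | None) -> dict:
    stack, truth = synth.simulate_two_layer_zstack(
        cfg["gap_um"], cfg["z_spacing_um"], seed=seed,
    )
    result = morpho.mucus_thickness(stack)
    if outdir is not None:
        stack.write_tiff(outdir / "zstack.tif")
    return {**result.to_dict(), "ground_truth": truth}


def _stage_morphometry(cfg: dict, seed: int, outdir: Path | None) -> dict:
    rng = np.random.default_rng(seed)
    n = cfg["field_px"]
    yy, xx = np.mgrid[0:n, 0:n]
    nuclei = np.zeros((n, n))
    for _ in range(cfg["n_nuclei"]):
        cy, cx = rng.uniform(8, n - 8, size=2)
        nuclei[(yy - cy) ** 2 + (xx - cx) ** 2 <= 16] = 500.0
    marker = np.zeros((n, n))
    marker[: int(cfg["marker_coverage"] * n), :] = 800.0
    res = morpho.marker_area_per_cell(marker, nuclei, marker_threshold=100.0,
                                      pixel_size_um=cfg["pixel_size_um"])
    labels = _skmeasure.label(nuclei > 0)
    shapes = morpho.cell_shape_metrics(labels, cfg["pixel_size_um"])
    return {
        **res.to_dict(),
        "mean_cell_area_um2": float(shapes["area_um2"].mean()) if len(shapes) else None,
        "mean_circularity": float(shapes["circularity"].mean()) if len(shapes) else None,
        "mean_aspect_ratio": float(shapes["aspect_ratio"].mean()) if len(shapes) else None,
    }


_STAGE_RUNNERS = {
    "rheology": _stage_rheology,
    "impedance": _stage_impedance,
    "fluidics": _stage_fluidics,
    "cbf": _stage_cbf,
    "thickness": _stage_thickness,
    "morphometry": _stage_morphometry,
}


def run_pipeline(config: dict | None = None,
                 output_dir: str | Path | None = None) -> dict:
    """Execute the selected stages in dependency order.

    Returns the machine-readable report (also written to
    ``output_dir/report.json`` when an output directory is given). All
    stage seeds derive from the master ``seed`` by fixed offsets, so a
    fixed seed and configuration reproduce every output bit-identically.
    """
    cfg = _merged_config(config)
    unknown = [s for s in cfg["stages"] if s not in _STAGE_RUNNERS]
    if unknown:
        raise ValueError(f"unknown stages {unknown}; available: {STAGE_ORDER}")
    outdir = None
    if output_dir is not None:
        outdir = Path(output_dir)
        outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"seed": cfg["seed"], "stages": {}, "config": cfg}
    for stage in STAGE_ORDER:
        if stage not in cfg["stages"]:
            continue
        seed = cfg["seed"] + _SEED_OFFSETS[stage]
        logger.info("running stage %s (seed %d)", stage, seed)
        try:
            report["stages"][stage] = _STAGE_RUNNERS[stage](cfg[stage], seed, outdir)
        except Exception as exc:
            raise StageError(stage, exc) from exc
    if outdir is not None:
        (outdir / "report.json").write_text(
            json.dumps(report, indent=2, sort_keys=True, default=str)
        )
    return report


def _flat_metrics(report: dict) -> dict:
    """Pull the headline scalar estimates out of a run report."""
    out: dict = {}
    stages = report.get("stages", {})
    if "rheology" in stages:
        out["viscosity_cp"] = stages["rheology"]["viscosity_cp_mean"]
        if "elastic_modulus_pa_mean" in stages["rheology"]:
            out["elastic_modulus_pa"] = stages["rheology"]["elastic_modulus_pa_mean"]
    if "cbf" in stages:
        out["cbf_hz"] = stages["cbf"]["cbf_hz"]
    if "thickness" in stages:
        out["thickness_um"] = stages["thickness"]["thickness_um"]
    if "impedance" in stages:
        rows = stages["impedance"]["timecourse"]
        if rows:
            last = rows[-1]
            out["r_teer_ohm"] = last["r_teer_ohm"]
            out["c_membrane_nf"] = last["c_membrane_nf"]
    if "fluidics" in stages:
        out["membrane_shear_dyn_cm2"] = stages["fluidics"]["membrane_shear_dyn_cm2_mean"]
    return out


def compare_conditions(
    reports_by_group: dict[str, list[dict]],
    stat_test: str | None = None,
) -> pd.DataFrame:
    """Group means +/- SD per metric across run reports.

    ``stat_test`` may be 'anova' or 'kruskal' to append a p-value per
    metric (delegated to scipy.stats); it requires at least two groups
    with at least two runs each carrying the metric.
    """
    if not reports_by_group:
        raise ValueError("no groups given")
    values: dict[str, dict[str, list[float]]] = {}
    for group, reports in reports_by_group.items():
        if not reports:
            raise ValueError(f"group '{group}' is empty")
        for report in reports:
            for metric, value in _flat_metrics(report).items():
                values.setdefault(metric, {}).setdefault(group, []).append(value)
    rows = []
    for metric, by_group in values.items():
        pval = None
        if stat_test is not None and len(by_group) >= 2:
            samples = [v for v in by_group.values() if len(v) >= 2]
            if len(samples) == len(by_group):
                if stat_test == "anova":
                    pval = float(scipy_stats.f_oneway(*samples).pvalue)
                elif stat_test == "kruskal":
                    pval = float(scipy_stats.kruskal(*samples).pvalue)
                else:
                    raise ValueError(f"unknown stat_test {stat_test!r}")
        for group, vals in by_group.items():
            rows.append(
                {
                    "metric": metric,
                    "group": group,
                    "n": len(vals),
                    "mean": float(np.mean(vals)),
                    "sd": float(np.std(vals, ddof=1)) if len(vals) > 1 else None,
                    "p_value": pval,
                }
            )
    return pd.DataFrame(rows, columns=["metric", "group", "n", "mean", "sd", "p_value"])
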