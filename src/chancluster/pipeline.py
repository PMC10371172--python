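"""Reproducible multi-stage runs: config, seed derivation, manifest.

A run executes a selection of stages (synthetic generation, assembly
simulation, cluster analysis, sparklet analysis, IV simulation) in
dependency order under one global seed. Every stage receives its own seed
derived deterministically from (global seed, stage name), every output file
is checksummed into a manifest, and the manifest plus config hash make
re-runs bit-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .assembly_sim import AssemblyParams, fit_exponential, simulate_assembly
from .cluster_metrics import (
    MacroThreshold,
    classify_macro_micro,
    restrict_to_membrane,
    segment_2d,
    segment_3d,
    summarize,
)
from .kv_current import KvModelParams, VoltageProtocol, calibrate_gmax, iv_curve
from .sparklet import CoupledGatingParams, analyze_site
from .synthetic_data import (
    FieldSpec,
    gen_confocal_stack,
    gen_localization_field,
    gen_sparklet_traces,
    write_field,
    write_stack,
)

logger = logging.getLogger(__name__)

STAGES = ("field", "stack", "assembly", "sparklets", "iv")


def derive_seed(global_seed: int, stage: str) -> int:
    """Stable per-stage seed: SHA-256 of (global_seed, stage), below 2**31."""
    digest = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def _config_hash(config: dict) -> str:
    return hashlib.sha256(json.dumps(config, sort_keys=True, default=str).encode()).hexdigest()


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def load_config(path: str | Path) -> dict:
    text = Path(path).read_text()
    if str(path).endswith((".yaml", ".yml")):
        return yaml.safe_load(text)
    return json.loads(text)


def validate_config(config: dict) -> dict:
    """Schema-light validation: known stages, integer seed, per-stage dicts."""
    cfg = dict(config)
    stages = cfg.get("stages", [])
    unknown = [s for s in stages if s not in STAGES]
    if unknown:
        raise ValueError(f"unknown stages {unknown}; valid: {STAGES}")
    seed = cfg.get("seed", 0)
    if not isinstance(seed, int) or seed < 0:
        raise ValueError("seed must be a non-negative integer")
    for s in stages:
        block = cfg.get(s, {})
        if not isinstance(block, dict):
            raise ValueError(f"config block for stage {s!r} must be a mapping")
    return cfg


def run_pipeline(config: dict, out_dir: str | Path) -> dict:
    """Execute the requested stages and return (and write) the run manifest."""
    cfg = validate_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    global_seed = cfg.get("seed", 0)
    manifest: dict = {
        "version": __version__,
        "config_hash": _config_hash(cfg),
        "global_seed": global_seed,
        "stages": {},
        "outputs": {},
    }
    written: list[Path] = []

    for stage in cfg.get("stages", []):
        seed = derive_seed(global_seed, stage)
        manifest["stages"][stage] = {"seed": seed}
        block = cfg.get(stage, {})
        logger.info("stage %s (seed %d)", stage, seed)

        if stage == "field":
            spec = FieldSpec(
                width_nm=block.get("width_nm", 20000.0),
                height_nm=block.get("height_nm", 20000.0),
                pixel_nm=block.get("pixel_nm", 20.0),
                psf_sigma_nm=block.get("psf_sigma_nm", 0.0),
                noise_sd=block.get("noise_sd", 0.0),
                seed=seed,
            )
            image, truth = gen_localization_field(
                spec, block.get("n_clusters", 500), block.get("mean_area_nm2", 2500.0)
            )
            paths = write_field(out, "field", image, truth, spec)
            clusters = segment_2d(image, spec.pixel_nm, block.get("threshold", 0.5))
            fit = fit_exponential(clusters.sizes) if len(clusters) >= 30 else None
            report = {
                "n_true": len(truth),
                "n_detected": len(clusters),
                "fitted_scale_nm2": fit.scale if fit else None,
                "fit_r_squared": fit.r_squared if fit else None,
            }
            rp = out / "field_report.json"
            rp.write_text(json.dumps(report, indent=2))
            written += [*paths.values(), rp]

        elif stage == "stack":
            spec = FieldSpec(
                width_nm=block.get("width_nm", 15000.0),
                height_nm=block.get("height_nm", 15000.0),
                depth_um=block.get("depth_um", 6.0),
                pixel_nm=block.get("pixel_nm", 100.0),
                voxel_z_um=block.get("voxel_z_um", 0.13),
                psf_sigma_nm=block.get("psf_sigma_nm", 50.0),
                noise_sd=block.get("noise_sd", 0.02),
                seed=seed,
            )
            stack, mask, truth = gen_confocal_stack(
                spec,
                block.get("n_clusters", 150),
                block.get("mean_volume_um3", 0.09),
                shell=block.get("shell", "whole"),
            )
            paths = write_stack(out, "stack", stack, mask, truth, spec)
            clusters = segment_3d(
                stack,
                (spec.pixel_nm, spec.voxel_z_um),
                block.get("threshold", 0.15),
                min_diameter=tuple(block.get("min_diameter", (0.0, 0.0))),
            )
            clusters = restrict_to_membrane(clusters, mask)
            thr = MacroThreshold(block.get("macro_thr_um3", 0.03))
            macro, micro = classify_macro_micro(clusters, thr)
            clusters.to_frame().to_csv(out / "stack_clusters.csv", index=False)
            report = {
                "n_true": len(truth),
                "n_detected": len(clusters),
                "macro_pct": macro,
                "micro_pct": micro,
            }
            rp = out / "stack_report.json"
            rp.write_text(json.dumps(report, indent=2))
            written += [*paths.values(), out / "stack_clusters.csv", rp]

        elif stage == "assembly":
            params = AssemblyParams(
                P_n=block.get("P_n", 0.5),
                P_g=block.get("P_g", 0.2),
                P_r=block.get("P_r", 0.02),
                grid_w=block.get("grid_w", 128),
                grid_h=block.get("grid_h", 128),
                n_steps=block.get("n_steps", 2000),
                seed=seed,
            )
            dist = simulate_assembly(params)
            pd.DataFrame({"size_sites": dist.sizes}).to_csv(out / "assembly_sizes.csv", index=False)
            fit = fit_exponential(dist.sizes) if dist.sizes.size >= 30 else None
            report = {
                "params": dataclasses.asdict(params),
                "n_clusters": int(dist.sizes.size),
                "fitted_scale_sites": fit.scale if fit else None,
                "fit_r_squared": fit.r_squared if fit else None,
                "unverified_from_supplement": True,
            }
            rp = out / "assembly_report.json"
            rp.write_text(json.dumps(report, indent=2))
            written += [out / "assembly_sizes.csv", rp]

        elif stage == "sparklets":
            gparams = CoupledGatingParams(
                N=block.get("N", 3),
                p_open=block.get("p_open", 0.05),
                kappa=block.get("kappa", 0.3),
                n_frames=block.get("n_frames", 5000),
                seed=seed,
            )
            q = block.get("quantal_dF", 1.0)
            trace, true_k = gen_sparklet_traces(
                gparams, q, block.get("noise_sd", 0.15), block.get("fs_hz", 100.0)
            )
            trace.to_csv(out / "sparklet_trace.csv", index=False)
            site = analyze_site(trace, q, gparams.N, n_boot=block.get("n_boot", 200), seed=seed)
            report = {
                "true_kappa": gparams.kappa,
                "nPs": site.nPs,
                "activity_class": site.activity_class,
                "kappa_hat": site.kappa_hat,
                "kappa_ci": list(site.kappa_ci),
                "n_quantal_levels": site.n_quantal_levels,
                "coupling_model": "frame-wise coordination mixture",
            }
            rp = out / "sparklet_report.json"
            rp.write_text(json.dumps(report, indent=2))
            written += [out / "sparklet_trace.csv", rp]

        elif stage == "iv":
            protocol = VoltageProtocol(
                holding_mV=block.get("holding_mV", -70.0),
                step_mVs=tuple(block.get("step_mVs", tuple(range(-70, 80, 10)))),
                step_ms=block.get("step_ms", 500.0),
                dt_ms=block.get("dt_ms", 0.05),
            )
            params = KvModelParams()
            target = block.get("calibrate_to_pA_pF", 7006.0)
            at_v = block.get("calibrate_at_mV", 50.0)
            params = calibrate_gmax(params, target, at_v, protocol)
            rows = []
            for f in block.get("fractions", (1.0, 0.5, 0.1, 0.01)):
                curve = iv_curve(dataclasses.replace(params, f_functional=f), protocol)
                for v, d in zip(curve.voltages_mV, curve.densities_pA_pF):
                    rows.append({"f_functional": f, "V_mV": v, "I_pA_per_pF": d})
            pd.DataFrame(rows).to_csv(out / "iv_curves.csv", index=False)
            written.append(out / "iv_curves.csv")

    for p in written:
        manifest["outputs"][str(p.relative_to(out))] = _checksum(p)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
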