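"""End-to-end stiffness-design workflow: simulate/load → fit → map → design → verify.

The run writes a reproducible artifact bundle into an output directory:

* ``doe_data.csv`` — the measurement table used (synthetic unless supplied)
* ``model_actual.json`` / ``model_coded.json`` — the fitted model, both forms
* ``diagnostics.json`` / ``anova.csv`` — fit statistics
* ``parameter_map.csv`` — modulus over (hyaluronidase, time) at a fixed formulation
* ``design_solutions.csv`` — inverse-design settings for the target moduli and
  tissue presets
* ``verification.json`` — simulated verification trials vs prediction intervals

All outputs are deterministic functions of the inputs and the seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import pandas as pd

from . import __version__, design, io, rsm, synthetic
from .exceptions import GelrsmError
from .fitting import fit_quadratic

log = logging.getLogger("gelrsm")

DEFAULT_TARGETS = (5.0, 15.0, 30.0, 65.0, 110.0)
DEFAULT_MAP_FORMULATION = {"gelma": 5.0, "hama": 3.0}

DEFAULTS = {
    "seed": 0,
    "noise_sd_modulus": 8.0,
    "replicates": 3,
    "data": None,  # path to a DoE CSV; if None, simulate
    "targets": list(DEFAULT_TARGETS),
    "tissues": ["brain", "liver", "lung", "heart"],
    "map_gelma": DEFAULT_MAP_FORMULATION["gelma"],
    "map_hama": DEFAULT_MAP_FORMULATION["hama"],
    "map_resolution": 50,
    "n_rep": 3,
    "level": 0.95,
}


def resolve_config(overrides: dict | None = None) -> dict:
    config = dict(DEFAULTS)
    for key, value in (overrides or {}).items():
        if key not in DEFAULTS:
            raise GelrsmError(f"unknown configuration key {key!r}")
        if value is not None:
            config[key] = value
    return config


def end_to_end(config: dict | None, outdir) -> dict[str, Path]:
    """Run the full pipeline; returns the mapping of artifact names to paths."""
    cfg = resolve_config(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log.info("gelrsm %s | seed=%s | resolved config: %s", __version__,
             cfg["seed"], cfg)

    sim = synthetic.SimulationConfig(
        seed=int(cfg["seed"]),
        noise_sd_modulus=float(cfg["noise_sd_modulus"]),
        replicates=int(cfg["replicates"]),
    )
    if cfg["data"]:
        log.info("loading measurements from %s (sha256=%s)", cfg["data"],
                 io.file_digest(cfg["data"]))
        data = io.load_doe_table(cfg["data"])
    else:
        log.info("simulating digestion sweep from the reference model")
        data = synthetic.generate_doe_dataset(rsm.reference_model(), sim)

    paths: dict[str, Path] = {}
    paths["doe_data"] = outdir / "doe_data.csv"
    io.save_doe_table(data, paths["doe_data"])

    fit = fit_quadratic(data, form=rsm.FORM_ACTUAL)
    log.info("fit: R²=%.4f adjR²=%.4f AP=%.2f σ̂=%.3f kPa",
             fit.diagnostics.r2, fit.diagnostics.adj_r2,
             fit.diagnostics.adequate_precision, fit.sigma)
    paths["model_actual"] = outdir / "model_actual.json"
    paths["model_coded"] = outdir / "model_coded.json"
    io.save_model(fit.model, paths["model_actual"], provenance="gelrsm end_to_end fit")
    io.save_model(fit.coded_model, paths["model_coded"],
                  provenance="gelrsm end_to_end fit")
    paths["diagnostics"] = outdir / "diagnostics.json"
    io.save_diagnostics(fit.diagnostics, paths["diagnostics"])
    paths["anova"] = outdir / "anova.csv"
    io.save_anova(fit.diagnostics, paths["anova"])

    map_df = design.parameter_map(
        fit.model,
        {"gelma": float(cfg["map_gelma"]), "hama": float(cfg["map_hama"])},
        hase_levels=None if cfg["map_resolution"] == 50 else
        _linspace_levels(fit.space, rsm.HASE, cfg["map_resolution"]),
        time_levels=None if cfg["map_resolution"] == 50 else
        _linspace_levels(fit.space, rsm.TIME, cfg["map_resolution"]),
    )
    paths["parameter_map"] = outdir / "parameter_map.csv"
    io.save_parameter_map(map_df, paths["parameter_map"])

    rows = []
    for target in cfg["targets"]:
        sol = design.design_for_target(fit.model, float(target))
        rows.append(_solution_row(f"target:{target:g}kPa", sol))
    for tissue in cfg["tissues"]:
        sol = design.design_for_tissue(fit.model, tissue)
        rows.append(_solution_row(f"tissue:{tissue}", sol))
    paths["design_solutions"] = outdir / "design_solutions.csv"
    pd.DataFrame(rows).to_csv(paths["design_solutions"], index=False,
                              float_format="%.17g")

    ver = design.run_verification_protocol(
        fit, cfg["targets"], noise_sd=float(cfg["noise_sd_modulus"]),
        n_rep=int(cfg["n_rep"]), seed=int(cfg["seed"]), level=float(cfg["level"]),
    )
    payload = [
        {
            "target_kpa": v.target,
            "settings": v.solution.settings,
            "predicted_kpa": v.solution.predicted,
            "pi_lower_kpa": v.interval.lower,
            "pi_upper_kpa": v.interval.upper,
            "trial_mean_kpa": v.trial_mean,
            "inside_pi": v.inside,
        }
        for v in ver
    ]
    paths["verification"] = outdir / "verification.json"
    paths["verification"].write_text(json.dumps(payload, indent=2) + "\n",
                                     encoding="utf-8")
    log.info("verification: %d/%d trial means inside their PIs",
             sum(v.inside for v in ver), len(ver))
    return paths


def _linspace_levels(space, name, resolution):
    import numpy as np

    f = space.factor(name)
    return np.linspace(f.low, f.high, int(resolution))


def _solution_row(label: str, sol: design.DesignSolution) -> dict:
    return {
        "label": label,
        "gelma_pct": sol.settings["gelma"],
        "hama_pct": sol.settings["hama"],
        "hase_u_per_ml": sol.settings["hase"],
        "time_h": sol.settings["time"],
        "predicted_kpa": sol.predicted,
        "target_kpa": sol.target,
        "residual_kpa": sol.residual,
        "feasible": sol.feasible,
        "nearest_achievable_kpa": sol.nearest_achievable,
    }
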