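"""Readers and writers for the pipeline's file formats.

CSV dialect: comma-separated, UTF-8, mandatory header row, ``.`` decimal
separator.  JSON numbers are written at full double precision (Python's
shortest-round-trip float repr), so every writer round-trips through its
reader without loss.

DoE measurement tables use the headers
``gelma_pct,hama_pct,hase_u_per_ml,time_h,modulus_kpa`` (+ optional
``replicate``); model files are JSON with explicit factors, term maps and a
provenance string.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import rsm
from .diffusion import DiffusionProfile, normalize_profile
from .exceptions import InputError
from .fitting import DoEDataset, FitDiagnostics
from .photopoly import WorkingCurve

__all__ = [
    "load_doe_table",
    "save_doe_table",
    "load_model",
    "save_model",
    "model_to_dict",
    "model_from_dict",
    "save_diagnostics",
    "save_anova",
    "load_working_curve_table",
    "save_working_curve",
    "load_diffusion_profile",
    "save_parameter_map",
    "file_digest",
]

DOE_COLUMNS = {
    "gelma_pct": rsm.GELMA,
    "hama_pct": rsm.HAMA,
    "hase_u_per_ml": rsm.HASE,
    "time_h": rsm.TIME,
    "modulus_kpa": "modulus",
}
_DOE_REVERSE = {v: k for k, v in DOE_COLUMNS.items()}


def load_doe_table(path) -> DoEDataset:
    """Read a formulation/digestion measurement CSV into a typed dataset.

    Errors name the offending row (1-based, excluding the header) and column.
    """
    frame = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in DOE_COLUMNS if c not in frame.columns]
    if missing:
        raise InputError(f"{path}: missing required column(s) {missing}")
    for col in DOE_COLUMNS:
        vals = pd.to_numeric(frame[col], errors="coerce")
        bad = np.where(vals.isna() & frame[col].notna())[0]
        if len(bad) or vals.isna().any():
            row = int(bad[0]) + 1 if len(bad) else int(np.where(vals.isna())[0][0]) + 1
            raise InputError(f"{path}: non-numeric or missing value in column "
                             f"{col!r} at data row {row}")
        if (vals < 0).any():
            row = int(np.where(vals < 0)[0][0]) + 1
            raise InputError(f"{path}: negative value in column {col!r} at "
                             f"data row {row}")
        frame[col] = vals.astype(float)
    out = frame.rename(columns=DOE_COLUMNS)
    keep = list(DOE_COLUMNS.values()) + (["replicate"] if "replicate" in out else [])
    return DoEDataset(out[keep])


def save_doe_table(data: DoEDataset, path) -> None:
    frame = data.frame.rename(columns=_DOE_REVERSE)
    cols = list(DOE_COLUMNS) + (["replicate"] if "replicate" in frame else [])
    frame[cols].to_csv(path, index=False, float_format="%.17g")


def model_to_dict(model: rsm.QuadraticModel, provenance: str = "") -> dict:
    return {
        "form": model.form,
        "factors": [
            {"name": f.name, "units": f.units, "low": f.low, "high": f.high}
            for f in model.space.factors
        ],
        "intercept": model.intercept,
        "linear": dict(model.linear),
        "interaction": {f"{a}*{b}": v for (a, b), v in model.interaction.items()},
        "quadratic": dict(model.quadratic),
        "term_set": list(model.term_set),
        "provenance": provenance,
    }


def model_from_dict(d: dict) -> rsm.QuadraticModel:
    space = rsm.DesignSpace(
        tuple(
            rsm.Factor(f["name"], f["units"], float(f["low"]), float(f["high"]))
            for f in d["factors"]
        )
    )
    interaction = {}
    for key, v in d.get("interaction", {}).items():
        a, b = key.split("*")
        interaction[(a, b)] = float(v)
    model = rsm.QuadraticModel(
        form=d["form"],
        intercept=float(d["intercept"]),
        linear={k: float(v) for k, v in d.get("linear", {}).items()},
        interaction=interaction,
        quadratic={k: float(v) for k, v in d.get("quadratic", {}).items()},
        space=space,
    )
    stated = d.get("term_set")
    if stated is not None and tuple(stated) != model.term_set:
        raise InputError(
            f"model file term_set {stated} disagrees with its coefficient maps "
            f"{list(model.term_set)}"
        )
    return model


def save_model(model: rsm.QuadraticModel, path, provenance: str = "") -> None:
    Path(path).write_text(
        json.dumps(model_to_dict(model, provenance), indent=2) + "\n",
        encoding="utf-8",
    )


def load_model(path) -> rsm.QuadraticModel:
    return model_from_dict(json.loads(Path(path).read_text(encoding="utf-8")))


def save_diagnostics(diag: FitDiagnostics, path) -> None:
    payload = {
        "r2": diag.r2,
        "adj_r2": diag.adj_r2,
        "adequate_precision": diag.adequate_precision,
        "residual_sd_kpa": diag.residual_sd,
        "dof": diag.dof,
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n", encoding="utf-8")


def save_anova(diag: FitDiagnostics, path) -> None:
    diag.anova.to_csv(path, index=False, float_format="%.17g")


def load_working_curve_table(path) -> pd.DataFrame:
    """Working-curve CSV: ``exposure,depth_um`` + optional ``absorber_pct``
    grouping column (one curve per photoabsorber level)."""
    frame = pd.read_csv(path, float_precision="round_trip")
    for col in ("exposure", "depth_um"):
        if col not in frame.columns:
            raise InputError(f"{path}: missing required column {col!r}")
        frame[col] = pd.to_numeric(frame[col], errors="raise")
    return frame


def save_working_curve(curve: WorkingCurve, path) -> None:
    payload = {
        "dp_um": curve.dp,
        "ec": curve.ec,
        "ec_units": curve.ec_units,
        "n_points": len(curve.measurements),
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n", encoding="utf-8")


def load_diffusion_profile(path, time_s: float) -> DiffusionProfile:
    """Diffusion CSV ``x_cm,intensity``; normalization applied on load."""
    frame = pd.read_csv(path, float_precision="round_trip")
    for col in ("x_cm", "intensity"):
        if col not in frame.columns:
            raise InputError(f"{path}: missing required column {col!r}")
    return normalize_profile(
        frame["x_cm"].to_numpy(dtype=float),
        frame["intensity"].to_numpy(dtype=float),
        time_s,
    )


def save_parameter_map(map_df: pd.DataFrame, path) -> None:
    out = map_df.rename(columns={"modulus": "modulus_kpa"})
    out.to_csv(path, index=False, float_format="%.17g")


def file_digest(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()
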