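"""Synthetic measurement generators for the stiffness-design pipeline.

Every stage of the pipeline (model fitting, working-curve fitting, diffusivity
estimation) can be exercised without laboratory data: these generators emit
tables with the statistical structure the estimators assume — a full-factorial
digestion sweep with replicate Gaussian noise on the modulus, Jacobs-curve
cure-depth measurements, and erfc axial diffusion profiles.

Defaults encode the study conditions of the GelMA/HAMA system: the factorial
sweep GelMA ∈ {2.5, 5.0, 7.5} % × HAMA ∈ {1.5, 3.0} % × hyaluronidase
∈ {0, 75, 150, 300, 500, 1000} U/mL × time ∈ {0, 1, 2, 4, 8, 12, 24} h in
triplicate, with noise scales matching the reported measurement SDs
(modulus ≈ 8 kPa, cure depth ≈ 20 µm, normalized intensity ≈ 0.02).

All generators are deterministic functions of (parameters, seed).  A single
integer seed drives a counter-based Philox generator; each generator family
draws from its own sub-stream so composed pipelines do not cross-contaminate.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import rsm
from .diffusion import DiffusionProfile, predict_profile
from .exceptions import InputError
from .fitting import DoEDataset
from .photopoly import WorkingCurve

__all__ = [
    "SimulationConfig",
    "generate_doe_dataset",
    "generate_working_curve_data",
    "generate_diffusion_profile",
]

_STREAMS = {"doe": 0, "workcurve": 1, "diffusion": 2}


@dataclass(frozen=True)
class SimulationConfig:
    """Noise scales, replicate count and factor grid for the generators."""

    seed: int = 0
    noise_sd_modulus: float = 8.0  # kPa
    noise_sd_depth: float = 20.0  # µm
    noise_sd_intensity: float = 0.02  # dimensionless
    replicates: int = 3
    gelma_levels: tuple[float, ...] = (2.5, 5.0, 7.5)
    hama_levels: tuple[float, ...] = (1.5, 3.0)
    hase_levels: tuple[float, ...] = (0.0, 75.0, 150.0, 300.0, 500.0, 1000.0)
    time_levels: tuple[float, ...] = (0.0, 1.0, 2.0, 4.0, 8.0, 12.0, 24.0)
    proportional_noise: bool = False  # if set, modulus SD = cv × |mean|
    cv: float = 0.05

    def __post_init__(self) -> None:
        if min(self.noise_sd_modulus, self.noise_sd_depth,
               self.noise_sd_intensity) < 0:
            raise InputError("noise SDs must be >= 0")
        if self.replicates < 1:
            raise InputError("replicates must be >= 1")

    def rng(self, stream: str) -> np.random.Generator:
        """Independent sub-stream per generator family."""
        ss = np.random.SeedSequence(self.seed, spawn_key=(_STREAMS[stream],))
        return np.random.Generator(np.random.Philox(ss))


def generate_doe_dataset(
    model: rsm.QuadraticModel, config: SimulationConfig = SimulationConfig()
) -> DoEDataset:
    """Full-factorial digestion sweep with replicate Gaussian modulus noise.

    Modulus draws below the 0 kPa physical floor are truncated to 0 (keeping
    the generator a pure function); the count is reported in
    ``frame.attrs["n_truncated"]``.
    """
    if model.form != rsm.FORM_ACTUAL:
        raise InputError("generator expects an actual-units model")
    grid = list(
        itertools.product(
            config.gelma_levels, config.hama_levels, config.hase_levels,
            config.time_levels,
        )
    )
    if not grid:
        raise InputError("factor grid is empty")
    rng = config.rng("doe")
    rows = []
    for gelma, hama, hase, time in grid:
        for rep in range(config.replicates):
            rows.append((gelma, time, hase, hama, rep))
    frame = pd.DataFrame(
        rows, columns=[rsm.GELMA, rsm.TIME, rsm.HASE, rsm.HAMA, "replicate"]
    )
    mean = np.asarray(
        rsm.evaluate_model(
            model,
            {n: frame[n].to_numpy() for n in (rsm.GELMA, rsm.TIME, rsm.HASE,
                                              rsm.HAMA)},
        )
    )
    sd = (
        config.cv * np.abs(mean)
        if config.proportional_noise
        else config.noise_sd_modulus
    )
    modulus = mean + rng.normal(0.0, 1.0, size=len(frame)) * sd
    n_truncated = int((modulus < 0).sum())
    frame["modulus"] = np.maximum(modulus, 0.0)
    frame.attrs["n_truncated"] = n_truncated
    return DoEDataset(frame)


def generate_working_curve_data(
    dp: float,
    ec: float,
    exposures,
    config: SimulationConfig = SimulationConfig(),
) -> pd.DataFrame:
    """Cure-depth measurements dp·ln(E/ec) + noise, truncated at 0 µm.

    Exposures at or below the critical exposure are flagged ``no_cure`` (depth
    recorded as 0) rather than producing negative depths.
    """
    if not (dp > 0 and ec > 0):
        raise InputError("dp and ec must be positive")
    exposures = np.asarray(exposures, dtype=float)
    if (exposures <= 0).any():
        raise InputError("exposures must be positive")
    rng = config.rng("workcurve")
    no_cure = exposures <= ec
    depth = np.where(no_cure, 0.0, dp * np.log(np.maximum(exposures, ec) / ec))
    if config.noise_sd_depth > 0:
        noisy = depth + rng.normal(0.0, config.noise_sd_depth, size=len(exposures))
        depth = np.where(no_cure, 0.0, np.maximum(noisy, 0.0))
    return pd.DataFrame(
        {"exposure": exposures, "depth_um": depth, "no_cure": no_cure}
    )


def generate_diffusion_profile(
    d_eff: float,
    t: float,
    x_grid,
    config: SimulationConfig = SimulationConfig(),
) -> DiffusionProfile:
    """erfc profile with intensity noise, clipped to [-0.1, 1.1] and
    endpoint-renormalized (as the imaging protocol would)."""
    x = np.asarray(x_grid, dtype=float)
    f = np.asarray(predict_profile(d_eff, t, x), dtype=float)
    if config.noise_sd_intensity > 0:
        rng = config.rng("diffusion")
        f = f + rng.normal(0.0, config.noise_sd_intensity, size=x.shape)
    f = np.clip(f, -0.1, 1.1)
    if f[0] == f[-1]:
        raise InputError("degenerate synthetic profile (equal endpoints)")
    f = (f - f[-1]) / (f[0] - f[-1])
    return DiffusionProfile(x=x, f=f, t=float(t))
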