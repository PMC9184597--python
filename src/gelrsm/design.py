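"""Inverse stiffness design over the bounded formulation/digestion space.

Given the fitted quadratic stiffness model, find GelMA/HAMA concentrations and
hyaluronidase digestion parameters that achieve a target post-digestion
compressive modulus.  The objective |ŷ(x) − target| is minimized over the
design box by bounded gradient descent (analytic gradient of the quadratic)
from a fixed 81-point multistart (3 levels per factor); the quadratic-over-box
structure makes this reliable and cheap.  Ties among equally good solutions
are broken toward the gentlest digestion — minimal enzyme concentration, then
minimal digestion time — since harsh digestion conditions are hostile to
embedded cells.

Also provides the parameter maps and 3-D surface grids used to visualize the
model, tissue-stiffness presets (brain, liver, lung, heart), and a simulated
verification protocol that checks inverse-design solutions against 95%
prediction intervals.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from . import rsm
from .exceptions import InputError
from .fitting import FitResult, PredictionInterval, predict_with_interval

__all__ = [
    "TissuePreset",
    "TISSUE_PRESETS",
    "DesignSolution",
    "design_for_target",
    "design_for_tissue",
    "achievable_range",
    "parameter_map",
    "iso_modulus_contours",
    "surface_grid",
    "SurfaceGrid",
    "run_verification_protocol",
    "VerificationResult",
]


@dataclass(frozen=True)
class TissuePreset:
    """Named soft-tissue compressive-modulus range (kPa)."""

    name: str
    modulus_range: tuple[float, float]

    def __post_init__(self) -> None:
        lo, hi = self.modulus_range
        if not lo <= hi:
            raise InputError(f"preset {self.name!r}: empty modulus range")

    @property
    def midpoint(self) -> float:
        return 0.5 * sum(self.modulus_range)


TISSUE_PRESETS: dict[str, TissuePreset] = {
    "brain": TissuePreset("brain", (1.0, 4.0)),
    "liver": TissuePreset("liver", (1.0, 10.0)),
    "lung": TissuePreset("lung", (10.0, 15.0)),
    "heart": TissuePreset("heart", (30.0, 60.0)),
}


@dataclass(frozen=True)
class DesignSolution:
    """Result of an inverse-design query."""

    settings: dict[str, float]  # actual units, inside the box
    predicted: float  # kPa, forward model at settings
    target: float  # kPa
    feasible: bool
    at_bound: dict[str, bool]
    nearest_achievable: float | None = None  # set when infeasible
    warnings: tuple[str, ...] = ()

    @property
    def residual(self) -> float:
        return abs(self.predicted - self.target)


def _as_actual(model: rsm.QuadraticModel) -> rsm.QuadraticModel:
    return model if model.form == rsm.FORM_ACTUAL else rsm.to_actual(model)


def _quad_arrays(model: rsm.QuadraticModel):
    """(b, C) with f(x) = a0 + bᵀx + xᵀCx, C symmetric, in space factor order."""
    names = model.space.names
    idx = {n: i for i, n in enumerate(names)}
    b = np.zeros(len(names))
    C = np.zeros((len(names), len(names)))
    for n, v in model.linear.items():
        b[idx[n]] = v
    for n, v in model.quadratic.items():
        C[idx[n], idx[n]] = v
    for (p, q), v in model.interaction.items():
        C[idx[p], idx[q]] += 0.5 * v
        C[idx[q], idx[p]] += 0.5 * v
    return b, C


def _multistart_points(space: rsm.DesignSpace) -> list[np.ndarray]:
    levels = [(f.low, f.center, f.high) for f in space.factors]
    return [np.array(p) for p in itertools.product(*levels)]


def _minimize_objective(model, target, space, starts):
    """Run bounded L-BFGS-B from each start; return (x, |resid|) candidates."""
    b, C = _quad_arrays(model)
    a0 = model.intercept
    bounds = [(f.low, f.high) for f in space.factors]

    def fun(x):
        d = a0 + b @ x + x @ C @ x - target
        return d * d

    def jac(x):
        d = a0 + b @ x + x @ C @ x - target
        return 2.0 * d * (b + 2.0 * C @ x)

    out = []
    for x0 in starts:
        res = optimize.minimize(fun, x0, jac=jac, method="L-BFGS-B", bounds=bounds)
        out.append((res.x, float(np.sqrt(max(res.fun, 0.0)))))
    return out


def _select_solution(candidates, space: rsm.DesignSpace, tie_tol: float = 1e-6):
    """Best candidate; ties (residual within tie_tol of best) broken by
    minimal hyaluronidase concentration, then minimal digestion time."""
    best = min(r for _, r in candidates)
    eligible = [(x, r) for x, r in candidates if r <= best + tie_tol]
    names = space.names
    i_hase = names.index(rsm.HASE) if rsm.HASE in names else None
    i_time = names.index(rsm.TIME) if rsm.TIME in names else None

    def key(c):
        x, r = c
        return (
            x[i_hase] if i_hase is not None else 0.0,
            x[i_time] if i_time is not None else 0.0,
            r,
            tuple(x),  # full determinism
        )

    return min(eligible, key=key)


def achievable_range(
    model: rsm.QuadraticModel, space: rsm.DesignSpace | None = None
) -> tuple[float, float]:
    """(min, max) of the model over the design box, by multistart optimization."""
    model = _as_actual(model)
    space = space or model.space
    b, C = _quad_arrays(model)
    a0 = model.intercept
    bounds = [(f.low, f.high) for f in space.factors]
    starts = _multistart_points(space)

    def extremum(sign):
        best = None
        for x0 in starts:
            res = optimize.minimize(
                lambda x: sign * (a0 + b @ x + x @ C @ x),
                x0,
                jac=lambda x: sign * (b + 2.0 * C @ x),
                method="L-BFGS-B",
                bounds=bounds,
            )
            v = sign * res.fun
            if best is None or (sign > 0 and v < best) or (sign < 0 and v > best):
                best = v
        return float(best)

    return extremum(1.0), extremum(-1.0)


def design_for_target(
    model: rsm.QuadraticModel,
    target: float,
    space: rsm.DesignSpace | None = None,
    constraints: dict[str, tuple[float, float]] | None = None,
    success_tol: float = 0.01,
) -> DesignSolution:
    """Find in-range factor settings whose predicted modulus matches ``target``.

    ``constraints`` optionally narrows individual factor bounds, e.g. to pin a
    formulation while designing the digestion.  An out-of-range target yields
    an explicit infeasibility result carrying the nearest achievable modulus,
    never a silent clamp.
    """
    if not target > 0:
        raise InputError("target modulus must be positive")
    model = _as_actual(model)
    space = space or model.space
    if constraints:
        factors = []
        for f in space.factors:
            if f.name in constraints:
                lo, hi = constraints[f.name]
                if lo < f.low or hi > f.high:
                    raise InputError(
                        f"constraint for {f.name!r} exceeds the design space"
                    )
                f = rsm.Factor(f.name, f.units, lo, hi)
            factors.append(f)
        space = rsm.DesignSpace(tuple(factors))

    candidates = _multistart_points(space)
    results = _minimize_objective(model, target, space, candidates)
    x, resid = _select_solution(results, space)
    settings = {n: float(v) for n, v in zip(space.names, x)}
    predicted = float(rsm.evaluate_model(model, settings))
    at_bound = {
        f.name: bool(
            abs(settings[f.name] - f.low) < 1e-9 * (f.high - f.low)
            or abs(settings[f.name] - f.high) < 1e-9 * (f.high - f.low)
        )
        for f in space.factors
    }
    warn = ()
    if predicted < 0:
        warn = ("predicted modulus is negative: the empirical quadratic is "
                "outside its physically meaningful range here",)
    if resid <= success_tol:
        return DesignSolution(settings, predicted, target, True, at_bound,
                              warnings=warn)
    lo, hi = achievable_range(model, space)
    nearest = float(np.clip(target, lo, hi))
    return DesignSolution(settings, predicted, target, False, at_bound,
                          nearest_achievable=nearest, warnings=warn)


def design_for_tissue(
    model: rsm.QuadraticModel,
    preset: TissuePreset | str,
    space: rsm.DesignSpace | None = None,
) -> DesignSolution:
    """Design toward the midpoint of a tissue-stiffness preset range."""
    if isinstance(preset, str):
        try:
            preset = TISSUE_PRESETS[preset]
        except KeyError:
            raise InputError(
                f"unknown tissue preset {preset!r}; known: {sorted(TISSUE_PRESETS)}"
            ) from None
    return design_for_target(model, preset.midpoint, space=space)


@dataclass(frozen=True)
class SurfaceGrid:
    """Model response over a 2-D slice of the design space."""

    x_name: str
    y_name: str
    x: np.ndarray
    y: np.ndarray
    values: np.ndarray  # shape (len(y), len(x))
    fixed: dict[str, float]
    out_of_range: bool = False


def surface_grid(
    model: rsm.QuadraticModel,
    varying: tuple[str, str],
    fixed: dict[str, float],
    resolution: int = 50,
) -> SurfaceGrid:
    """Evaluate the model over a grid in two factors with the others fixed.

    Coordinates are interpreted in the model's own form: full factor ranges for
    an actual-units model, [-1, 1] for a coded one.  Fixed values outside range
    set the ``out_of_range`` flag rather than erroring.
    """
    if resolution < 1:
        raise InputError("resolution must be >= 1")
    xn, yn = varying
    space = model.space
    names = set(space.names)
    if {xn, yn} - names or set(fixed) - names:
        raise InputError("varying/fixed name unknown to the design space")
    if set(fixed) != names - {xn, yn}:
        raise InputError("fixed must cover exactly the non-varying factors")

    def axis(name):
        f = space.factor(name)
        lo, hi = (f.low, f.high) if model.form == rsm.FORM_ACTUAL else (-1.0, 1.0)
        if resolution == 1:
            return np.array([0.5 * (lo + hi)])
        return np.linspace(lo, hi, resolution)

    xv, yv = axis(xn), axis(yn)
    XX, YY = np.meshgrid(xv, yv)
    point = {xn: XX, yn: YY, **{k: np.full_like(XX, v) for k, v in fixed.items()}}
    values = np.asarray(rsm.evaluate_model(model, point))
    oor = False
    if model.form == rsm.FORM_ACTUAL:
        for k, v in fixed.items():
            f = space.factor(k)
            oor = oor or not (f.low <= v <= f.high)
    else:
        oor = any(abs(v) > 1 for v in fixed.values())
    return SurfaceGrid(xn, yn, xv, yv, values, dict(fixed), oor)


def parameter_map(
    model: rsm.QuadraticModel,
    fixed: dict[str, float],
    hase_levels=None,
    time_levels=None,
) -> pd.DataFrame:
    """Digestion parameter map: modulus over (hyaluronidase, time) at a fixed
    formulation.  Returns a long-format frame (hase, time, modulus) with an
    ``out_of_range`` attr flag if the fixed formulation leaves the space."""
    model = _as_actual(model)
    space = model.space
    if set(fixed) != {rsm.GELMA, rsm.HAMA}:
        raise InputError("fixed must supply exactly gelma and hama")
    hase_levels = (
        np.linspace(space.factor(rsm.HASE).low, space.factor(rsm.HASE).high, 50)
        if hase_levels is None
        else np.asarray(hase_levels, dtype=float)
    )
    time_levels = (
        np.linspace(space.factor(rsm.TIME).low, space.factor(rsm.TIME).high, 50)
        if time_levels is None
        else np.asarray(time_levels, dtype=float)
    )
    grid = surface_grid_from_levels(model, fixed, hase_levels, time_levels)
    H, T = np.meshgrid(hase_levels, time_levels)
    out = pd.DataFrame(
        {"hase": H.ravel(), "time": T.ravel(), "modulus": grid.ravel()}
    )
    oor = any(
        not (space.factor(k).low <= v <= space.factor(k).high)
        for k, v in fixed.items()
    )
    out.attrs["out_of_range"] = oor
    out.attrs["fixed"] = dict(fixed)
    return out


def surface_grid_from_levels(model, fixed, hase_levels, time_levels) -> np.ndarray:
    H, T = np.meshgrid(np.asarray(hase_levels, float), np.asarray(time_levels, float))
    point = {
        rsm.HASE: H,
        rsm.TIME: T,
        **{k: np.full_like(H, v) for k, v in fixed.items()},
    }
    return np.atleast_2d(np.asarray(rsm.evaluate_model(model, point)))


def iso_modulus_contours(map_df: pd.DataFrame, level: float):
    """Iso-modulus polylines [(hase, time) arrays] from a parameter map."""
    from contourpy import contour_generator

    hase = np.sort(map_df["hase"].unique())
    time = np.sort(map_df["time"].unique())
    Z = (
        map_df.pivot(index="time", columns="hase", values="modulus")
        .loc[time, hase]
        .to_numpy()
    )
    gen = contour_generator(x=hase, y=time, z=Z)
    return gen.lines(level)


@dataclass(frozen=True)
class VerificationResult:
    target: float
    solution: DesignSolution
    interval: PredictionInterval
    trial_mean: float
    trials: tuple[float, ...]
    inside: bool


def run_verification_protocol(
    fit: FitResult,
    targets,
    noise_sd: float = 8.0,
    n_rep: int = 3,
    seed: int = 0,
    level: float = 0.95,
) -> list[VerificationResult]:
    """Simulated analogue of the study's verification trials.

    For each target modulus: inverse-design a formulation/digestion setting,
    compute the 95% prediction interval for the mean of ``n_rep`` new
    measurements there, simulate those measurements (model prediction plus
    Gaussian noise), and flag whether the trial mean falls inside the PI.
    """
    if noise_sd < 0 or n_rep < 1:
        raise InputError("noise_sd must be >= 0 and n_rep >= 1")
    rng = np.random.Generator(np.random.Philox(np.random.SeedSequence(seed)))
    model = _as_actual(fit.model)
    out = []
    for target in targets:
        sol = design_for_target(model, float(target), space=fit.space)
        pi = predict_with_interval(fit, sol.settings, level=level, n_new=n_rep)
        trials = sol.predicted + rng.normal(0.0, noise_sd, size=n_rep)
        mean = float(np.mean(trials))
        out.append(
            VerificationResult(
                target=float(target),
                solution=sol,
                interval=pi,
                trial_mean=mean,
                trials=tuple(float(t) for t in trials),
                inside=pi.contains(mean),
            )
        )
    return out
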