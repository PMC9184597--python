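"""Jacobs working curve and radial print-resolution calculations.

In projection photopolymerization the cure depth of a resin layer follows the
Jacobs working curve

    C_d = D_p ln(E / E_c),

with D_p the light penetration depth (µm) and E_c the critical exposure at the
gelation point.  Plotting measured cure depth against ln(exposure) gives a
straight line whose slope is D_p and whose x-intercept is ln(E_c) — the
standard linearization, fitted here by ordinary least squares.

When the projector irradiance is unknown, exposure time (s) stands in for
dosage and E_c becomes a critical exposure *time*; because the model is
shift-invariant in ln-space this changes neither D_p nor the shape of the
curve, only the unit in which E_c is quoted (E_c = I · t_c for irradiance I).

Print resolution is assessed with a radial test pattern of n lines of designed
width h meeting at a circle of measured diameter D:

    p = D tan(π/n) − h / cos(π/n),

the smallest resolvable gap between two lines; p ≤ 0 means the lines merged.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .exceptions import FitError, InputError

__all__ = [
    "WorkingCurve",
    "RadialPattern",
    "fit_working_curve",
    "predict_cure_depth",
    "exposure_for_depth",
    "radial_resolution",
    "implied_line_width",
]


@dataclass(frozen=True)
class WorkingCurve:
    """Fitted light penetration depth and critical exposure.

    ``ec_units`` is "mJ/cm^2" when the irradiance was known (dosage fitting)
    and "s" when exposure was supplied as time only.
    """

    dp: float  # light penetration depth, µm
    ec: float  # critical exposure (gelation point)
    measurements: tuple[tuple[float, float], ...]
    ec_units: str = "s"

    def __post_init__(self) -> None:
        if not (self.dp > 0 and self.ec > 0):
            raise InputError("working curve requires dp > 0 and ec > 0")

    @property
    def intensity_known(self) -> bool:
        return self.ec_units != "s"


def fit_working_curve(
    measurements: Sequence[tuple[float, float]],
    intensity: float | None = None,
) -> WorkingCurve:
    """Least-squares Jacobs fit of (exposure, cure depth µm) pairs.

    With exactly two points the fitted curve passes through both (the
    closed-form two-point solution).  ``intensity`` (mW/cm²), if given,
    converts exposure times to dosages so E_c is reported in mJ/cm².
    """
    pairs = [(float(e), float(d)) for e, d in measurements]
    if len(pairs) < 2:
        raise InputError("need at least 2 (exposure, depth) measurements")
    exposures = np.array([e for e, _ in pairs])
    depths = np.array([d for _, d in pairs])
    if (exposures <= 0).any():
        raise InputError("exposures must be positive")
    if (depths <= 0).any():
        raise InputError("cure depths must be positive (no-gelation points "
                         "cannot anchor the fit)")
    if len(np.unique(exposures)) < 2:
        raise InputError("need at least two distinct exposures")
    if intensity is not None:
        if intensity <= 0:
            raise InputError("intensity must be positive")
        exposures = exposures * intensity
    slope, icept = np.polyfit(np.log(exposures), depths, 1)
    if slope <= 0:
        raise FitError("fitted penetration depth is non-positive; cure depth "
                       "must increase with exposure")
    ec = math.exp(-icept / slope)
    return WorkingCurve(
        dp=float(slope),
        ec=float(ec),
        measurements=tuple(pairs),
        ec_units="s" if intensity is None else "mJ/cm^2",
    )


def predict_cure_depth(curve: WorkingCurve, exposure):
    """Cure depth D_p ln(E/E_c) in µm; values ≤ 0 mean no gelation.

    The signed value is returned (diagnostically useful); CLI-level reporting
    clamps it to zero with a no-cure flag.
    """
    exposure = np.asarray(exposure, dtype=float)
    if (exposure <= 0).any():
        raise InputError("exposure must be positive")
    d = curve.dp * np.log(exposure / curve.ec)
    return float(d) if np.ndim(d) == 0 else d


def exposure_for_depth(curve: WorkingCurve, target_depth):
    """Exposure achieving a target cure depth: E_c · exp(C_d / D_p)."""
    target_depth = np.asarray(target_depth, dtype=float)
    if (target_depth < 0).any():
        raise InputError("target depth must be >= 0")
    e = curve.ec * np.exp(target_depth / curve.dp)
    return float(e) if np.ndim(e) == 0 else e


@dataclass(frozen=True)
class RadialPattern:
    """Radial resolution test pattern: n lines of width h (mm) around a
    central circle of measured diameter d_measured (mm)."""

    n: int
    h: float
    d_measured: float

    def __post_init__(self) -> None:
        if int(self.n) != self.n or self.n < 3:
            raise InputError("n must be an integer >= 3")
        if self.h < 0:
            raise InputError("designed line width must be >= 0")
        if not self.d_measured > 0:
            raise InputError("measured circle diameter must be > 0")


def radial_resolution(pattern: RadialPattern) -> float:
    """p = D tan(π/n) − h/cos(π/n) in mm; p ≤ 0 means unresolved lines."""
    a = math.pi / pattern.n
    return pattern.d_measured * math.tan(a) - pattern.h / math.cos(a)


def implied_line_width(p: float, d: float, n: int) -> float:
    """Invert the resolution formula for the printed line width h (mm)."""
    if int(n) != n or n < 3:
        raise InputError("n must be an integer >= 3")
    if not (math.isfinite(p) and math.isfinite(d)):
        raise InputError("p and d must be finite")
    a = math.pi / n
    return (d * math.tan(a) - p) * math.cos(a)
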