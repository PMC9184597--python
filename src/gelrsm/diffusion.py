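"""Effective diffusivity of solutes in hydrogels from erfc intensity profiles.

A fluorescent tracer placed on top of a gel column at time zero diffuses in
from a constant source.  For a semi-infinite medium, Fick's second law gives
the concentration (and hence normalized fluorescence intensity) profile

    F(x) = erfc( x / (2 sqrt(D_eff t)) ),

with x the axial distance from the opening (cm), t the contact time (s) and
D_eff the effective diffusion coefficient (cm²/s).  Profiles are normalized so
the opening-side intensity is 1 and the far-end intensity is 0, which pins the
proportionality constant of the erfc law to one; an optional two-parameter
mode leaves the amplitude free for un-normalized data.

The single-parameter fit runs in log10(D_eff) with bounds [-12, -2] for
conditioning, started from the value implied by the half-maximum position
(erfc(u) = 1/2 at u ≈ 0.4769).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, special

from .exceptions import FitError, InputError

__all__ = [
    "DiffusionProfile",
    "DiffusivityFit",
    "normalize_profile",
    "predict_profile",
    "fit_effective_diffusivity",
]

_HALF_MAX_U = 0.47693627620446987  # erfcinv(0.5)
_LOG10_BOUNDS = (-12.0, -2.0)


@dataclass(frozen=True)
class DiffusionProfile:
    """Normalized axial intensity profile at a known contact time."""

    x: np.ndarray  # cm, >= 0, strictly increasing
    f: np.ndarray  # dimensionless intensity
    t: float  # s, > 0

    def __post_init__(self) -> None:
        x = np.asarray(self.x, dtype=float)
        f = np.asarray(self.f, dtype=float)
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "f", f)
        if x.ndim != 1 or f.shape != x.shape:
            raise InputError("x and f must be 1-D arrays of equal length")
        if (np.diff(x) <= 0).any():
            raise InputError("positions must be strictly increasing")
        if (x < 0).any():
            raise InputError("positions must be >= 0")
        if not self.t > 0:
            raise InputError("contact time must be positive")

    @property
    def n_points(self) -> int:
        return len(self.x)


def normalize_profile(raw_x, raw_intensity, t: float) -> DiffusionProfile:
    """Affine rescale so the opening-side intensity is 1 and the far end 0."""
    x = np.asarray(raw_x, dtype=float)
    f = np.asarray(raw_intensity, dtype=float)
    if len(x) < 5:
        raise InputError("need at least 5 samples to normalize a profile")
    if f[0] == f[-1]:
        raise InputError("endpoint intensities are equal; normalization is "
                         "degenerate")
    return DiffusionProfile(x=x, f=(f - f[-1]) / (f[0] - f[-1]), t=float(t))


def predict_profile(d_eff: float, t: float, x):
    """erfc(x / (2 sqrt(D_eff t))): 1 at x = 0, monotone decreasing in x."""
    if not d_eff > 0:
        raise InputError("d_eff must be positive")
    if not t > 0:
        raise InputError("t must be positive")
    x = np.asarray(x, dtype=float)
    out = special.erfc(x / (2.0 * np.sqrt(d_eff * t)))
    return float(out) if np.ndim(out) == 0 else out


@dataclass(frozen=True)
class DiffusivityFit:
    d_eff: float  # cm²/s
    se: float  # asymptotic standard error, cm²/s
    n_points: int
    amplitude: float = 1.0  # only ≠ 1 in the amplitude-free mode


def _initial_guess(profile: DiffusionProfile) -> float:
    """D implied by the half-maximum position of the profile."""
    x, f = profile.x, profile.f
    below = np.where(f <= 0.5)[0]
    if len(below) == 0 or below[0] == 0:
        x_half = 0.5 * (x[0] + x[-1])  # no crossing: fall back to mid-grid
    else:
        i = below[0]
        # linear interpolation of the 0.5 crossing
        x0, x1, f0, f1 = x[i - 1], x[i], f[i - 1], f[i]
        x_half = x0 + (0.5 - f0) * (x1 - x0) / (f1 - f0) if f1 != f0 else x1
    if x_half <= 0:
        x_half = x[-1] / 2 if x[-1] > 0 else 1e-3
    return (x_half / (2.0 * _HALF_MAX_U)) ** 2 / profile.t


def fit_effective_diffusivity(
    profile: DiffusionProfile, amplitude_free: bool = False
) -> DiffusivityFit:
    """Nonlinear least-squares estimate of D_eff from a normalized profile.

    D_eff is the single free parameter (amplitude fixed to 1 by the endpoint
    normalization) unless ``amplitude_free`` is set.  Reports the asymptotic
    standard error from the Jacobian at the optimum.
    """
    x, f, t = profile.x, profile.f, profile.t
    informative = x > 0
    if informative.sum() < (2 if amplitude_free else 1) or len(x) < 2:
        raise FitError("profile is underdetermined: no interior positions "
                       "carry information about D_eff")
    theta0 = np.log10(np.clip(_initial_guess(profile), 10.0 ** _LOG10_BOUNDS[0],
                              10.0 ** _LOG10_BOUNDS[1]))

    if amplitude_free:
        p0 = np.array([theta0, 1.0])
        lo = np.array([_LOG10_BOUNDS[0], 0.0])
        hi = np.array([_LOG10_BOUNDS[1], np.inf])

        def resid(p):
            return p[1] * special.erfc(x / (2.0 * np.sqrt(10.0 ** p[0] * t))) - f
    else:
        p0 = np.array([theta0])
        lo, hi = np.array([_LOG10_BOUNDS[0]]), np.array([_LOG10_BOUNDS[1]])

        def resid(p):
            return special.erfc(x / (2.0 * np.sqrt(10.0 ** p[0] * t))) - f

    res = optimize.least_squares(resid, p0, bounds=(lo, hi), method="trf",
                                 xtol=1e-14, ftol=1e-14, gtol=1e-14)
    if not res.success:
        raise FitError(f"diffusivity fit did not converge: {res.message}")
    d_eff = float(10.0 ** res.x[0])
    amplitude = float(res.x[1]) if amplitude_free else 1.0

    # asymptotic SE of D_eff via the delta method on theta = log10(D)
    dof = len(x) - len(res.x)
    sigma2 = float(res.cost * 2.0 / dof) if dof > 0 else 0.0
    J = res.jac
    try:
        cov_theta = sigma2 * np.linalg.inv(J.T @ J)
        se = float(np.sqrt(max(cov_theta[0, 0], 0.0)) * d_eff * np.log(10.0))
    except np.linalg.LinAlgError:
        se = float("nan")
    return DiffusivityFit(d_eff=d_eff, se=se, n_points=len(x),
                          amplitude=amplitude)
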