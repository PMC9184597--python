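"""Reduced-quadratic response-surface models over a boxed design space.

The stiffness of a photocrosslinked GelMA/HAMA construct after enzymatic
(hyaluronidase) digestion is modelled as a second-degree polynomial in four
design factors: GelMA concentration (% w/v), digestion time (h), hyaluronidase
concentration (U/mL) and HAMA concentration (% w/v).  The model exists in two
algebraically equivalent parameterizations:

* **actual** — factors in their physical units; coefficients carry mixed units
  and are not comparable to each other.
* **coded** — each factor linearly rescaled so its low level maps to -1 and
  its high level to +1; coefficient magnitudes are directly comparable and the
  design matrix is well conditioned.

This module holds the model container, pure evaluation, and the exact
polynomial change of variables between the two forms, plus the published
reference model for the GelMA/HAMA system as a pair of named fixtures.

Terms are identified by canonical string keys built from factor names:
``"gelma"`` (linear), ``"time*hama"`` (interaction, factor order of the design
space), ``"hase^2"`` (quadratic).  The model stores coefficients only for the
terms it actually contains — a reduced model never zero-fills excluded terms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

from .exceptions import InputError, ModelIntegrityError

FORM_ACTUAL = "actual"
FORM_CODED = "coded"

__all__ = [
    "Factor",
    "DesignSpace",
    "QuadraticModel",
    "evaluate_model",
    "to_coded",
    "to_actual",
    "refine_reference",
    "reference_space",
    "printed_actual_model",
    "printed_coded_model",
    "reference_model",
    "FORM_ACTUAL",
    "FORM_CODED",
]


@dataclass(frozen=True)
class Factor:
    """One design factor with its coding levels.

    ``low`` and ``high`` are the physical values coded as -1 and +1.
    """

    name: str
    units: str
    low: float
    high: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.low) and math.isfinite(self.high)):
            raise InputError(f"factor {self.name!r}: levels must be finite")
        if not self.high > self.low:
            raise InputError(
                f"factor {self.name!r}: high ({self.high}) must exceed low ({self.low})"
            )

    @property
    def center(self) -> float:
        return 0.5 * (self.low + self.high)

    @property
    def half_range(self) -> float:
        return 0.5 * (self.high - self.low)

    def code(self, x):
        """Physical value -> coded units."""
        return (np.asarray(x, dtype=float) - self.center) / self.half_range

    def decode(self, u):
        """Coded units -> physical value."""
        return np.asarray(u, dtype=float) * self.half_range + self.center


@dataclass(frozen=True)
class DesignSpace:
    """Ordered collection of design factors with unique names."""

    factors: tuple[Factor, ...]

    def __post_init__(self) -> None:
        names = [f.name for f in self.factors]
        if len(set(names)) != len(names):
            raise InputError(f"duplicate factor names: {names}")

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(f.name for f in self.factors)

    def factor(self, name: str) -> Factor:
        for f in self.factors:
            if f.name == name:
                return f
        raise InputError(f"unknown factor {name!r}")

    def center_point(self) -> dict[str, float]:
        return {f.name: f.center for f in self.factors}

    def code_point(self, point: Mapping[str, float]) -> dict[str, float]:
        return {f.name: float(f.code(point[f.name])) for f in self.factors}

    def decode_point(self, point: Mapping[str, float]) -> dict[str, float]:
        return {f.name: float(f.decode(point[f.name])) for f in self.factors}

    def contains(self, point: Mapping[str, float], rtol: float = 1e-9) -> bool:
        for f in self.factors:
            pad = rtol * (f.high - f.low)
            if not (f.low - pad <= point[f.name] <= f.high + pad):
                return False
        return True


def _order_pair(space: DesignSpace, a: str, b: str) -> tuple[str, str]:
    order = {n: i for i, n in enumerate(space.names)}
    if a not in order or b not in order:
        raise InputError(f"interaction ({a},{b}) names unknown factors")
    if a == b:
        raise InputError(f"interaction ({a},{b}) must pair distinct factors")
    return (a, b) if order[a] < order[b] else (b, a)


@dataclass(frozen=True)
class QuadraticModel:
    """Reduced quadratic polynomial Y = a0 + Σ bᵢxᵢ + Σ c_ij xᵢxⱼ + Σ c_ii xᵢ².

    The response is a compressive modulus in kPa regardless of form.  Maps hold
    only the terms present in the model; ``term_set`` lists them canonically.
    """

    form: str
    intercept: float
    linear: dict[str, float]
    interaction: dict[tuple[str, str], float]
    quadratic: dict[str, float]
    space: DesignSpace

    def __post_init__(self) -> None:
        if self.form not in (FORM_ACTUAL, FORM_CODED):
            raise InputError(f"form must be 'actual' or 'coded', got {self.form!r}")
        names = set(self.space.names)
        object.__setattr__(
            self,
            "interaction",
            {_order_pair(self.space, a, b): v for (a, b), v in self.interaction.items()},
        )
        for n in list(self.linear) + list(self.quadratic):
            if n not in names:
                raise InputError(f"term references unknown factor {n!r}")
        coeffs = (
            [self.intercept]
            + list(self.linear.values())
            + list(self.interaction.values())
            + list(self.quadratic.values())
        )
        if not all(math.isfinite(c) for c in coeffs):
            raise ModelIntegrityError("model has a non-finite coefficient")

    @property
    def term_set(self) -> tuple[str, ...]:
        """Canonical term keys in design-space order: linears, interactions, quadratics."""
        order = {n: i for i, n in enumerate(self.space.names)}
        lin = sorted(self.linear, key=order.__getitem__)
        inter = sorted(self.interaction, key=lambda p: (order[p[0]], order[p[1]]))
        quad = sorted(self.quadratic, key=order.__getitem__)
        return tuple(lin) + tuple(f"{a}*{b}" for a, b in inter) + tuple(
            f"{n}^2" for n in quad
        )

    @property
    def n_terms(self) -> int:
        return len(self.linear) + len(self.interaction) + len(self.quadratic)


def evaluate_model(model: QuadraticModel, point: Mapping[str, float]):
    """Evaluate the polynomial at ``point`` (given in the model's own form).

    Values may be scalars or numpy arrays (broadcast together).  Pure and
    deterministic; only terms in the model's term set contribute.
    """
    vals = {}
    for f in model.space.factors:
        if f.name not in point:
            raise InputError(f"point is missing factor {f.name!r}")
        vals[f.name] = np.asarray(point[f.name], dtype=float)
    y = np.asarray(model.intercept, dtype=float)
    for n, b in model.linear.items():
        y = y + b * vals[n]
    for (a, b_), c in model.interaction.items():
        y = y + c * vals[a] * vals[b_]
    for n, c in model.quadratic.items():
        y = y + c * vals[n] ** 2
    return float(y) if np.ndim(y) == 0 else y


def _implied_linear_names(model: QuadraticModel) -> set[str]:
    """Factors that acquire a linear coefficient under an affine substitution."""
    names = set(model.linear) | set(model.quadratic)
    for a, b in model.interaction:
        names.add(a)
        names.add(b)
    return names


def to_coded(model: QuadraticModel) -> QuadraticModel:
    """Exact change of variables from actual units to coded units.

    Substituting x_i = m_i + h_i u_i (m = center, h = half-range) into the
    polynomial gives the coded coefficients in closed form:

    * quadratic: c_ii h_i²
    * interaction: c_ij h_i h_j
    * linear: h_i (b_i + 2 c_ii m_i + Σ_{j≠i} c_ij m_j)
    * intercept: the actual model evaluated at the design center.

    Interactions and quadratics can therefore induce linear terms that the
    actual model did not list explicitly; those appear in the coded term set.
    """
    if model.form != FORM_ACTUAL:
        raise InputError("to_coded expects an actual-form model")
    for f in model.space.factors:
        if f.half_range == 0:
            raise InputError(f"factor {f.name!r} has zero half-range")
    h = {f.name: f.half_range for f in model.space.factors}
    m = {f.name: f.center for f in model.space.factors}

    quadratic = {n: c * h[n] ** 2 for n, c in model.quadratic.items()}
    interaction = {(a, b): c * h[a] * h[b] for (a, b), c in model.interaction.items()}
    linear = {}
    for n in _implied_linear_names(model):
        b = model.linear.get(n, 0.0)
        b += 2.0 * model.quadratic.get(n, 0.0) * m[n]
        for (a, b_), c in model.interaction.items():
            if n == a:
                b += c * m[b_]
            elif n == b_:
                b += c * m[a]
        linear[n] = b * h[n]
    intercept = evaluate_model(model, model.space.center_point())
    return QuadraticModel(
        form=FORM_CODED,
        intercept=intercept,
        linear=linear,
        interaction=interaction,
        quadratic=quadratic,
        space=model.space,
    )


def to_actual(model: QuadraticModel) -> QuadraticModel:
    """Exact inverse of :func:`to_coded` (coded units back to physical units)."""
    if model.form != FORM_CODED:
        raise InputError("to_actual expects a coded-form model")
    for f in model.space.factors:
        if f.half_range == 0:
            raise InputError(f"factor {f.name!r} has zero half-range")
    h = {f.name: f.half_range for f in model.space.factors}
    m = {f.name: f.center for f in model.space.factors}

    quadratic = {n: c / h[n] ** 2 for n, c in model.quadratic.items()}
    interaction = {(a, b): c / (h[a] * h[b]) for (a, b), c in model.interaction.items()}
    linear = {}
    for n in _implied_linear_names(model):
        b = model.linear.get(n, 0.0) / h[n]
        b -= 2.0 * quadratic.get(n, 0.0) * m[n]
        for (a, b_), c in interaction.items():
            if n == a:
                b -= c * m[b_]
            elif n == b_:
                b -= c * m[a]
        linear[n] = b
    # intercept = polynomial value at physical origin = coded model at u(x=0)
    origin_coded = {n: -m[n] / h[n] for n in h}
    intercept = evaluate_model(model, origin_coded)
    return QuadraticModel(
        form=FORM_ACTUAL,
        intercept=intercept,
        linear=linear,
        interaction=interaction,
        quadratic=quadratic,
        space=model.space,
    )


def refine_reference(
    actual: QuadraticModel,
    coded: QuadraticModel,
    terms: Iterable[str] = ("hase",),
) -> QuadraticModel:
    """Repair truncated quadratic coefficients of a printed actual-units model.

    Published actual-units equations are typically printed to four decimals,
    which destroys small quadratic coefficients (the hyaluronidase-squared
    coefficient of the reference model is printed as 0.0001 but recodes to
    26.58 in coded units, i.e. its true value is 26.58/500² ≈ 1.0632e-4).
    This replaces each named quadratic coefficient in ``actual`` by the coded
    model's value divided by the squared half-range; everything else is kept.
    """
    quadratic = dict(actual.quadratic)
    for n in terms:
        if n not in coded.quadratic:
            raise InputError(f"coded model has no quadratic term for {n!r}")
        quadratic[n] = coded.quadratic[n] / actual.space.factor(n).half_range ** 2
    return QuadraticModel(
        form=FORM_ACTUAL,
        intercept=actual.intercept,
        linear=dict(actual.linear),
        interaction=dict(actual.interaction),
        quadratic=quadratic,
        space=actual.space,
    )


# ---------------------------------------------------------------------------
# Reference system: GelMA/HAMA digestion stiffness model
# ---------------------------------------------------------------------------

GELMA, TIME, HASE, HAMA = "gelma", "time", "hase", "hama"

#: Coded letters conventionally used for the four factors.
CODED_LETTERS = {GELMA: "A", TIME: "B", HASE: "C", HAMA: "D"}


def reference_space() -> DesignSpace:
    """The experimental sweep bounds of the GelMA/HAMA digestion study.

    GelMA 2.5-7.5 % w/v, digestion time 0-24 h, hyaluronidase 0-1000 U/mL,
    HAMA 1.5-3.0 % w/v.  These bounds are also the coding levels (-1/+1);
    recoding the published actual-units model over them reproduces the
    published coded coefficients, which is the evidence for this choice.
    """
    return DesignSpace(
        (
            Factor(GELMA, "% w/v", 2.5, 7.5),
            Factor(TIME, "h", 0.0, 24.0),
            Factor(HASE, "U/mL", 0.0, 1000.0),
            Factor(HAMA, "% w/v", 1.5, 3.0),
        )
    )


def printed_actual_model(space: DesignSpace | None = None) -> QuadraticModel:
    """The published actual-units stiffness model, coefficients as printed.

    Note the hase² coefficient is printed truncated (0.0001); use
    :func:`reference_model` for prediction and inverse design.
    """
    space = space or reference_space()
    return QuadraticModel(
        form=FORM_ACTUAL,
        intercept=-113.3016,
        linear={GELMA: 5.8599, TIME: -0.1708, HASE: -0.0173, HAMA: 66.1107},
        interaction={
            (GELMA, TIME): -0.3595,
            (GELMA, HASE): -0.0099,
            (GELMA, HAMA): 6.9941,
            (TIME, HAMA): -2.1007,
            (HASE, HAMA): -0.0458,
        },
        quadratic={TIME: 0.1663, HASE: 0.0001},
        space=space,
    )


def printed_coded_model(space: DesignSpace | None = None) -> QuadraticModel:
    """The published coded-units stiffness model, coefficients as printed."""
    space = space or reference_space()
    return QuadraticModel(
        form=FORM_CODED,
        intercept=28.76,
        linear={GELMA: 30.87, TIME: -32.44, HASE: -31.7, HAMA: 39.73},
        interaction={
            (GELMA, TIME): -10.79,
            (GELMA, HASE): -12.33,
            (GELMA, HAMA): 13.11,
            (TIME, HAMA): -18.91,
            (HASE, HAMA): -17.18,
        },
        quadratic={TIME: 23.95, HASE: 26.58},
        space=space,
    )


def reference_model() -> QuadraticModel:
    """Refined actual-units reference model (default for prediction/design)."""
    return refine_reference(printed_actual_model(), printed_coded_model())
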