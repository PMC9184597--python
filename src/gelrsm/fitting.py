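"""OLS fitting of the reduced-quadratic stiffness model, with diagnostics.

Fits are performed in coded units for numerical conditioning (the
hyaluronidase factor spans 0-1000 U/mL, so actual-units quadratic columns
reach 1e6) and converted back through :mod:`gelrsm.rsm` on request — the two
parameterizations span the same column space, so fitted values, R² and ANOVA
are identical either way.

Diagnostics follow standard design-of-experiments practice:

* R² and adjusted R²;
* *adequate precision*, the signal-to-noise ratio
  (max ŷ − min ŷ) / sqrt(p·σ̂²/n) over the design points, where p counts the
  model parameters (intercept included) and n the design points; values > 4
  indicate the model can navigate the design space;
* per-term partial (Type III) F-tests at α = 0.05;
* 95% prediction intervals ŷ ± t·σ̂·sqrt(1/n_new + x₀ᵀ(XᵀX)⁻¹x₀) for the mean
  of ``n_new`` future observations at x₀.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from . import rsm
from .exceptions import FitError, InputError

__all__ = [
    "DoEDataset",
    "FitDiagnostics",
    "PredictionInterval",
    "FitResult",
    "build_design_matrix",
    "fit_quadratic",
    "adequate_precision",
    "adequate_precision_from_predictions",
    "predict_with_interval",
    "REFERENCE_TERM_SET",
]

FACTOR_COLUMNS = (rsm.GELMA, rsm.TIME, rsm.HASE, rsm.HAMA)
RESPONSE_COLUMN = "modulus"

#: Reduced term set of the reference model: all four linears, five of the six
#: two-way interactions (no time*hase), and quadratics in time and hase.
REFERENCE_TERM_SET = (
    "gelma",
    "time",
    "hase",
    "hama",
    "gelma*time",
    "gelma*hase",
    "gelma*hama",
    "time*hama",
    "hase*hama",
    "time^2",
    "hase^2",
)


def full_quadratic_term_set(space: rsm.DesignSpace) -> tuple[str, ...]:
    """All linear, two-way interaction and quadratic terms of a space."""
    names = space.names
    lin = list(names)
    inter = [f"{a}*{b}" for i, a in enumerate(names) for b in names[i + 1 :]]
    quad = [f"{n}^2" for n in names]
    return tuple(lin + inter + quad)


@dataclass(frozen=True)
class DoEDataset:
    """Factor settings with measured compressive moduli (replicates allowed).

    ``frame`` columns: gelma, time, hase, hama, modulus (all actual units),
    plus an optional ``replicate`` id column.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in (*FACTOR_COLUMNS, RESPONSE_COLUMN) if c not in self.frame]
        if missing:
            raise InputError(f"dataset is missing columns: {missing}")
        sub = self.frame[list(FACTOR_COLUMNS) + [RESPONSE_COLUMN]].to_numpy(dtype=float)
        if not np.isfinite(sub).all():
            bad = int(np.argwhere(~np.isfinite(sub))[0][0])
            raise InputError(f"non-finite value in dataset at row {bad}")
        if (sub < 0).any():
            bad = int(np.argwhere((sub < 0).any(axis=1))[0][0])
            raise InputError(f"negative factor or modulus value at row {bad}")

    @property
    def n_rows(self) -> int:
        return len(self.frame)

    def factor_values(self, name: str) -> np.ndarray:
        return self.frame[name].to_numpy(dtype=float)

    @property
    def modulus(self) -> np.ndarray:
        return self.frame[RESPONSE_COLUMN].to_numpy(dtype=float)


@dataclass(frozen=True)
class FitDiagnostics:
    r2: float
    adj_r2: float
    adequate_precision: float
    residual_sd: float
    dof: int
    anova: pd.DataFrame  # columns: term, coef, se, F, p, significant

    def __post_init__(self) -> None:
        if self.adj_r2 > self.r2 + 1e-12:
            raise FitError("adjusted R² exceeds R²")


@dataclass(frozen=True)
class PredictionInterval:
    point: float
    lower: float
    upper: float
    level: float = 0.95

    def __post_init__(self) -> None:
        if not (self.lower <= self.point <= self.upper):
            raise InputError("prediction interval must bracket the point estimate")

    @property
    def width(self) -> float:
        return self.upper - self.lower

    def contains(self, value: float, atol: float = 1e-9) -> bool:
        return self.lower - atol <= value <= self.upper + atol


def _term_column(term: str, vals: dict[str, np.ndarray]) -> np.ndarray:
    if term.endswith("^2"):
        return vals[term[:-2]] ** 2
    if "*" in term:
        a, b = term.split("*")
        return vals[a] * vals[b]
    return vals[term]


def build_design_matrix(
    data: DoEDataset,
    term_set=REFERENCE_TERM_SET,
    space: rsm.DesignSpace | None = None,
    form: str = rsm.FORM_CODED,
):
    """Regressor matrix (intercept column first, then term_set order) and response.

    Returns ``(X, y, columns)``.  In coded form the coding transform is applied
    to the factor columns before terms are formed.
    """
    space = space or rsm.reference_space()
    if form not in (rsm.FORM_ACTUAL, rsm.FORM_CODED):
        raise InputError(f"unknown form {form!r}")
    if data.n_rows == 0:
        raise InputError("dataset is empty")
    vals = {}
    for f in space.factors:
        x = data.factor_values(f.name)
        vals[f.name] = f.code(x) if form == rsm.FORM_CODED else x
    cols = [np.ones(data.n_rows)] + [_term_column(t, vals) for t in term_set]
    X = np.column_stack(cols)
    return X, data.modulus, ["intercept", *term_set]


def _model_from_params(params, term_set, space, form) -> rsm.QuadraticModel:
    linear, interaction, quadratic = {}, {}, {}
    for t, b in zip(term_set, params[1:]):
        if t.endswith("^2"):
            quadratic[t[:-2]] = float(b)
        elif "*" in t:
            a, c = t.split("*")
            interaction[(a, c)] = float(b)
        else:
            linear[t] = float(b)
    return rsm.QuadraticModel(
        form=form,
        intercept=float(params[0]),
        linear=linear,
        interaction=interaction,
        quadratic=quadratic,
        space=space,
    )


@dataclass(frozen=True)
class FitResult:
    """Fitted model plus the regression context needed for intervals."""

    model: rsm.QuadraticModel  # in the requested form
    coded_model: rsm.QuadraticModel
    diagnostics: FitDiagnostics
    space: rsm.DesignSpace
    term_set: tuple[str, ...]
    sigma: float  # residual SD, kPa
    dof: int
    n_rows: int
    xtx_inv: np.ndarray  # (XᵀX)⁻¹ of the coded design matrix
    fitted: np.ndarray  # ŷ at the design points

    def coded_row(self, point_actual) -> np.ndarray:
        """Coded regressor row for a point given in actual units."""
        coded = self.space.code_point(point_actual)
        vals = {k: np.asarray(v, dtype=float) for k, v in coded.items()}
        return np.array([1.0] + [float(_term_column(t, vals)) for t in self.term_set])


def fit_quadratic(
    data: DoEDataset,
    term_set=REFERENCE_TERM_SET,
    space: rsm.DesignSpace | None = None,
    form: str = rsm.FORM_CODED,
    alpha: float = 0.05,
    ap_n_mode: str = "rows",
) -> FitResult:
    """Ordinary least squares fit of the reduced quadratic model.

    The regression itself runs in coded units; ``form`` selects the
    parameterization of the returned model.  Raises :class:`FitError` on a
    rank-deficient design matrix (naming the collinear columns) or a constant
    response.
    """
    space = space or rsm.reference_space()
    term_set = tuple(term_set)
    n_params = len(term_set) + 1
    if data.n_rows < n_params + 1:
        raise InputError(
            f"need at least {n_params + 1} rows to fit {n_params} parameters, "
            f"got {data.n_rows}"
        )
    X, y, columns = build_design_matrix(data, term_set, space, rsm.FORM_CODED)
    if np.var(y) == 0:
        raise FitError("response has zero variance; nothing to fit")
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # flag columns with (numerically) zero R diagonal in a pivoted QR
        _, R = np.linalg.qr(X)
        diag = np.abs(np.diag(R))
        bad = [columns[i] for i in np.where(diag < 1e-8 * diag.max())[0]]
        raise FitError(f"design matrix is rank deficient; collinear terms: {bad}")

    res = sm.OLS(y, X).fit()
    dof = int(res.df_resid)
    sigma = float(np.sqrt(res.mse_resid))
    fitted = np.asarray(res.fittedvalues)

    # partial (Type III) F test per single-df term: F = t²
    fvals = res.tvalues**2
    anova = pd.DataFrame(
        {
            "term": columns,
            "coef": res.params,
            "se": res.bse,
            "F": fvals,
            "p": res.pvalues,
            "significant": res.pvalues < alpha,
        }
    )

    try:
        ap = adequate_precision_from_predictions(
            fitted, n_params=n_params, sigma2=sigma**2,
            n=_ap_n(data, ap_n_mode),
        )
    except FitError:
        ap = float("inf")  # σ̂ = 0 (noiseless data): infinite signal-to-noise

    diagnostics = FitDiagnostics(
        r2=float(res.rsquared),
        adj_r2=float(res.rsquared_adj),
        adequate_precision=ap,
        residual_sd=sigma,
        dof=dof,
        anova=anova,
    )
    coded_model = _model_from_params(res.params, term_set, space, rsm.FORM_CODED)
    model = coded_model if form == rsm.FORM_CODED else rsm.to_actual(coded_model)
    return FitResult(
        model=model,
        coded_model=coded_model,
        diagnostics=diagnostics,
        space=space,
        term_set=term_set,
        sigma=sigma,
        dof=dof,
        n_rows=data.n_rows,
        xtx_inv=np.linalg.inv(X.T @ X),
        fitted=fitted,
    )


def _ap_n(data: DoEDataset, n_mode: str) -> int:
    if n_mode == "rows":
        return data.n_rows
    if n_mode == "distinct":
        return len(data.frame[list(FACTOR_COLUMNS)].drop_duplicates())
    raise InputError(f"ap_n_mode must be 'rows' or 'distinct', got {n_mode!r}")


def adequate_precision_from_predictions(
    yhat: np.ndarray, n_params: int, sigma2: float, n: int | None = None
) -> float:
    """(max ŷ − min ŷ) / sqrt(p·σ̂²/n) — signal-to-noise over the design points."""
    yhat = np.asarray(yhat, dtype=float)
    if sigma2 <= 0:
        raise FitError("residual variance is zero; adequate precision is infinite")
    n = len(yhat) if n is None else n
    return float((yhat.max() - yhat.min()) / np.sqrt(n_params * sigma2 / n))


def adequate_precision(fit: FitResult, data: DoEDataset | None = None,
                       n_mode: str = "rows") -> float:
    """Adequate precision of a fit; ``n_mode`` chooses n = rows or distinct points."""
    n = fit.n_rows if data is None else _ap_n(data, n_mode)
    if n_mode == "distinct" and data is None:
        raise InputError("n_mode='distinct' requires the dataset")
    return adequate_precision_from_predictions(
        fit.fitted, n_params=len(fit.term_set) + 1, sigma2=fit.sigma**2, n=n
    )


def predict_with_interval(
    fit: FitResult,
    point: dict[str, float],
    level: float = 0.95,
    n_new: int = 1,
) -> PredictionInterval:
    """Prediction interval for the mean of ``n_new`` future observations.

    ``point`` is given in actual units.  A point outside the design space is
    allowed but triggers a warning (the quadratic is an interpolating
    surrogate).
    """
    if fit.dof <= 0:
        raise InputError("no residual degrees of freedom for an interval")
    if not 0 < level < 1:
        raise InputError("level must be in (0, 1)")
    if n_new < 1:
        raise InputError("n_new must be >= 1")
    if not fit.space.contains(point):
        warnings.warn("prediction point lies outside the design space", stacklevel=2)
    x0 = fit.coded_row(point)
    yhat = float(rsm.evaluate_model(fit.coded_model, fit.space.code_point(point)))
    se = fit.sigma * float(np.sqrt(1.0 / n_new + x0 @ fit.xtx_inv @ x0))
    half = float(stats.t.ppf(0.5 + level / 2.0, fit.dof)) * se
    return PredictionInterval(point=yhat, lower=yhat - half, upper=yhat + half,
                              level=level)
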