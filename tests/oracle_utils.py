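"""Independent oracles used by the test suite.

Everything here is deliberately implemented without the package's own
algorithms: brute-force normal equations, exact quadratic-over-box optimization
by face enumeration, sympy symbolic change of variables, and term-by-term
polynomial evaluation.
"""

from __future__ import annotations

import itertools

import numpy as np


def ols_normal_equations(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Brute-force OLS solve of (XᵀX)β = Xᵀy."""
    return np.linalg.solve(X.T @ X, X.T @ y)


def eval_terms_brute(model, point) -> float:
    """Term-by-term polynomial sum, independent of evaluate_model's loop."""
    total = model.intercept
    contributions = []
    for name, coef in model.linear.items():
        contributions.append(coef * point[name])
    for (a, b), coef in model.interaction.items():
        contributions.append(coef * point[a] * point[b])
    for name, coef in model.quadratic.items():
        contributions.append(coef * point[name] ** 2)
    return total + sum(sorted(contributions, key=abs))


def quad_box_extrema(model, space):
    """Exact (min, max) of a quadratic over a box by face enumeration.

    Every face of the box fixes a subset of coordinates at bounds; on each
    face the stationary point of the restricted quadratic is found by solving
    a linear system, kept if it lies inside the face.  Corners are the
    zero-dimensional faces.  Exact up to linear-algebra roundoff.
    """
    names = list(space.names)
    idx = {n: i for i, n in enumerate(names)}
    k = len(names)
    b = np.zeros(k)
    C = np.zeros((k, k))
    for n, v in model.linear.items():
        b[idx[n]] = v
    for n, v in model.quadratic.items():
        C[idx[n], idx[n]] = v
    for (p, q), v in model.interaction.items():
        C[idx[p], idx[q]] += 0.5 * v
        C[idx[q], idx[p]] += 0.5 * v
    lows = np.array([f.low for f in space.factors])
    highs = np.array([f.high for f in space.factors])

    def f(x):
        return model.intercept + b @ x + x @ C @ x

    candidates = []
    for assignment in itertools.product((0, 1, 2), repeat=k):
        fixed = {i: lows[i] if a == 0 else highs[i]
                 for i, a in enumerate(assignment) if a != 2}
        free = [i for i, a in enumerate(assignment) if a == 2]
        x = np.empty(k)
        for i, v in fixed.items():
            x[i] = v
        if not free:
            candidates.append(x.copy())
            continue
        # stationary point: 2 C_FF x_F = -(b_F + 2 C_Ff x_f)
        F = np.array(free)
        A = 2.0 * C[np.ix_(F, F)]
        rhs = -(b[F] + 2.0 * C[np.ix_(F, [i for i in fixed])] @
                np.array([fixed[i] for i in fixed])) if fixed else -b[F]
        try:
            xf = np.linalg.solve(A, rhs)
        except np.linalg.LinAlgError:
            continue
        x[F] = xf
        if ((x >= lows - 1e-9) & (x <= highs + 1e-9)).all():
            candidates.append(np.clip(x, lows, highs))
    vals = [f(x) for x in candidates]
    return float(min(vals)), float(max(vals))


def sympy_recode(model):
    """Symbolic actual→coded change of variables; returns coefficient dicts."""
    import sympy as sp

    names = list(model.space.names)
    x = {n: sp.Symbol(n) for n in names}
    u = {n: sp.Symbol("u_" + n) for n in names}
    expr = sp.Float(model.intercept, 30)
    for n, c in model.linear.items():
        expr += sp.Float(c, 30) * x[n]
    for (a, b), c in model.interaction.items():
        expr += sp.Float(c, 30) * x[a] * x[b]
    for n, c in model.quadratic.items():
        expr += sp.Float(c, 30) * x[n] ** 2
    subs = {
        x[f.name]: f.center + f.half_range * u[f.name]
        for f in model.space.factors
    }
    poly = sp.Poly(sp.expand(expr.subs(subs)), *[u[n] for n in names])
    out = {"intercept": float(poly.coeff_monomial(1)), "linear": {},
           "interaction": {}, "quadratic": {}}
    for n in names:
        out["linear"][n] = float(poly.coeff_monomial(u[n]))
        out["quadratic"][n] = float(poly.coeff_monomial(u[n] ** 2))
    for i, a in enumerate(names):
        for bn in names[i + 1:]:
            out["interaction"][(a, bn)] = float(poly.coeff_monomial(u[a] * u[bn]))
    return out


def sympy_decode(model):
    """Symbolic coded→actual change of variables."""
    import sympy as sp

    names = list(model.space.names)
    x = {n: sp.Symbol(n) for n in names}
    u = {n: sp.Symbol("u_" + n) for n in names}
    expr = sp.Float(model.intercept, 30)
    for n, c in model.linear.items():
        expr += sp.Float(c, 30) * u[n]
    for (a, b), c in model.interaction.items():
        expr += sp.Float(c, 30) * u[a] * u[b]
    for n, c in model.quadratic.items():
        expr += sp.Float(c, 30) * u[n] ** 2
    subs = {
        u[f.name]: (x[f.name] - f.center) / f.half_range
        for f in model.space.factors
    }
    poly = sp.Poly(sp.expand(expr.subs(subs)), *[x[n] for n in names])
    out = {"intercept": float(poly.coeff_monomial(1)), "linear": {},
           "interaction": {}, "quadratic": {}}
    for n in names:
        out["linear"][n] = float(poly.coeff_monomial(x[n]))
        out["quadratic"][n] = float(poly.coeff_monomial(x[n] ** 2))
    for i, a in enumerate(names):
        for bn in names[i + 1:]:
            out["interaction"][(a, bn)] = float(poly.coeff_monomial(x[a] * x[bn]))
    return out
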