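"""Limiting ooid size from the stationarity condition of the growth model.

At the limiting size the outer-layer growth exactly balances the inner-zone
losses.  With the outer layer approximated as a thin shell of constant width
``w`` (volume ~ 4*pi*R^2*w) and the inner zone as the full sphere
(volume ~ (4/3)*pi*R^3), stationarity of the total volume reads

    -A*R^3 + B*R^2 + C = 0,
    A = (4*pi/3)*|k_b_I - k_m/c|,  B = 4*pi*k_b_II*w,  C = |k_b_I - k_m/c|*V_m,

which, having exactly one sign change in its coefficients, has exactly one
positive root (Descartes' rule of signs).  The root grows with the mineral
volume ``V_m`` already accreted and linearly with the layer width ``w``.

The width itself comes from a steady diffusion-consumption balance across the
active layer: nutrients at background concentration ``c_II`` diffuse in from
the surrounding medium and are consumed at constant volumetric rate ``k``;
the layer extends down to where the concentration falls to the survival
threshold ``c_I``.  In the thin-shell (planar) limit

    w = sqrt(2*(c_II - c_I)*D/k),

and :func:`shell_width_exact` solves the full spherical problem, to which the
planar formula is the leading-order approximation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

from .errors import ParameterError
from .model_core import ModelParams, NutrientParams

__all__ = [
    "LimitingSizeResult",
    "RadiusBounds",
    "ShellWidthResult",
    "outer_width",
    "cubic_coefficients",
    "limiting_radius",
    "radius_bounds",
    "sensitivity_exponents",
    "shell_width_exact",
]


@dataclass(frozen=True)
class RadiusBounds:
    """Analytic bounds on the limiting radius; ``upper`` is None when the
    finite-upper-bound regime (c*k_b_I - k_m - c*k_b_II > 0) does not hold."""

    lower: float
    upper: float | None

    @property
    def unbounded_upper(self) -> bool:
        return self.upper is None


@dataclass(frozen=True)
class LimitingSizeResult:
    """Unique positive root of the stationarity cubic plus diagnostics."""

    R: float
    lower: float
    upper: float | None
    w: float
    A: float
    B: float
    C: float

    @property
    def unbounded_upper(self) -> bool:
        return self.upper is None

    def to_dict(self) -> dict:
        return {
            "R": self.R,
            "lower": self.lower,
            "upper": self.upper,
            "unbounded_upper": self.unbounded_upper,
            "w": self.w,
            "A": self.A,
            "B": self.B,
            "C": self.C,
        }


def outer_width(nutrients: NutrientParams) -> float:
    """Thin-shell active-layer width ``sqrt(2*(c_II - c_I)*D/k)``."""
    return math.sqrt(2.0 * (nutrients.c_II - nutrients.c_I) * nutrients.D / nutrients.k)


def _check_regime(params: ModelParams) -> float:
    diff = params.k_b_I - params.k_m / params.c
    if diff <= 0:
        raise ParameterError(
            "no finite limiting size: requires c*k_b_I > k_m (inner-zone losses "
            f"must outpace mineral gain), got c*k_b_I - k_m = {params.c * diff}"
        )
    return diff


def cubic_coefficients(
    params: ModelParams, w: float, V_m: float = 0.0
) -> tuple[float, float, float]:
    """Coefficients (A, B, C) of the stationarity cubic -A*R^3 + B*R^2 + C."""
    diff = _check_regime(params)
    A = (4.0 * math.pi / 3.0) * diff
    B = 4.0 * math.pi * params.k_b_II * w
    C = diff * V_m
    return A, B, C


def limiting_radius(params: ModelParams, w: float, V_m: float = 0.0) -> LimitingSizeResult:
    """Unique positive root of the limiting-size cubic.

    For ``V_m = 0`` the cubic degenerates to a quadratic and the root is
    exactly ``B/A = 3*c*k_b_II*w/(c*k_b_I - k_m)`` (the lower bound, attained).
    Otherwise the root is bracketed on (0, B/A + (C/A)^(1/3) + 1] — the cubic
    is positive at 0 (value C) and provably negative at the bracket end — and
    solved by Brent's method, then polished with Newton steps.  The residual
    is verified to be <= 1e-10 relative to the largest cubic term.
    """
    if w <= 0:
        raise ParameterError(f"layer width w must be > 0, got {w}")
    if V_m < 0:
        raise ParameterError(f"mineral volume V_m must be >= 0, got {V_m}")
    A, B, C = cubic_coefficients(params, w, V_m)

    def f(r: float) -> float:
        return -A * r**3 + B * r**2 + C

    if C == 0.0:
        root = B / A
    else:
        hi = B / A + (C / A) ** (1.0 / 3.0) + 1.0
        root = brentq(f, 0.0, hi, xtol=1e-300, rtol=4 * np.finfo(float).eps)
        for _ in range(3):  # Newton polish to machine precision
            df = -3 * A * root**2 + 2 * B * root
            if df == 0:
                break
            step = f(root) / df
            root -= step
            if abs(step) <= 1e-16 * root:
                break
    scale = max(A * root**3, B * root**2, C)
    if scale > 0 and abs(f(root)) > 1e-10 * scale:
        raise ParameterError(
            f"cubic root residual {f(root):.3e} exceeds tolerance at R = {root}"
        )
    bounds = radius_bounds(params, w)
    return LimitingSizeResult(
        R=root, lower=bounds.lower, upper=bounds.upper, w=w, A=A, B=B, C=C
    )


def radius_bounds(params: ModelParams, w: float) -> RadiusBounds:
    """Analytic bounds on the limiting radius, both linear in ``w``.

    lower = 3*c*k_b_II*w / (c*k_b_I - k_m)  (the V_m = 0 radius, attained as
    an infimum), and

    upper = w*(c*k_b_I - k_m) / (c*k_b_I - k_m - c*k_b_II)

    whenever the denominator is positive; otherwise the limiting radius is
    unbounded in V_m and ``upper`` is None.  The upper bound follows from the
    geometric constraint V_m < (4/3)*pi*(R - w)^3: substituting the boundary
    mineral volume into the stationarity condition and solving for R.
    """
    if w < 0:
        raise ParameterError(f"layer width w must be >= 0, got {w}")
    _check_regime(params)
    num = params.c * params.k_b_I - params.k_m
    lower = 3.0 * params.c * params.k_b_II * w / num
    denom = num - params.c * params.k_b_II
    upper = w * num / denom if denom > 0 else None
    return RadiusBounds(lower=lower, upper=upper)


def sensitivity_exponents(
    params: ModelParams,
    nutrients: NutrientParams,
    decades: float = 2.0,
    n_points: int = 21,
) -> tuple[float, float]:
    """Log-log sensitivity of the V_m = 0 limiting radius to D and to k.

    Sweeps each nutrient constant over ``decades`` decades (geometric grid
    about its current value, other constants fixed), computes the limiting
    radius through the full width-plus-cubic pipeline, and returns the
    least-squares slopes of log R against log D and log k.  Because R is
    proportional to w and w = sqrt(2*(c_II - c_I)*D/k), the slopes are +1/2
    and -1/2.
    """
    factors = np.logspace(-decades / 2.0, decades / 2.0, n_points)

    def radius_for(nut: NutrientParams) -> float:
        return limiting_radius(params, outer_width(nut), 0.0).R

    logs_D = [
        math.log(radius_for(NutrientParams(nutrients.c_I, nutrients.c_II,
                                           nutrients.D * f, nutrients.k)))
        for f in factors
    ]
    logs_k = [
        math.log(radius_for(NutrientParams(nutrients.c_I, nutrients.c_II,
                                           nutrients.D, nutrients.k * f)))
        for f in factors
    ]
    x = np.log(factors)
    slope_D = float(np.polyfit(x, logs_D, 1)[0])
    slope_k = float(np.polyfit(x, logs_k, 1)[0])
    return slope_D, slope_k


@dataclass(frozen=True)
class ShellWidthResult:
    """Active-layer width from the spherical diffusion-consumption balance.

    ``full_penetration`` is True when nutrients reach the centre above the
    survival threshold, i.e. no starved inner zone exists yet (the initial
    growth stage); then ``width`` equals the full radius.
    """

    width: float
    inner_radius: float
    full_penetration: bool


def shell_width_exact(nutrients: NutrientParams, R: float) -> ShellWidthResult:
    """Active-layer width of a sphere of radius ``R``, exactly.

    Solves the steady spherically symmetric diffusion-consumption problem
    D*(1/r^2)(r^2 c')' = k on [R_i, R] with c(R) = c_II and a free inner
    interface R_i where c(R_i) = c_I and c'(R_i) = 0 (zero flux into the
    starved core).  The general solution c(r) = k r^2/(6D) + a/r + b reduces
    the interface condition to the scalar equation

        (k/(6D)) * (R^2 + 2*R_i^3/R - 3*R_i^2) = c_II - c_I,

    whose left side decreases monotonically from k*R^2/(6D) at R_i = 0 to 0
    at R_i = R; it is solved with Brent's method.  If even R_i = 0 leaves the
    centre above threshold (k*R^2/(6D) <= c_II - c_I) the layer fills the
    whole sphere and full penetration is reported.  As width/R -> 0 the width
    approaches the planar value sqrt(2*(c_II - c_I)*D/k).
    """
    if R <= 0:
        raise ParameterError(f"outer radius R must be > 0, got {R}")
    excess = nutrients.c_II - nutrients.c_I
    if excess == 0.0:
        return ShellWidthResult(width=0.0, inner_radius=R, full_penetration=False)
    pref = nutrients.k / (6.0 * nutrients.D)

    def g(r_i: float) -> float:
        return pref * (R**2 + 2.0 * r_i**3 / R - 3.0 * r_i**2) - excess

    if g(0.0) <= 0.0:
        return ShellWidthResult(width=R, inner_radius=0.0, full_penetration=True)
    r_i = brentq(g, 0.0, R, xtol=1e-300, rtol=4 * np.finfo(float).eps)
    return ShellWidthResult(width=R - r_i, inner_radius=r_i, full_penetration=False)


def shell_width_shooting(
    nutrients: NutrientParams, R: float, rtol: float = 1e-12
) -> ShellWidthResult:
    """Independent route to :func:`shell_width_exact` by ODE shooting.

    Integrates the radial diffusion-consumption ODE outward from a candidate
    inner interface (c = c_I, zero flux) and adjusts the interface until the
    concentration at the outer radius matches c_II.  Kept as a cross-check:
    it shares no algebra with the closed-form reduction.
    """
    if R <= 0:
        raise ParameterError(f"outer radius R must be > 0, got {R}")
    excess = nutrients.c_II - nutrients.c_I
    if excess == 0.0:
        return ShellWidthResult(width=0.0, inner_radius=R, full_penetration=False)
    D, k = nutrients.D, nutrients.k

    def c_at_outer(r_i: float) -> float:
        # y = [c, c']; c'' = k/D - 2 c'/r ; start just off r_i to avoid 1/r issues
        def rhs(r, y):
            return [y[1], k / D - 2.0 * y[1] / r]

        start = max(r_i, 1e-12 * R)
        sol = solve_ivp(rhs, (start, R), [nutrients.c_I, 0.0],
                        method="DOP853", rtol=rtol, atol=1e-14 * excess)
        return sol.y[0, -1]

    if c_at_outer(0.0) - nutrients.c_II <= 0.0:
        return ShellWidthResult(width=R, inner_radius=0.0, full_penetration=True)
    r_i = brentq(lambda r: c_at_outer(r) - nutrients.c_II, 0.0, R * (1 - 1e-12),
                 xtol=1e-14 * R)
    return ShellWidthResult(width=R - r_i, inner_radius=r_i, full_penetration=False)
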