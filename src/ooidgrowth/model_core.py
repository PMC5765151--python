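"""Core three-compartment model of nutrient-limited ooid growth.

The ooid is modelled as a radially symmetric biofilm with two biotic
compartments and one mineral compartment:

* ``V_m``    — mineralised volume in the nutrient-starved inner zone,
* ``V_b_I``  — biotic volume in the inner zone (decaying, being mineralised),
* ``V_b_II`` — biotic volume in the nutrient-supplied outer layer (growing).

The dynamics are linear ODEs::

    dV_m/dt    =  k_m * V_b_I
    dV_b_I/dt  = -k_b_I * V_b_I + k_b * V_b_II
    dV_b_II/dt =  (k_b_II - k_b) * V_b_II

where ``k_b`` is the rate at which outer-layer microbes transition into the
inner zone.  The total ooid volume is ``V = V_m + c*(V_b_I + V_b_II)`` with
``c`` the biofilm-to-microbe volume scale factor.

With no replenishment of the inner zone (``k_b = 0``) the mineralisation
front admits the closed form

    R_m(t) = ( (k_m R^3 / (k_b_I c)) * (1 - exp(-k_b_I (t - tau))) )^(1/3)

for ``t >= tau`` (onset of mineralisation at radius ``R``).  In the canonical
dimensionless units used throughout (k_b_I = 1, k_m R^3/(k_b_I c) = 1, time
scaled so onset is at t = 1) this becomes

    R_m(t) = (1 + alpha*(t - 1) - exp(-(t - 1)))^(1/3),   t >= 1,

where the replenishment parameter ``alpha >= 0`` accounts for a constant
resupply of inner-zone microbes from the outer layer; ``alpha = 0`` is the
non-replenished law.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterator, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .errors import DomainError, NumericalError, ParameterError

__all__ = [
    "ModelParams",
    "NutrientParams",
    "BiofilmState",
    "Trajectory",
    "integrate_model",
    "total_volume",
    "volume_rate",
    "mineral_front_radius",
    "mineral_front_radius_dimensional",
    "replenishment_alpha",
    "mineralisation_ode_alternative",
]

#: Default solver tolerances: the system is linear and non-stiff, but tight
#: tolerances keep comparisons against the closed forms meaningful.
DEFAULT_RTOL = 1e-10
DEFAULT_ATOL = 1e-12


def _require_finite(name: str, value: float) -> float:
    value = float(value)
    if not math.isfinite(value):
        raise ParameterError(f"{name} must be finite, got {value!r}")
    return value


@dataclass(frozen=True)
class ModelParams:
    """Kinetic and volumetric constants of the compartment model.

    Parameters
    ----------
    k_m : float
        Mineralisation rate constant: conversion of inner-zone biotic volume
        to mineral, per unit time.
    k_b : float
        Rate at which outer-layer microbes transition into the inner zone,
        per unit time.
    k_b_I : float
        Decay rate of inner-zone microbes, per unit time.
    k_b_II : float
        Growth rate of outer-layer microbes, per unit time.
    c : float
        Dimensionless scale factor relating biofilm volume to the volume of
        microbes it contains.
    """

    k_m: float
    k_b: float
    k_b_I: float
    k_b_II: float
    c: float

    def __post_init__(self) -> None:
        for name in ("k_m", "k_b", "k_b_I", "k_b_II"):
            v = _require_finite(name, getattr(self, name))
            if v < 0:
                raise ParameterError(f"rate constant {name} must be >= 0, got {v}")
            object.__setattr__(self, name, v)
        c = _require_finite("c", self.c)
        if c <= 0:
            raise ParameterError(f"scale factor c must be > 0, got {c}")
        object.__setattr__(self, "c", c)

    @property
    def limiting_size_regime(self) -> bool:
        """True iff c*k_b_I - k_m > 0, i.e. the stationarity cubic has A > 0."""
        return self.c * self.k_b_I - self.k_m > 0

    @property
    def finite_upper_bound_regime(self) -> bool:
        """True iff c*k_b_I - k_m - c*k_b_II > 0 so the upper bound is finite."""
        return self.c * self.k_b_I - self.k_m - self.c * self.k_b_II > 0


@dataclass(frozen=True)
class NutrientParams:
    """Nutrient field constants entering the outer-layer width.

    ``c_I`` is the threshold concentration microbes need to survive, ``c_II``
    the background concentration in the surrounding medium, ``D`` the nutrient
    diffusivity (length^2/time) and ``k`` the volumetric consumption rate
    (concentration/time).
    """

    c_I: float
    c_II: float
    D: float
    k: float

    def __post_init__(self) -> None:
        c_I = _require_finite("c_I", self.c_I)
        c_II = _require_finite("c_II", self.c_II)
        if c_I < 0:
            raise ParameterError(f"c_I must be >= 0, got {c_I}")
        if c_II < c_I:
            raise ParameterError(
                f"background concentration c_II ({c_II}) must be >= threshold c_I ({c_I})"
            )
        D = _require_finite("D", self.D)
        k = _require_finite("k", self.k)
        if D <= 0:
            raise ParameterError(f"diffusivity D must be > 0, got {D}")
        if k <= 0:
            raise ParameterError(f"consumption rate k must be > 0, got {k}")
        object.__setattr__(self, "c_I", c_I)
        object.__setattr__(self, "c_II", c_II)
        object.__setattr__(self, "D", D)
        object.__setattr__(self, "k", k)


@dataclass(frozen=True)
class BiofilmState:
    """Compartment volumes at a single time point."""

    t: float
    V_m: float
    V_b_I: float
    V_b_II: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "t", _require_finite("t", self.t))
        for name in ("V_m", "V_b_I", "V_b_II"):
            v = _require_finite(name, getattr(self, name))
            if v < 0:
                raise ParameterError(f"volume {name} must be >= 0, got {v}")
            object.__setattr__(self, name, v)


@dataclass
class Trajectory:
    """Time course of the compartment volumes plus integration metadata.

    Times are strictly increasing and ``V_m`` is non-decreasing (its rate
    ``k_m * V_b_I`` is never negative).
    """

    t: np.ndarray
    V_m: np.ndarray
    V_b_I: np.ndarray
    V_b_II: np.ndarray
    params: ModelParams
    rtol: float = DEFAULT_RTOL
    atol: float = DEFAULT_ATOL
    tau: float = 0.0  # onset time of mineralisation, metadata only

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.V_m = np.asarray(self.V_m, dtype=float)
        self.V_b_I = np.asarray(self.V_b_I, dtype=float)
        self.V_b_II = np.asarray(self.V_b_II, dtype=float)
        n = self.t.size
        if not (self.V_m.size == self.V_b_I.size == self.V_b_II.size == n):
            raise ParameterError("trajectory arrays must share one length")
        if n >= 2 and not np.all(np.diff(self.t) > 0):
            raise ParameterError("trajectory times must be strictly increasing")
        if n >= 2 and np.any(np.diff(self.V_m) < -10 * self.atol):
            raise NumericalError("V_m decreased along the trajectory")

    def __len__(self) -> int:
        return int(self.t.size)

    def state(self, i: int) -> BiofilmState:
        return BiofilmState(
            t=float(self.t[i]),
            V_m=float(max(self.V_m[i], 0.0)),
            V_b_I=float(max(self.V_b_I[i], 0.0)),
            V_b_II=float(max(self.V_b_II[i], 0.0)),
        )

    def states(self) -> Iterator[BiofilmState]:
        for i in range(len(self)):
            yield self.state(i)

    @property
    def V_total(self) -> np.ndarray:
        c = self.params.c
        return self.V_m + c * (self.V_b_I + self.V_b_II)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "t": self.t,
                "V_m": self.V_m,
                "V_b_I": self.V_b_I,
                "V_b_II": self.V_b_II,
                "V_total": self.V_total,
            }
        )


def integrate_model(
    params: ModelParams,
    init: BiofilmState,
    t_end: float,
    n_steps: int = 200,
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
) -> Trajectory:
    """Integrate the three-compartment ODE system from ``init.t`` to ``t_end``.

    Uses an adaptive high-order explicit integrator (the system is linear and
    non-stiff) with tight default tolerances, sampled on a uniform grid of
    ``n_steps`` points including both endpoints.

    Raises
    ------
    ParameterError
        If preconditions on the time window or step count are violated.
    NumericalError
        If the solver fails or produces non-finite or negative volumes beyond
        ``10 * atol`` (the linear system preserves non-negativity exactly, so
        such a violation indicates solver misuse; volumes are never clipped).
    """
    if not isinstance(params, ModelParams):
        params = ModelParams(*params)
    if n_steps < 2:
        raise ParameterError(f"n_steps must be >= 2, got {n_steps}")
    t_end = _require_finite("t_end", t_end)
    if t_end <= init.t:
        raise ParameterError(f"t_end ({t_end}) must exceed init.t ({init.t})")

    k_m, k_b, k_b_I, k_b_II = params.k_m, params.k_b, params.k_b_I, params.k_b_II

    def rhs(t: float, y: np.ndarray) -> list[float]:
        V_m, V_b_I, V_b_II = y
        return [
            k_m * V_b_I,
            -k_b_I * V_b_I + k_b * V_b_II,
            (k_b_II - k_b) * V_b_II,
        ]

    t_eval = np.linspace(init.t, t_end, n_steps)
    sol = solve_ivp(
        rhs,
        (init.t, t_end),
        [init.V_m, init.V_b_I, init.V_b_II],
        method="DOP853",
        t_eval=t_eval,
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        raise NumericalError(f"ODE integration failed: {sol.message}")
    y = sol.y
    if not np.all(np.isfinite(y)):
        bad = np.argwhere(~np.isfinite(y))
        comp = ("V_m", "V_b_I", "V_b_II")[bad[0, 0]]
        raise NumericalError(
            f"non-finite {comp} at t = {t_eval[bad[0, 1]]:.6g} during integration"
        )
    for name, row in zip(("V_m", "V_b_I", "V_b_II"), y):
        v = row.min()
        if v < -10 * atol:
            t_bad = t_eval[int(np.argmin(row))]
            raise NumericalError(f"{name} fell to {v:.3e} (< -10*atol) at t = {t_bad:.6g}")
    return Trajectory(
        t=t_eval,
        V_m=y[0],
        V_b_I=y[1],
        V_b_II=y[2],
        params=params,
        rtol=rtol,
        atol=atol,
        tau=init.t,
    )


def total_volume(state: BiofilmState, c: float) -> float:
    """Total ooid volume ``V_m + c*(V_b_I + V_b_II)``."""
    if c <= 0:
        raise ParameterError(f"scale factor c must be > 0, got {c}")
    return state.V_m + c * (state.V_b_I + state.V_b_II)


def volume_rate(state: BiofilmState, params: ModelParams) -> float:
    """Instantaneous rate of change of the total volume.

    dV/dt = -(c*k_b_I - k_m) * V_b_I + c*k_b_II * V_b_II.  The total volume is
    stationary (the ooid at its limiting size) when the mineral-plus-decay
    losses of the inner zone balance outer-layer growth.
    """
    return (
        -(params.c * params.k_b_I - params.k_m) * state.V_b_I
        + params.c * params.k_b_II * state.V_b_II
    )


def mineral_front_radius(t, alpha: float = 0.0):
    """Dimensionless mineralisation-front radius.

    R_m(t) = (1 + alpha*(t-1) - exp(-(t-1)))^(1/3) for dimensionless time
    t >= 1 (onset at t = 1, where the radius is exactly zero).  The
    ``1 - exp`` difference is computed with ``expm1`` so the early-time
    t^(1/3) scaling is resolved accurately down to (t-1) ~ 1e-300.

    For ``alpha = 0`` the front saturates at radius 1 (the limiting size);
    for ``alpha > 0`` the cubed radius grows asymptotically linearly in time.

    Accepts scalars or arrays; scalar input returns a float.
    """
    if alpha < 0:
        raise ParameterError(f"replenishment parameter alpha must be >= 0, got {alpha}")
    arr = np.asarray(t, dtype=float)
    if np.any(arr < 1.0):
        raise DomainError(
            "mineralisation has not begun: dimensionless time must be >= 1 (onset)"
        )
    s = arr - 1.0
    cube = alpha * s - np.expm1(-s)
    r = np.cbrt(cube)
    return float(r) if np.isscalar(t) or arr.ndim == 0 else r


def mineral_front_radius_dimensional(
    t, tau: float, params: ModelParams, R: float
):
    """Dimensional mineralisation-front radius without replenishment.

    R_m(t) = ((k_m R^3/(k_b_I c)) * (1 - exp(-k_b_I (t - tau))))^(1/3) for
    t >= tau, where ``R`` is the (pre-onset) limiting biofilm radius and
    ``tau`` the onset time of mineralisation.  Under the canonical scalings
    k_m R^3/(k_b_I c) = 1 and k_b_I = 1 this reduces to the dimensionless law.
    """
    if R <= 0:
        raise ParameterError(f"pre-onset radius R must be > 0, got {R}")
    if params.k_b_I <= 0:
        raise ParameterError("k_b_I must be > 0 for the mineralisation front")
    arr = np.asarray(t, dtype=float)
    if np.any(arr < tau):
        raise DomainError(f"t must be >= onset time tau = {tau}")
    amplitude = params.k_m * R**3 / (params.k_b_I * params.c)
    cube = amplitude * (-np.expm1(-params.k_b_I * (arr - tau)))
    r = np.cbrt(cube)
    return float(r) if np.isscalar(t) or arr.ndim == 0 else r


def replenishment_alpha(params: ModelParams, V_bI_tau: float, V0: float) -> float:
    """Replenishment parameter for a constant outer-layer volume ``V0``.

    Solving the inner-zone balance dV_b_I/dt = -k_b_I V_b_I + k_b V0 with
    V_b_II held at V0 and substituting into the mineralisation law gives a
    cubed-radius law 1 + alpha*(t-1) - exp(-(t-1)) with

        alpha = k_b * V0 / (k_b_I * V_b_I(tau) - k_b * V0),

    which is dimensionless and validated against direct numerical integration
    of the compartment ODEs.  ``V0 = 0`` gives alpha = 0, recovering the
    non-replenished front.
    """
    if V_bI_tau < 0 or V0 < 0:
        raise ParameterError("volumes must be >= 0")
    denom = params.k_b_I * V_bI_tau - params.k_b * V0
    if denom <= 0:
        raise ParameterError(
            "no valid replenishment parameter: k_b_I*V_b_I(tau) - k_b*V0 must be "
            f"positive, got {denom}"
        )
    return params.k_b * V0 / denom


def mineralisation_ode_alternative(
    V_total: float,
    params: ModelParams,
    t_grid: Sequence[float],
    V_m0: float = 0.0,
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
) -> np.ndarray:
    """Mineral volume via the fixed-total-volume route.

    Holds the overall volume fixed at ``V_total`` and assumes the inner-zone
    biotic volume is whatever is not yet mineralised, V_b_I = c*(V - V_m),
    giving dV_m/dt = k_m*c*(V - V_m).  Integrated numerically so it provides
    an independent route to the same dimensionless front law as the
    compartment system.

    Returns the mineral volume evaluated on ``t_grid`` (first entry is the
    initial time, where V_m = ``V_m0``).
    """
    if V_total <= 0:
        raise ParameterError(f"V_total must be > 0, got {V_total}")
    if V_m0 < 0 or V_m0 > V_total:
        raise ParameterError("V_m0 must lie in [0, V_total]")
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.size < 2 or not np.all(np.diff(t_grid) > 0):
        raise ParameterError("t_grid must be strictly increasing with >= 2 points")
    rate = params.k_m * params.c

    sol = solve_ivp(
        lambda t, y: [rate * (V_total - y[0])],
        (t_grid[0], t_grid[-1]),
        [V_m0],
        method="DOP853",
        t_eval=t_grid,
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        raise NumericalError(f"ODE integration failed: {sol.message}")
    return sol.y[0]
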