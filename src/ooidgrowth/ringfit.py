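"""Fit the lamination law to observed concentric ring radii.

Given ring radii digitised from a thin section (e.g. of a laboratory-grown
ooid), the model predicts ring j at

    r_j = scale * (1 + alpha*(j + j0)*dt - exp(-(j + j0)*dt))^(1/3),

so the canonical fit has only two parameters: the overall magnification
``scale`` (length per dimensionless radius unit) and the sampling interval
``dt``.  Optionally the replenishment parameter ``alpha`` and an integer
ring-index offset ``j0`` (for unresolved innermost laminations) can be freed.

Fitting minimises the unweighted sum of squared radial residuals.  For fixed
(dt, alpha, j0) the optimal scale is linear least squares in closed form, so
the search is a 1-D (or low-dimensional) profile over dt: a 61-point
logarithmic grid on [1e-3, 10] followed by bounded local refinement.

A synthetic-ring generator with multiplicative Gaussian digitisation noise
provides parameter-recovery test inputs; the package ships no measured data.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import minimize_scalar

from .errors import DataError, DomainError, GenerationError, ParameterError
from .laminations import ring_law

__all__ = [
    "RingObservations",
    "RingFit",
    "SyntheticRingConfig",
    "fit_rings",
    "synth_rings",
    "residual_profile",
    "DT_GRID",
]

#: Default logarithmic search grid for the sampling interval dt.
DT_GRID = np.logspace(-3.0, 1.0, 61)

_J0_MAX = 5  # exhaustive offset search range when free_offset is set


@dataclass(frozen=True)
class RingObservations:
    """Ordered observed ring radii, innermost first.

    ``j0`` is a known non-negative index offset: the first observed ring is
    lamination number ``j0 + 1`` of the underlying pattern (innermost rings
    may be unresolved in an image).
    """

    radii: tuple[float, ...]
    j0: int = 0

    def __post_init__(self) -> None:
        r = np.asarray(self.radii, dtype=float)
        if r.size == 0:
            raise DataError("at least one ring radius is required")
        if not np.all(np.isfinite(r)) or np.any(r <= 0):
            raise DataError("ring radii must be finite and positive")
        if r.size >= 2 and not np.all(np.diff(r) > 0):
            raise DataError("ring radii must be strictly increasing (degenerate or unsorted input)")
        if self.j0 < 0 or int(self.j0) != self.j0:
            raise DataError(f"j0 must be a non-negative integer, got {self.j0}")
        object.__setattr__(self, "radii", tuple(float(x) for x in r))
        object.__setattr__(self, "j0", int(self.j0))

    @property
    def n_rings(self) -> int:
        return len(self.radii)


@dataclass(frozen=True)
class RingFit:
    """Result of a lamination-law fit."""

    scale: float
    dt: float
    alpha: float
    j0: int
    rmse: float
    converged: bool
    per_ring_residuals: tuple[float, ...]

    @property
    def n_rings(self) -> int:
        return len(self.per_ring_residuals)

    def to_dict(self) -> dict:
        return {
            "scale": self.scale,
            "dt": self.dt,
            "alpha": self.alpha,
            "j0": self.j0,
            "rmse": self.rmse,
            "converged": self.converged,
            "per_ring_residuals": list(self.per_ring_residuals),
        }


@dataclass(frozen=True)
class SyntheticRingConfig:
    """Settings for the synthetic ring generator.

    ``noise_sd`` is the relative (multiplicative) standard deviation of the
    Gaussian digitisation noise applied to each radius — digitisation error
    scales with image magnification, hence multiplicative.  Generation is
    deterministic given ``seed``; draws that break monotonicity are rejected
    and redrawn deterministically.
    """

    n_rings: int
    scale: float
    dt: float
    alpha: float = 0.0
    j0: int = 0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_rings < 1:
            raise ParameterError(f"n_rings must be >= 1, got {self.n_rings}")
        if self.scale <= 0 or self.dt <= 0:
            raise ParameterError("scale and dt must be > 0")
        if self.alpha < 0:
            raise ParameterError(f"alpha must be >= 0, got {self.alpha}")
        if self.j0 < 0:
            raise ParameterError(f"j0 must be >= 0, got {self.j0}")
        if self.noise_sd < 0:
            raise ParameterError(f"noise_sd must be >= 0, got {self.noise_sd}")


def _model_dimensionless(n: int, dt: float, alpha: float, j0: int) -> np.ndarray:
    j = np.arange(1, n + 1, dtype=float) + j0
    return ring_law(j * dt, alpha)


def _profiled_ss(radii: np.ndarray, f: np.ndarray) -> tuple[float, float]:
    """Optimal scale (closed-form linear LS) and the resulting sum of squares."""
    denom = float(f @ f)
    if denom == 0.0:
        return 0.0, float(radii @ radii)
    scale = float(radii @ f) / denom
    resid = radii - scale * f
    return scale, float(resid @ resid)


def synth_rings(config: SyntheticRingConfig, max_attempts: int = 1000) -> RingObservations:
    """Generate noisy synthetic ring observations from the lamination law.

    Radii are ``model * (1 + eps_j)`` with i.i.d. zero-mean Gaussian ``eps_j``
    of standard deviation ``noise_sd``.  If a draw breaks strict monotonicity
    the whole vector is redrawn (up to ``max_attempts``, advancing the same
    seeded generator, so output is deterministic given the seed).
    """
    model = config.scale * _model_dimensionless(
        config.n_rings, config.dt, config.alpha, config.j0
    )
    if config.noise_sd == 0.0:
        return RingObservations(radii=tuple(model), j0=config.j0)
    rng = np.random.default_rng(config.seed)
    for _ in range(max_attempts):
        radii = model * (1.0 + rng.normal(0.0, config.noise_sd, config.n_rings))
        if np.all(radii > 0) and np.all(np.diff(radii) > 0):
            return RingObservations(radii=tuple(radii), j0=config.j0)
    raise GenerationError(
        f"could not generate strictly increasing radii in {max_attempts} attempts "
        f"(noise_sd = {config.noise_sd} too large for dt = {config.dt})"
    )


def _best_alpha(radii: np.ndarray, dt: float, j0: int,
                alpha_max: float = 50.0) -> tuple[float, float, float]:
    """Profile out alpha for fixed (dt, j0): returns (alpha, scale, ss)."""
    n = radii.size

    def obj(a: float) -> float:
        return _profiled_ss(radii, _model_dimensionless(n, dt, a, j0))[1]

    res = minimize_scalar(obj, bounds=(0.0, alpha_max), method="bounded",
                          options={"xatol": 1e-12})
    a = float(res.x)
    # alpha = 0 exactly when the boundary is at least as good
    if obj(0.0) <= res.fun:
        a = 0.0
    scale, ss = _profiled_ss(radii, _model_dimensionless(n, dt, a, j0))
    return a, scale, ss


def fit_rings(
    obs: RingObservations,
    free_alpha: bool = False,
    free_offset: bool = False,
    dt_grid: Sequence[float] | None = None,
) -> RingFit:
    """Least-squares fit of the lamination law to observed ring radii.

    Searches dt on a logarithmic grid with the scale profiled out in closed
    form (and alpha / the integer offset j0 profiled numerically or
    exhaustively when freed), then refines dt by bounded minimisation between
    the best grid point's neighbours.  Deterministic for fixed input.
    """
    n_free = 2 + int(free_alpha) + int(free_offset)
    if obs.n_rings < n_free + 1:
        raise DomainError(
            f"too few rings: {obs.n_rings} observed but a {n_free}-parameter fit "
            f"needs at least {n_free + 1}"
        )
    radii = np.asarray(obs.radii)
    grid = DT_GRID if dt_grid is None else np.asarray(dt_grid, dtype=float)
    j0_candidates = range(0, _J0_MAX + 1) if free_offset else (obs.j0,)

    def eval_dt(dt: float, j0: int) -> tuple[float, float, float]:
        """(ss, scale, alpha) at fixed dt, j0."""
        if free_alpha:
            a, scale, ss = _best_alpha(radii, dt, j0)
            return ss, scale, a
        scale, ss = _profiled_ss(radii, _model_dimensionless(radii.size, dt, 0.0, j0))
        return ss, scale, 0.0

    best = None  # (ss, dt, j0, scale, alpha)
    for j0 in j0_candidates:
        for dt in grid:
            ss, scale, a = eval_dt(float(dt), j0)
            if best is None or ss < best[0]:
                best = (ss, float(dt), j0, scale, a)

    ss0, dt0, j0_hat, _, _ = best
    i = int(np.argmin(np.abs(grid - dt0)))
    lo = float(grid[max(i - 1, 0)])
    hi = float(grid[min(i + 1, grid.size - 1)])
    if lo == hi:  # single-point grid
        lo, hi = dt0 * 0.5, dt0 * 2.0
    res = minimize_scalar(lambda d: eval_dt(d, j0_hat)[0], bounds=(lo, hi),
                          method="bounded", options={"xatol": 1e-13})
    converged = bool(res.success)
    dt_hat = float(res.x) if res.fun <= ss0 else dt0
    ss, scale_hat, alpha_hat = eval_dt(dt_hat, j0_hat)
    fitted = scale_hat * _model_dimensionless(radii.size, dt_hat, alpha_hat, j0_hat)
    resid = radii - fitted
    rmse = float(np.sqrt(np.mean(resid**2)))
    return RingFit(
        scale=scale_hat,
        dt=dt_hat,
        alpha=alpha_hat,
        j0=j0_hat,
        rmse=rmse,
        converged=converged,
        per_ring_residuals=tuple(float(r) for r in resid),
    )


def residual_profile(obs: RingObservations, fit: RingFit) -> np.ndarray:
    """Signed per-ring residuals (observed - fitted) for a fit of ``obs``.

    The sum of squared residuals equals ``n * rmse**2``.
    """
    if fit.n_rings != obs.n_rings:
        raise DataError(
            f"fit covers {fit.n_rings} rings but observations have {obs.n_rings}"
        )
    radii = np.asarray(obs.radii)
    fitted = fit.scale * _model_dimensionless(obs.n_rings, fit.dt, fit.alpha, fit.j0)
    return radii - fitted
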