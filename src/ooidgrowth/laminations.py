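"""Concentric lamination patterns from constant-interval front sampling.

Sampling the mineralisation front at a constant dimensionless interval dt
places ring j (j = 1, 2, ...) at

    R_m(j) = scale * (1 + alpha*j*dt - exp(-j*dt))^(1/3),

producing a large central region surrounded by rings whose spacing strictly
decreases outward.  For alpha = 0 the rings saturate below ``scale`` (the
limiting size); for alpha > 0 the cubed radii grow linearly with ring index.
Patterns can be rendered as deterministic SVG (concentric circles), with an
optional shaded core disc and optional alternate light/dark annuli.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import DomainError, ParameterError

__all__ = ["LaminationPattern", "ring_law", "ring_radii", "make_pattern",
           "ring_spacings", "render_pattern", "render_radii",
           "render_pattern_png"]


def ring_law(elapsed, alpha: float = 0.0) -> np.ndarray:
    """Dimensionless front radius as a function of time since onset.

    Identical to the front law at dimensionless time ``1 + elapsed`` but
    computed directly from the elapsed time, so ring grids like ``j*dt``
    evaluate without a lossy ``(1 + x) - 1`` round trip.
    """
    if alpha < 0:
        raise ParameterError(f"replenishment parameter alpha must be >= 0, got {alpha}")
    s = np.asarray(elapsed, dtype=float)
    if np.any(s < 0):
        raise ParameterError("elapsed time since onset must be >= 0")
    return np.cbrt(alpha * s - np.expm1(-s))


def ring_radii(n_rings: int, dt: float, alpha: float = 0.0, scale: float = 1.0) -> np.ndarray:
    """Radii of the first ``n_rings`` laminations at sampling interval ``dt``."""
    if n_rings < 0:
        raise ParameterError(f"n_rings must be >= 0, got {n_rings}")
    if dt <= 0:
        raise ParameterError(f"sampling interval dt must be > 0, got {dt}")
    if scale <= 0:
        raise ParameterError(f"scale must be > 0, got {scale}")
    j = np.arange(1, n_rings + 1, dtype=float)
    return scale * ring_law(j * dt, alpha)


@dataclass(frozen=True)
class LaminationPattern:
    """An ordered set of concentric ring radii and the law that produced them.

    Invariants checked at construction: radii increasing with non-increasing
    spacings, and (for alpha = 0) no radius above the overall ``scale`` — the
    dimensionless front never exceeds its limiting size 1.  Mathematically the
    inequalities are strict; in double precision the alpha = 0 front saturates
    at the limiting size once j*dt exceeds ~37, producing exact ties, so
    validation rejects only genuine violations (decreasing radii, growing
    spacings, radii beyond the limiting size).
    """

    scale: float
    dt: float
    alpha: float
    radii: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.scale <= 0:
            raise ParameterError(f"scale must be > 0, got {self.scale}")
        if self.dt <= 0:
            raise ParameterError(f"dt must be > 0, got {self.dt}")
        if self.alpha < 0:
            raise ParameterError(f"alpha must be >= 0, got {self.alpha}")
        r = np.asarray(self.radii, dtype=float)
        object.__setattr__(self, "radii", tuple(float(x) for x in r))
        if r.size >= 2 and not np.all(np.diff(r) >= 0):
            raise ParameterError("ring radii must be increasing")
        if r.size >= 3 and not np.all(np.diff(np.diff(r)) <= 0):
            raise ParameterError("ring spacings must not increase outward")
        if self.alpha == 0.0 and r.size and r.max() > self.scale:
            raise ParameterError("with alpha = 0 no ring can exceed the limiting size")

    @property
    def n_rings(self) -> int:
        return len(self.radii)


def make_pattern(n_rings: int, dt: float, alpha: float = 0.0, scale: float = 1.0) -> LaminationPattern:
    """Build a :class:`LaminationPattern` from the sampled front law."""
    return LaminationPattern(
        scale=scale, dt=dt, alpha=alpha,
        radii=tuple(ring_radii(n_rings, dt, alpha, scale)),
    )


def ring_spacings(pattern: LaminationPattern) -> np.ndarray:
    """First differences of the ring radii (widths of successive laminae)."""
    if pattern.n_rings < 2:
        raise DomainError("at least 2 rings are required to form spacings")
    return np.diff(np.asarray(pattern.radii))


def _fmt(x: float) -> str:
    return f"{x:.12g}"


def render_pattern(
    pattern: LaminationPattern,
    path: str | Path | None = None,
    core_shading: bool = False,
    alternate_shading: bool = False,
    margin: float = 0.05,
) -> str:
    """Render the pattern as concentric circles in SVG.

    The output is a deterministic function of the inputs (identical input
    yields byte-identical SVG).  ``core_shading`` fills the disc inside ring 1
    (the large central region); ``alternate_shading`` fills every second
    annulus to mimic the light/dark couplets of natural ooid cortices.  An
    empty pattern renders a centre mark only.

    Returns the SVG text; if ``path`` is given the text is also written there.
    """
    return render_radii(pattern.radii, path, core_shading=core_shading,
                        alternate_shading=alternate_shading, margin=margin,
                        fallback_extent=pattern.scale)


def render_radii(
    radii,
    path: str | Path | None = None,
    core_shading: bool = False,
    alternate_shading: bool = False,
    margin: float = 0.05,
    fallback_extent: float = 1.0,
) -> str:
    """Deterministic SVG of concentric circles at arbitrary increasing radii.

    Used both by :func:`render_pattern` and to draw observed (possibly noisy)
    ring measurements, which need not satisfy the model-pattern invariants.
    """
    radii = [float(r) for r in radii]
    r_max = radii[-1] if radii else fallback_extent
    half = r_max * (1.0 + margin)
    parts = [
        '<?xml version="1.0" encoding="UTF-8"?>\n',
        f'<svg xmlns="http://www.w3.org/2000/svg" viewBox="{_fmt(-half)} {_fmt(-half)} '
        f'{_fmt(2 * half)} {_fmt(2 * half)}">\n',
    ]
    stroke = r_max / 400.0
    if alternate_shading and radii:
        # fill annuli outermost-first so inner discs paint over outer ones
        for i in range(len(radii) - 1, -1, -1):
            fill = "#c8b89a" if i % 2 == 0 else "#efe8d8"
            parts.append(
                f'  <circle cx="0" cy="0" r="{_fmt(radii[i])}" fill="{fill}" stroke="none"/>\n'
            )
    if core_shading and radii:
        parts.append(
            f'  <circle cx="0" cy="0" r="{_fmt(radii[0])}" fill="#a89878" stroke="none"/>\n'
        )
    for r in radii:
        parts.append(
            f'  <circle class="ring" cx="0" cy="0" r="{_fmt(r)}" fill="none" '
            f'stroke="black" stroke-width="{_fmt(stroke)}"/>\n'
        )
    if not radii:
        parts.append(
            f'  <circle class="centre" cx="0" cy="0" r="{_fmt(stroke * 2)}" fill="black"/>\n'
        )
    parts.append("</svg>\n")
    svg = "".join(parts)
    if path is not None:
        Path(path).write_text(svg)
    return svg


def render_pattern_png(
    pattern: LaminationPattern,
    path: str | Path,
    core_shading: bool = False,
    dpi: int = 150,
) -> None:
    """Thin raster export of the same concentric-circle drawing."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt
    from matplotlib.patches import Circle

    radii = list(pattern.radii)
    r_max = radii[-1] if radii else pattern.scale
    fig, ax = plt.subplots(figsize=(4, 4))
    if core_shading and radii:
        ax.add_patch(Circle((0, 0), radii[0], facecolor="#a89878", edgecolor="none"))
    for r in radii:
        ax.add_patch(Circle((0, 0), r, facecolor="none", edgecolor="black",
                            linewidth=0.8))
    if not radii:
        ax.plot(0, 0, "k.", markersize=3)
    lim = r_max * 1.05
    ax.set_xlim(-lim, lim)
    ax.set_ylim(-lim, lim)
    ax.set_aspect("equal")
    ax.axis("off")
    fig.savefig(path, dpi=dpi, bbox_inches="tight")
    plt.close(fig)
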