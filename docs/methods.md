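# Methods

## The model

Ooids — spherical sediment grains with a nucleus wrapped in concentric
mineral laminae — are modelled here as the product of organomineralisation in
a surface biofilm growing in a nutrient-limited environment. The construction
follows the classic avascular-growth picture: nutrients at background
concentration `c_II` diffuse in from the surrounding medium and are consumed
by microbes at a constant volumetric rate `k`. Once the grain is large enough,
consumption in the outer rim starves the interior below the survival
threshold `c_I`, splitting the biofilm into an **outer active layer** of
roughly constant width and a **starved inner zone** where microbes decay and
mineral accretes.

The state is three well-mixed volumes: mineral `V_m`, inner-zone biotic
volume `V_b^I`, and outer-layer biotic volume `V_b^II`, with linear kinetics

```
dV_m/dt    =  k_m  V_b^I
dV_b^I/dt  = -k_b^I V_b^I + k_b V_b^II
dV_b^II/dt = (k_b^II - k_b) V_b^II
```

`k_m` converts inner-zone biomass to mineral, `k_b^I` is the inner-zone decay
rate, `k_b^II` the outer-layer **growth** rate, and `k_b` the rate at which
outer-layer microbes transition inward. The total grain volume is
`V = V_m + c (V_b^I + V_b^II)` where `c` converts microbe volume to biofilm
volume, so

```
dV/dt = -(c k_b^I - k_m) V_b^I + c k_b^II V_b^II.
```

No spatial resolution is attempted: compartments are well-mixed volumes, and
the spherical geometry enters only through the thin-shell closures below.
The biochemistry of the organomineralisation itself is deliberately a black
box — only its volumetric rate `k_m` appears.

## Limiting size

At stationarity (`dV/dt = 0`), closing the geometry with an outer layer that
is a thin shell (`V^II ≈ 4πR²w`) and an inner zone that is the full sphere
(`V^I = c V_b^I + V_m ≈ (4/3)πR³`) gives the cubic

```
-A R³ + B R² + C = 0,
A = (4π/3)|k_b^I - k_m/c|,  B = 4π k_b^II w,  C = |k_b^I - k_m/c| V_m,
```

valid in the *limiting-size regime* `c k_b^I > k_m` (inner-zone volume loss
outpaces mineral gain). With exactly one sign change in the coefficients,
Descartes' rule gives exactly one positive root. We solve it by Brent
bracketing on `(0, B/A + (C/A)^{1/3} + 1]` — the cubic is provably positive
at 0 and negative at the bracket end — plus Newton polishing, rather than by
closed-form radicals, which cancel catastrophically for extreme parameter
ratios; `numpy.roots` serves as a cross-check in the tests, never as the
implementation. The `V_m = 0` case degenerates to the exact quadratic root
`B/A`.

Analytic bounds: `R > 3 c k_b^II w/(c k_b^I - k_m)` (from `V_m = 0`; we treat
this value as an attained infimum) and, substituting the geometric ceiling
`V_m = (4/3)πR³ - 4πR²w + 4πRw²`,

```
R < w (c k_b^I - k_m) / (c k_b^I - k_m - c k_b^II),
```

finite only in the *finite-upper-bound regime*
`c k_b^I - k_m - c k_b^II > 0`; otherwise the bound is reported as an
explicit unbounded flag, never as an infinity in serialised output. Carrying
out the substitution gives `c k_b^I - k_m` in the numerator; derivations in
circulation sometimes show `c k_b - k_m` there, which does not follow from
the substitution and is not used. Both bounds are exactly linear in `w`, so
with `w = sqrt(2 (c_II - c_I) D / k)` the limiting size scales as `D^{1/2}`
and `k^{-1/2}` — measured in the package by log–log regression over
two-decade sweeps through the full width-plus-cubic pipeline.

### Layer width

The planar width formula is the thin-shell limit of the spherical
diffusion–consumption balance `D (r² c')'/r² = k` on `[R_i, R]` with
`c(R) = c_II`, `c(R_i) = c_I`, `c'(R_i) = 0`. The general solution
`c(r) = k r²/(6D) + a/r + b` reduces the free-interface problem to one scalar
equation,

```
(k/6D) (R² + 2R_i³/R - 3R_i²) = c_II - c_I,
```

with a monotone left side, solved by Brent's method
(`shell_width_exact`). We use this exact reduction rather than a
finite-difference discretisation because it is closed-form up to a scalar
root find; an independent ODE-shooting solver (`shell_width_shooting`,
integrating outward from the zero-flux interface) provides the dual-route
check in the tests. When even `R_i = 0` leaves the centre above threshold
(`k R²/(6D) ≤ c_II - c_I`) there is no starved zone yet — the initial,
fully-active growth stage — and the solver reports full penetration instead
of failing. Expanding the scalar equation at `R_i = R - w` gives
`w²(3 - 2w/R) k/(6D) = c_II - c_I`, i.e. the planar formula with a relative
correction `+w/(3R)`; at `w/R = 10⁻³` the measured ratio is 1.00033.

## Mineralisation front and laminations

With no replenishment of the inner zone (`k_b = 0`), integrating the
compartment system from the onset of mineralisation (time `τ`, radius `R`,
`V_b^I(τ) = (4π/3)R³/c`, `V_m(τ) = 0`) gives exponential closed forms and a
front radius

```
R_m(t) = ((k_m R³/(k_b^I c)) (1 - e^{-k_b^I (t-τ)}))^{1/3}.
```

The canonical internal representation adopts the natural scalings
`k_m R³/(k_b^I c) = 1` (sets the size unit), `k_b^I = 1` (sets the time
unit), onset at dimensionless time 1:

```
R_m(t) = (1 + α(t-1) - e^{-(t-1)})^{1/3},   t ≥ 1.
```

Dimensional wrappers convert in and out. We return exactly 0 at `t = 1`
(closed interval) and raise a domain error for `t < 1`. The `1 - e^{-s}`
difference is computed with `expm1`, which keeps the early-time behaviour
`R_m ~ ((1+α) s)^{1/3}` accurate at `s = 10⁻⁸` where naive subtraction would
lose 8 digits; the measured log–log slope over `s ∈ [10⁻⁸, 10⁻⁶]` is 1/3 to
better than 10⁻⁶ for all α tested. This cube-root law is the same scaling
form as Ostwald-ripening coarsening, but here it arises from volumetric
conversion of a finite biotic reservoir, and it cannot persist: for `α = 0`
the front saturates at the limiting size.

**Replenishment.** Holding the outer-layer volume constant at `V_0`
(continuous resupply of the inner zone at rate `k_b V_0`), the inner-zone
balance `dV_b^I/dt = -k_b^I V_b^I + k_b V_0` solves in closed form and the
cubed-radius law acquires a linear term with coefficient

```
α = k_b V_0 / (k_b^I V_b^I(τ) - k_b V_0),
```

requiring a positive denominator (decay of the initial inner-zone stock must
dominate the resupply term). This expression is dimensionless, as α must be;
a variant with `k_b²` in the numerator that appears in some statements of
the result is not, and disagrees with direct numerical integration of the
compartment ODEs by exactly a factor `k_b` — the package tests pin the
implemented form against that integration oracle at 10⁻⁶ relative. `V_0 = 0`
recovers α = 0 bit-identically.

An equivalent route treats the total volume as fixed after onset and the
inner biotic volume as whatever is not yet mineralised,
`dV_m/dt = k_m c (V - V_m)`; integrated numerically it reproduces the same
dimensionless front to ~10⁻¹³, a genuine two-route consistency check.

**Laminations.** Sampling the front at a constant interval Δt puts ring j at
`scale · (1 + α j Δt - e^{-j Δt})^{1/3}`, j = 1, 2, … — rings indexed from 1,
with the core rendered as the disc inside ring 1. The cubed-radius law is
concave, so spacings strictly decrease outward: a large central region
wrapped in progressively finer laminae, with size-limited growth for α = 0.
These strict inequalities are mathematical; in double precision the α = 0
front saturates exactly once `j Δt ≳ 37`, producing tied radii, so the
pattern type tolerates ties and the strictness tests run on grids where
doubles resolve them. Rendering is deterministic SVG (byte-identical for
identical input; circle elements are countable in tests); smooth circles are
the model's statement — lamination roughness is out of scope. Raster export
is a thin matplotlib conversion.

## Ring fitting

Observed ring radii (digitised upstream; this package does no image
processing) are fit by unweighted least squares on radii to
`scale · (1 + α (j+j0) Δt - e^{-(j+j0) Δt})^{1/3}`. The canonical fit frees
only `(scale, Δt)` — the two-parameter comparison used against
laboratory-grown ooids; `α` and a small integer index offset `j0 ∈ [0, 5]`
(for unresolved innermost laminae) are opt-in. For fixed `(Δt, α, j0)` the
optimal scale is linear least squares in closed form, so the search is a
61-point logarithmic grid on `Δt ∈ [10⁻³, 10]` with profiled scale (α
profiled by bounded scalar minimisation, j0 exhaustively), then bounded
refinement of Δt between the best grid point's neighbours. The objective is
smooth in Δt; fitting radii rather than spacings is the simpler objective
and avoids differencing noise. Minimum ring counts are one more than the
number of free parameters (3 for the two-parameter fit).

**Synthetic observations.** The generator emulates digitisation of a
thin-section image: exact model radii times `(1 + ε_j)` with i.i.d. Gaussian
`ε_j` of standard deviation `noise_sd` — multiplicative because digitisation
error scales with magnification. Draws breaking strict monotonicity are
rejected and redrawn deterministically from the same seeded generator. The
recovery study uses 12 rings, Δt = 0.4, scale = 500 (a lamination stack
spanning ~350–500 µm, the scale of experimentally grown ooids), and 1%
noise; these are the package's reference conditions. What the generator does
*not* emulate: non-circular rings, missing or merged laminae, diagenetic
overprint, and correlated digitisation errors — so passing recovery tests
demonstrate identifiability of the law under idealised measurement, not
robustness to real petrographic complications. Under the reference
conditions the median relative recovery errors over 100 seeded replicates
are ~3% for Δt and ~0.3% for scale; noiseless self-fits recover both to
~10⁻⁹ relative.

## Numerical choices

- ODE integration: `solve_ivp` DOP853 with rtol 10⁻¹⁰ / atol 10⁻¹² by
  default (the systems are linear and non-stiff; tight tolerances make
  closed-form comparisons meaningful). The integrator never clips volumes; a
  post-hoc assertion fails the run if any volume drops below −10·atol, since
  the linear system preserves non-negativity exactly and a violation
  indicates solver misuse.
- Default kinetic parameters `k_m = 0.5, k_b = 0.1, k_b^I = 1, k_b^II = 0.2,
  c = 1` with nutrients `c_I = 0.5, c_II = 1, D = 1, k = 1` (so `w = 1`):
  chosen once to sit inside both regimes (limiting size margin 0.5,
  finite-upper-bound margin 0.3) at the canonical time scale `k_b^I = 1`.
- Config files are flat key/value YAML (JSON parses as a YAML subset);
  unknown keys are rejected with the nearest valid key suggested; CLI flags
  override file values which override defaults. All CSV/JSON serialisation
  carries ≥ 12 significant digits.
- Problem sizes in the test and acceptance runs (1000-draw root sweeps,
  300-draw bound sweeps, 100-replicate recovery study, 500-point equivalence
  grids) were chosen as the smallest sizes at which the Monte-Carlo medians
  stabilise; the whole pipeline runs in a few seconds.

## Known limitations

- Compartments are well-mixed: no moving-boundary PDE couples the front to
  the nutrient field; the width formula is steady-state.
- The α > 0 front is derived for a *constant* outer-layer volume; the fully
  coupled case with growing `V_b^II` has no closed form here.
- The two-parameter fit has no uncertainty quantification beyond the
  Monte-Carlo recovery study (no bootstrap intervals).
- The `j0` offset search and the subset question (which laminae of a real
  image to include) are package conventions, not properties of the model.
- Diagenetic restructuring of laminae (radial spindle/cone fabrics,
  recrystallisation) is explicitly out of scope; departures of real ring
  profiles from this law are diagnostic signal, not model failure.
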