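# Methods

## Model and assumptions

The package treats a rigid particle sinking steadily through a quiescent,
incompressible Newtonian fluid. At terminal velocity the force balance
(weight = buoyancy + drag) with drag written as `F_drag = ½ ρ_f U² A C_D`
and `U` eliminated through `Re = L U ρ_f / μ` gives the constraint

    C_D^F(Re) = 2 g V (ρ_p − ρ_f) L² ρ_f / (A μ² Re²) = 2 Ar / Re²,

with `Ar = g L_Ar³ ρ_f (ρ_p − ρ_f) / μ²` and `L_Ar³ = V L² / A`. Because
`C_D^F ∝ Re⁻²` falls faster than any physical drag curve, its intersection
with a decreasing `C_D(Re)` is unique — the operating point
`(Re^O, C_D^O, U^O)`. All solvers exploit this: roots are bracketed on a
log-spaced `Re` (or `S`) grid and refined with Brent's method to machine
precision; residuals at the returned root are below 1e-8 relative.

Geometric descriptors follow settling conventions: `L` is the maximum extent
parallel to the sinking direction, `A` the projected frontal area
perpendicular to it, `V` the solid volume excluding fluid-filled cavities.
Orientation is an input, not a prediction: the package assumes the sinking
attitude is known (measured photographically in practice).

## Reference curves and corrections

**Sphere drag.** Morrison's four-term correlation, valid `0 < Re < 10⁶`,
tending to Stokes' `24/Re` at small `Re` (≈0.48 at `Re = 1000`). Below
`Re = 1e-4` the analytic Stokes branch is used outright; the switch is
continuous to < 5e-7 relative and avoids float overflow of the high-`Re`
terms. Five pinned regression values guard the transcription.

**Wall effects.** A tank of diameter `D` adds drag to a model of diameter
`d = L`. For `λ = d/D ≤ 0.1` and `Re ≲ 50` the axial-cylinder series
(Bohlin/Faxén form) applies:

    K(λ) = [1 − 2.10444 λ + 2.08877 λ³ − 0.94813 λ⁵ − 1.372 λ⁶
            + 3.87 λ⁸ − 4.19 λ¹⁰]⁻¹,

with the apparent in-tank drag coefficient `C_D^walls = K · C_D^∞` at matched
`Re`. At the diameter ratios of desk-scale experiments (λ ≈ 0.003–0.02) the
correction is 0.6–3.8%. Beyond `Re = 50` the correction is applied unchanged
with a warning; beyond `λ = 0.1` it raises, since stronger confinement needs
a different correction family. Because the virtual tank applies the same `K`
forward that the reduction removes, the closed loop is exactly consistent
under this convention.

## Empirical drag spline

Wall-corrected `(Re, C_D^∞)` points are fitted in `(log₁₀ Re, log₁₀ C_D)`,
where sphere-like drag curves are nearly straight. The cubic variant is a
degree-3 B-spline with three knots — the data endpoints plus one interior
knot chosen by a residual scan over five candidate positions — solved as a
least-squares problem under two linear inequality constraints evaluated on a
240-point grid across the data range: `y' ≤ 0` (monotone decreasing) and
`y'' ≥ 0` (concave up). A tiny roughness penalty (1e-8 relative) makes the
under-determined three-point case well-posed without visibly biasing larger
fits. Convex-decreasing in log space implies convex-decreasing in linear
space, so the constraints transfer. The linear variant interpolates the
points piecewise-linearly in log–log (falling back to the same constrained
machinery if the data are non-monotone, with a warning). Outside the data
range both variants continue linearly in fit space and mark evaluations as
extrapolated. Log-space fitting and constraint placement were genuinely open
choices; they are recorded in the curve metadata (`fit_space`).

## Experiment planning and volume prediction

The first scale `S1` targets the guessed operating point in the tank:
`C_D^F_tank(Re; S, V(S)) = K(λ(S)) C_D_target` solved for `S`. `S2`/`S3`
target the ends of the expected `Re` bracket (default 18–55, widened when the
guess falls outside it, so the three models always straddle the guess).
Scales are rounded to one decimal before "printing", and a requested scale
that collides with an existing model is stepped by 0.1 toward the side of the
current `Re` gap.

Printed models come out heavier than `S³V^O` (excess resin is harder to
remove from small models), so volumes are always *measured* (mass over resin
density) and predicted where needed by: cubic spline interpolation of the
`(S, V)` pairs when at least four exist and `S` is interior; otherwise
nearest-pair cubic scaling `V(S_near)(S/S_near)³`. Four pairs is the minimum
that supports a cubic interpolant.

## Convergence criteria

Per iteration, with `n ≥ 3` points: (1) the cubic-fit operating point must be
interpolated; (2) `|U_lin − U_cub| / U_cub ≤ 0.05`; (3)
`min_i |Re_i − Re^O| / Re^O < 0.15`. On `max_iter` (default 10) exhaustion
the best estimate is returned flagged unconverged with a warning, never
silently.

## Virtual tank

The synthetic-experiment generator emulates the physical measurement chain:
terminal force balance of the scaled model against a ground-truth drag curve
with the wall factor applied; measured mass from the biased volume
`V = S³V^O (1 + c/S)` with `c = 0.3` by default (matching the observed
direction of printing bias — small models proportionally heavier); five
replicate speeds with mean-one multiplicative lognormal noise (default
CV = 1%); deterministic substreams per (seed, scale). Optional straight-line
two-camera tracks with timestamp jitter exercise the velocimetry path.

What it does **not** model — and what passing tests therefore cannot show
about real data: drag curves that deviate from Morrison-like shapes more
radically than a 0.7–1.5× multiplier with a ±0.1 power tilt, release
disturbances, convection, air bubbles or residual resin on models, lens
distortion, and tracking/segmentation error. In particular, because the
virtual truths are smooth sphere-curve variants, the planned first model
lands close to the final operating point and the loop typically converges at
the three-model minimum; with real morphologies, extra iterations are
expected.

## Study-condition defaults

| Quantity | Default | Why |
|---|---|---|
| g | 9.80665 m s⁻² | standard gravity; configurable |
| Seawater | ρ = 1025 kg m⁻³, μ = 1.08e-3 Pa s | near-surface, ~20 °C, S = 35 |
| Working fluid | ρ = 830 kg m⁻³, μ = 0.022 Pa s | 'Carnation' white mineral oil |
| Model resin | ρ = 1121.43 kg m⁻³ | weighed printed-resin calibration cubes |
| Test density | 1400 kg m⁻³ | effective (bulk) density placing 750–1150 µm tests at Re^O ≈ 20–55, the regime reported for settling foraminifera |
| Tank | 0.9 m diameter, 1.18 m oil depth | cylindrical acrylic tank |
| Depth window | 0.19–0.99 m | central 0.8 m, past the transient and above end effects |
| Re bracket | (18, 55) | published settling range for foraminifera |

All are configuration values (YAML/JSON, with explicit µm/mm units accepted
for geometry), never hard-coded in operations.

## Transient settling

Between release and terminal velocity, `M dU/dt = V g Δρ − F_drag(U)` and
`dZ/dt = U` with `U(0) = Z(0) = 0`, integrated by adaptive RK45 at relative
tolerance 1e-8. The drag force is written as a function of `U` that tends to
`12 μ A U / L` (Stokes form; `3πμdU` for a sphere) as `U → 0`, so the
`C_D ∝ 1/Re` singularity at rest never enters. Added-mass and Basset history
forces are neglected. For sub-millimetre particles the depth to 99.9% of
terminal speed is a few millimetres to centimetres — far inside any
reasonable release lead-in — which is why the measured speeds are treated as
terminal.

## Numerical choices and degenerate inputs

- Root brackets: log-spaced scan (400 points) over `(1e-6, 1e6)` in `Re`, or
  `(1e-2, 1e4)` in `S`; absence of a sign change raises a no-intersection
  error naming the endpoint values.
- During scale bracketing only, `λ` is clamped at its 0.1 validity limit;
  genuine solutions sit far below it for any sensible tank.
- The replicate filter's ±5% boundary is inclusive, with a 1e-9 relative
  epsilon so exact boundary values are not dropped by rounding.
- Mesh volume requires watertightness (open-edge count reported otherwise);
  the silhouette area is the exact shapely union of projected triangles, so
  there is no resolution parameter; degenerate edge-on faces are skipped and
  an all-edge-on mesh yields a zero-area warning.
- Duplicate-`Re` drag points, fewer than three points, buoyant particles and
  non-positive quantities raise typed errors early.

## Problem sizes

The default test suite and the acceptance run use desk-scale sizes: 20–24
seeded closed-loop runs per suite, 5 replicates per model, meshes of ≤ ~5000
faces. A full suite completes in well under a minute on one core.

## Known limitations

- The wall correction is a small-λ, `Re ≲ 50` series; high-`Re` or
  strong-confinement experiments need a different correction.
- The spline's shape constraints assume drag that decreases and flattens with
  `Re`; drag-crisis behaviour (`Re > ~2e5`) is out of scope.
- Uncertainty is reported only through replicate spread; the spline carries
  no confidence band.
- Orientation stability of the sinking particle is assumed, not predicted.
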