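"""Orchestration of the dynamic-scaling estimation loop.

The loop mirrors the physical workflow: guess the operating Reynolds number of
the life-size particle from a sphere correlation, plan three model scale
factors that bracket the expected Re range in the tank, "sink" the models (a
virtual tank, or real measurements from file), turn each measurement into a
wall-corrected (Re, C_D) point, fit the empirical drag spline, intersect it
with the life-size force-balance constraint to get the operating point, and
repeat — printing one extra model per iteration at the scale the current
operating point implies — until three convergence criteria hold:

1. the operating point is not extrapolated beyond the measured data range;
2. cubic- and linear-spline estimates of U^O agree within 5%;
3. the predicted Re^O is within 15% of the closest measured Re.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Protocol, Sequence

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.optimize import brentq

from .core import (
    G_STANDARD,
    ExperimentRecord,
    FluidSpec,
    InsufficientDataError,
    InvalidInputError,
    MaterialSpec,
    NoIntersectionError,
    ParticleGeometry,
    cd_constraint_at_scale,
    cd_force_balance,
    reynolds,
    speed_from_reynolds,
)
from .correlations import MORRISON, DragCorrelation
from .kinematics import aggregate_replicates
from .spline import DragCurve, DragDataPoint, fit_drag_spline
from .walls import WallGeometry, cd_bounded, cd_unbounded, wall_factor_K

__all__ = [
    "OperatingPoint",
    "VolumePredictor",
    "ConvergenceReport",
    "IterationState",
    "EstimationResult",
    "terminal_state",
    "initial_operating_guess",
    "plan_first_scales",
    "predict_volume",
    "solve_operating_point",
    "next_scale",
    "check_convergence",
    "reduce_record",
    "run_estimation",
]

_CRIT2_MAX = 0.05  # max cubic-vs-linear U^O variation
_CRIT3_MAX = 0.15  # max relative gap between Re^O and the closest measured Re


@dataclass(frozen=True)
class OperatingPoint:
    """The particle's operating state: (Re^O, C_D^O, U^O) plus diagnostics."""

    Re_O: float
    C_D_O: float
    U_O: float
    extrapolated: bool = False
    iteration: int = 0


@dataclass
class VolumePredictor:
    """Predict printed-model volume V(S) from measured (S, V) pairs.

    With at least four pairs and a scale inside their range, a cubic spline
    interpolant of V versus S is used; otherwise the nearest measured pair is
    scaled cubically, ``V(S_near) * (S / S_near)^3``.
    """

    scales: list[float] = field(default_factory=list)
    volumes: list[float] = field(default_factory=list)

    def add(self, S: float, V: float) -> None:
        if not S > 0 or not V > 0:
            raise InvalidInputError(f"S and V must be positive: {S}, {V}")
        self.scales.append(float(S))
        self.volumes.append(float(V))

    def predict(self, S: float) -> float:
        if not self.scales:
            raise InsufficientDataError("no measured (S, V) pairs")
        if not S > 0:
            raise InvalidInputError(f"S must be positive, got {S!r}")
        s = np.asarray(self.scales)
        v = np.asarray(self.volumes)
        order = np.argsort(s)
        s, v = s[order], v[order]
        # exact pass-through at measured scales
        hit = np.isclose(s, S, rtol=1e-12, atol=0.0)
        if hit.any():
            return float(v[hit][0])
        if len(s) >= 4 and s[0] <= S <= s[-1]:
            return float(CubicSpline(s, v)(S))
        nearest = int(np.argmin(np.abs(s - S)))
        return float(v[nearest] * (S / s[nearest]) ** 3)


def predict_volume(predictor: VolumePredictor, S: float) -> float:
    """Functional alias for :meth:`VolumePredictor.predict`."""
    return predictor.predict(S)


@dataclass(frozen=True)
class ConvergenceReport:
    """Outcome of the three convergence criteria for one iteration."""

    criterion1_no_extrapolation: bool
    criterion2_spline_variation: float
    criterion3_re_gap: float
    converged: bool


@dataclass
class IterationState:
    """Audit record of one iteration of the loop."""

    iteration: int
    points: list[DragDataPoint]
    curve_cubic: DragCurve
    curve_linear: DragCurve
    op_cubic: OperatingPoint
    op_linear: OperatingPoint
    report: ConvergenceReport
    planned_S: float | None = None  # scale requested for the *next* model


@dataclass
class EstimationResult:
    """Final operating point, convergence report and full iteration history."""

    operating_point: OperatingPoint
    report: ConvergenceReport
    history: list[IterationState]
    records: list[ExperimentRecord]
    points: list[DragDataPoint]
    converged: bool
    models_sunk: int


class ExperimentSource(Protocol):
    """Anything able to produce a measured record for a requested scale."""

    def sink(self, S: float, experiment_id: str) -> ExperimentRecord: ...


# ---------------------------------------------------------------------------
# root-finding helpers
# ---------------------------------------------------------------------------


def _log_bracket_root(
    f: Callable[[float], float], lo: float, hi: float, n: int = 400
) -> float:
    """Find a sign change of f on a log-spaced grid in [lo, hi] and refine."""
    grid = np.logspace(np.log10(lo), np.log10(hi), n)
    vals = np.array([f(g) for g in grid])
    sign = np.sign(vals)
    idx = np.nonzero(np.diff(sign) != 0)[0]
    if len(idx) == 0:
        raise NoIntersectionError(
            f"no sign change of the objective on [{lo:g}, {hi:g}]; "
            f"endpoint values {vals[0]:.3g} and {vals[-1]:.3g}"
        )
    a, b = grid[idx[0]], grid[idx[0] + 1]
    return float(brentq(f, a, b, xtol=1e-300, rtol=8.9e-16, maxiter=200))


def terminal_state(
    geom: ParticleGeometry,
    particle_material: MaterialSpec,
    fluid: FluidSpec,
    drag: DragCorrelation = MORRISON,
    g: float = G_STANDARD,
) -> tuple[float, float, float]:
    """Terminal (Re, C_D, U) of a particle under a given drag correlation.

    Solves ``C_D^F(Re) = C_D(Re)`` by bracketed root finding on log Re.  The
    force-balance side falls as Re^-2, faster than any physical drag curve,
    so the crossing is unique.
    """

    def f(Re: float) -> float:
        return np.log(cd_force_balance(Re, geom, particle_material, fluid, g)) - np.log(
            drag(Re)
        )

    lo = max(1e-6, drag.re_min * (1 + 1e-9) if drag.re_min > 0 else 1e-6)
    hi = min(1e6, drag.re_max * (1 - 1e-9))
    Re = _log_bracket_root(f, lo, hi)
    C_D = cd_force_balance(Re, geom, particle_material, fluid, g)
    U = speed_from_reynolds(Re, geom.L, fluid)
    return Re, C_D, U


# ---------------------------------------------------------------------------
# the spec'd operations
# ---------------------------------------------------------------------------


def initial_operating_guess(
    original: ParticleGeometry,
    natural_fluid: FluidSpec,
    particle_material: MaterialSpec,
    correlation: DragCorrelation = MORRISON,
    g: float = G_STANDARD,
) -> OperatingPoint:
    """First estimate of the operating point using a sphere drag correlation."""
    Re, C_D, U = terminal_state(original, particle_material, natural_fluid, correlation, g)
    return OperatingPoint(Re_O=Re, C_D_O=C_D, U_O=U, extrapolated=False, iteration=0)


def _solve_scale_for_target(
    Re_target: float,
    C_D_target: float,
    volume_fn: Callable[[float], float],
    original: ParticleGeometry,
    tank: WallGeometry | float,
    working_fluid: FluidSpec,
    model_material: MaterialSpec,
    g: float = G_STANDARD,
) -> float:
    """Scale factor S at which a model is expected to land on (Re, C_D) in the tank.

    Solves ``C_D^F_tank(Re; S, V(S)) = K(lambda(S)) * C_D_target`` for S.  The
    wall factor is clamped to its validity limit during bracketing only; real
    solutions sit at small lambda for any sensible tank.
    """
    D = tank.tank_diameter if isinstance(tank, WallGeometry) else float(tank)

    def f(S: float) -> float:
        lam = min(S * original.L / D, 0.0999)
        lhs = cd_constraint_at_scale(
            Re_target, S, original, volume_fn(S), model_material, working_fluid, g
        )
        return np.log(lhs) - np.log(C_D_target * wall_factor_K(lam))

    return _log_bracket_root(f, 1e-2, 1e4)


def plan_first_scales(
    guess: OperatingPoint,
    original: ParticleGeometry,
    tank: WallGeometry | float,
    working_fluid: FluidSpec,
    model_material: MaterialSpec,
    re_bracket: tuple[float, float] = (18.0, 55.0),
    correlation: DragCorrelation = MORRISON,
    g: float = G_STANDARD,
) -> list[float]:
    """Choose the first three model scales [S2 < S1 < S3].

    S1 targets the guessed operating point in the tank (wall-adjusted); S2 and
    S3 target the ends of the expected Re bracket (default 18-55, the range
    reported for settling foraminifera), widened if needed so it also spans
    the guess.  Nominal cubic volume scaling is assumed since nothing has been
    printed yet.
    """
    lo, hi = re_bracket
    if not 0 < lo < hi:
        raise InvalidInputError(f"invalid Re bracket {re_bracket!r}")
    # widen so the bracket always straddles the guess
    lo = min(lo, guess.Re_O / 1.3)
    hi = max(hi, guess.Re_O * 1.3)

    def nominal_volume(S: float) -> float:
        return S**3 * original.V

    def solve(Re_t: float, Cd_t: float) -> float:
        return _solve_scale_for_target(
            Re_t, Cd_t, nominal_volume, original, tank, working_fluid, model_material, g
        )

    S1 = solve(guess.Re_O, guess.C_D_O)
    S2 = solve(lo, correlation(lo))
    S3 = solve(hi, correlation(hi))
    if not S2 < S1 < S3:  # numerical degeneracy; keep strict ordering
        S2, S1, S3 = sorted((S2, S1, S3))
        if S2 == S1:
            S2 *= 0.8
        if S3 == S1:
            S3 *= 1.25
    return [S2, S1, S3]


def solve_operating_point(
    curve: DragCurve,
    original: ParticleGeometry,
    natural_fluid: FluidSpec,
    particle_material: MaterialSpec,
    g: float = G_STANDARD,
    iteration: int = 0,
) -> OperatingPoint:
    """Intersect the life-size force-balance constraint with the fitted curve.

    The root of ``C_D^F(Re) - C_D^E(Re)`` is bracketed on
    (Re_min/10, Re_max*10) around the curve's data range; the operating point
    is flagged as extrapolated when it falls outside the data range itself.
    """
    lo = curve.data_range[0] / 10.0
    hi = curve.data_range[1] * 10.0

    def f(Re: float) -> float:
        return np.log(
            cd_force_balance(Re, original, particle_material, natural_fluid, g)
        ) - np.log(curve.evaluate(Re))

    Re_O = _log_bracket_root(f, lo, hi)
    C_D_O = cd_force_balance(Re_O, original, particle_material, natural_fluid, g)
    U_O = speed_from_reynolds(Re_O, original.L, natural_fluid)
    return OperatingPoint(
        Re_O=Re_O,
        C_D_O=C_D_O,
        U_O=U_O,
        extrapolated=curve.extrapolates(Re_O),
        iteration=iteration,
    )


def next_scale(
    op: OperatingPoint,
    predictor: VolumePredictor,
    original: ParticleGeometry,
    tank: WallGeometry | float,
    working_fluid: FluidSpec,
    model_material: MaterialSpec,
    g: float = G_STANDARD,
) -> float:
    """Scale for the next model, aimed at the current operating point."""
    return _solve_scale_for_target(
        op.Re_O, op.C_D_O, predictor.predict, original, tank, working_fluid,
        model_material, g,
    )


def check_convergence(
    op: OperatingPoint,
    points: Sequence[DragDataPoint],
    cubic_U: float,
    linear_U: float,
) -> ConvergenceReport:
    """Apply the three convergence criteria to the current iteration."""
    if len(points) < 3:
        raise InsufficientDataError("convergence check requires >= 3 data points")
    c1 = not op.extrapolated
    c2 = abs(linear_U - cubic_U) / cubic_U
    c3 = min(abs(p.Re - op.Re_O) for p in points) / op.Re_O
    return ConvergenceReport(
        criterion1_no_extrapolation=c1,
        criterion2_spline_variation=c2,
        criterion3_re_gap=c3,
        converged=c1 and c2 <= _CRIT2_MAX and c3 < _CRIT3_MAX,
    )


def reduce_record(
    record: ExperimentRecord,
    original: ParticleGeometry,
    tank: WallGeometry | float,
    working_fluid: FluidSpec,
    model_material: MaterialSpec,
    g: float = G_STANDARD,
) -> DragDataPoint:
    """Turn one sunk model into a wall-corrected (Re, C_D^inf) data point.

    Replicate speeds are aggregated with the +/-5%-of-median filter, Re is
    computed from the mean speed, the apparent drag coefficient from the model
    force balance at measured volume, and the wall correction removed.
    """
    D = tank.tank_diameter if isinstance(tank, WallGeometry) else float(tank)
    agg = aggregate_replicates(record.replicate_speeds)
    L_model = record.S * original.L
    Re = reynolds(L_model, agg.mean_U, working_fluid)
    cd_walls = cd_constraint_at_scale(
        Re, record.S, original, record.volume, model_material, working_fluid, g
    )
    lam = L_model / D
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # Re may exceed the stated validity
        cd_inf = cd_unbounded(cd_walls, lam, Re)
    record.Re = Re
    record.C_D_inf = cd_inf
    return DragDataPoint(Re=Re, C_D=cd_inf, S=record.S, experiment_id=record.experiment_id)


def _round_scale(S: float, used: Sequence[float], direction: float) -> float:
    """Round S to one decimal (as printed) and avoid re-printing an existing model."""
    S_r = max(round(S, 1), 0.1)
    step = 0.1 if direction >= 0 else -0.1
    while any(abs(S_r - u) < 0.05 for u in used):
        S_r = round(S_r + step, 1)
        if S_r < 0.1:
            S_r, step = max(round(S, 1), 0.1) + 0.1, 0.1
    return S_r


def run_estimation(
    original: ParticleGeometry,
    natural_fluid: FluidSpec,
    particle_material: MaterialSpec,
    tank: WallGeometry | float,
    working_fluid: FluidSpec,
    model_material: MaterialSpec,
    experiment_source: ExperimentSource,
    max_iter: int = 10,
    re_bracket: tuple[float, float] = (18.0, 55.0),
    correlation: DragCorrelation = MORRISON,
    g: float = G_STANDARD,
    round_scales: bool = True,
) -> EstimationResult:
    """Run the full iterative estimation loop against an experiment source.

    Returns the final operating point (from the cubic fit), the convergence
    report, and an audit history of every iteration.  If ``max_iter`` models
    are sunk without satisfying the criteria, the best estimate is returned
    flagged as unconverged (with a warning), never silently.
    """
    guess = initial_operating_guess(original, natural_fluid, particle_material,
                                    correlation, g)
    scales = plan_first_scales(
        guess, original, tank, working_fluid, model_material, re_bracket, correlation, g
    )
    if round_scales:
        used: list[float] = []
        rounded: list[float] = []
        for S in scales:
            S_r = _round_scale(S, used, +1)
            used.append(S_r)
            rounded.append(S_r)
        scales = rounded

    records: list[ExperimentRecord] = []
    points: list[DragDataPoint] = []
    predictor = VolumePredictor()
    history: list[IterationState] = []

    def sink(S: float) -> None:
        rec = experiment_source.sink(S, experiment_id=f"model-{len(records) + 1:02d}")
        records.append(rec)
        predictor.add(rec.S, rec.volume)
        points.append(
            reduce_record(rec, original, tank, working_fluid, model_material, g)
        )

    for S in scales[:max_iter]:
        sink(S)

    op_c = guess
    report = None
    while True:
        n = len(records)
        curve_c = fit_drag_spline(points, order="cubic")
        curve_l = fit_drag_spline(points, order="linear")
        op_c = solve_operating_point(
            curve_c, original, natural_fluid, particle_material, g, iteration=n
        )
        op_l = solve_operating_point(
            curve_l, original, natural_fluid, particle_material, g, iteration=n
        )
        report = check_convergence(op_c, points, op_c.U_O, op_l.U_O)
        state = IterationState(
            iteration=n,
            points=list(points),
            curve_cubic=curve_c,
            curve_linear=curve_l,
            op_cubic=op_c,
            op_linear=op_l,
            report=report,
        )
        history.append(state)
        if report.converged or n >= max_iter:
            break
        S_new = next_scale(op_c, predictor, original, tank, working_fluid,
                           model_material, g)
        if round_scales:
            nearest = points[int(np.argmin([abs(p.Re - op_c.Re_O) for p in points]))]
            direction = +1.0 if op_c.Re_O >= nearest.Re else -1.0
            S_new = _round_scale(S_new, [r.S for r in records], direction)
        state.planned_S = S_new
        sink(S_new)

    converged = bool(report.converged)
    if not converged:
        warnings.warn(
            f"estimation did not converge after {len(records)} models; "
            "returning the best (flagged) estimate",
            stacklevel=2,
        )
    return EstimationResult(
        operating_point=op_c,
        report=report,
        history=history,
        records=records,
        points=points,
        converged=converged,
        models_sunk=len(records),
    )
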