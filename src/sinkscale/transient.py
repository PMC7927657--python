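"""Unsteady sinking from rest: time and depth to terminal velocity.

Between release and terminal settling, the particle obeys Newton's second law
with weight, buoyancy and a velocity-dependent drag force::

    M dU/dt = V g (rho_p - rho_f) - 1/2 rho_f U^2 A C_D(Re(U)),   dZ/dt = U

with U(0) = Z(0) = 0.  The drag coefficient diverges as 24/Re at rest, but
the drag *force* is regular there: substituting the Stokes limit gives
F -> 12 mu A U / L as U -> 0 (equal to 3 pi mu d U for a sphere), which is
how the force is evaluated below the correlation's floor.  Added-mass and
Basset history forces are neglected.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

from .core import (
    G_STANDARD,
    FluidSpec,
    InvalidInputError,
    MaterialSpec,
    ParticleGeometry,
    reynolds,
)
from .controller import terminal_state
from .correlations import MORRISON, DragCorrelation

__all__ = ["TransientSolution", "IncompleteSolutionError", "solve_transient",
           "depth_to_fraction"]

_RE_FLOOR = 1e-4  # below this, drag force uses the analytic Stokes limit


class IncompleteSolutionError(RuntimeError):
    """The integration did not reach the requested velocity fraction."""


@dataclass
class TransientSolution:
    """Time histories U(t), Z(t) plus the terminal speed and completeness flag."""

    t: np.ndarray
    U: np.ndarray
    Z: np.ndarray
    U_terminal: float
    complete: bool
    _dense: object  # solve_ivp dense-output interpolant

    def velocity_at(self, t: float) -> float:
        return float(self._dense(t)[0])

    def depth_at(self, t: float) -> float:
        return float(self._dense(t)[1])


def _drag_force(
    U: float, geom: ParticleGeometry, fluid: FluidSpec, drag: DragCorrelation
) -> float:
    if U <= 0:
        return 0.0
    Re = reynolds(geom.L, U, fluid)
    if Re < _RE_FLOOR:
        return 12.0 * fluid.viscosity * geom.A * U / geom.L
    return 0.5 * fluid.density * U**2 * geom.A * drag(Re)


def solve_transient(
    geom: ParticleGeometry,
    particle_material: MaterialSpec,
    fluid: FluidSpec,
    drag: DragCorrelation = MORRISON,
    g: float = G_STANDARD,
    t_end: float | None = None,
    rtol: float = 1e-8,
) -> TransientSolution:
    """Integrate the settling ODEs from rest with an adaptive Runge-Kutta.

    ``t_end`` defaults to 20 momentum-relaxation times (M U_term over the net
    rest force), ample for 99.9% of terminal speed at any Re; if a shorter
    ``t_end`` is given and the fraction is not reached, the solution is
    returned flagged incomplete.
    """
    Re_t, _, U_term = terminal_state(geom, particle_material, fluid, drag, g)
    M = particle_material.density * geom.V
    drho = particle_material.density - fluid.density
    net_rest_force = geom.V * g * drho
    tau = M * U_term / net_rest_force
    if t_end is None:
        t_end = 20.0 * tau
    if not t_end > 0:
        raise InvalidInputError(f"t_end must be positive, got {t_end!r}")

    def rhs(t, y):
        U = y[0]
        dU = (net_rest_force - _drag_force(U, geom, fluid, drag)) / M
        return (dU, U)

    sol = solve_ivp(
        rhs,
        (0.0, t_end),
        (0.0, 0.0),
        method="RK45",
        rtol=rtol,
        atol=U_term * 1e-12,
        dense_output=True,
        max_step=t_end / 50.0,
    )
    complete = bool(sol.y[0, -1] >= 0.999 * U_term)
    return TransientSolution(
        t=sol.t, U=sol.y[0], Z=sol.y[1], U_terminal=U_term, complete=complete,
        _dense=sol.sol,
    )


def depth_to_fraction(sol: TransientSolution, fraction: float = 0.999) -> float:
    """Depth at which the speed first reaches ``fraction`` of terminal, m."""
    if fraction <= 0:
        return 0.0
    if fraction >= 1:
        raise InvalidInputError("fraction must be in (0, 1)")
    target = fraction * sol.U_terminal
    if sol.U[-1] < target:
        raise IncompleteSolutionError(
            f"solution reached {sol.U[-1] / sol.U_terminal:.4%} of terminal speed; "
            f"requested {fraction:.4%} — integrate further"
        )
    # U(t) is monotone for monotone drag; bracket on the stored grid
    idx = int(np.searchsorted(sol.U, target))
    t_lo = sol.t[max(idx - 1, 0)]
    t_hi = sol.t[min(idx, len(sol.t) - 1)]
    if t_lo == t_hi:
        return sol.depth_at(t_hi)
    t_star = brentq(lambda t: sol.velocity_at(t) - target, t_lo, t_hi, xtol=1e-15)
    return sol.depth_at(t_star)
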