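"""Domain types, dimensionless numbers and the terminal force balance.

A rigid particle sinking steadily in a quiescent Newtonian fluid satisfies a
three-way balance of weight, buoyancy and drag.  Eliminating the unknown speed
``U`` through the Reynolds number turns that balance into a one-parameter
constraint between the drag coefficient and ``Re``::

    C_D^F(Re) = 2 g V (rho_p - rho_f) L^2 rho_f / (A mu^2 Re^2)

which scales exactly as ``Re^-2`` and equals ``2 Ar / Re^2`` with the
Archimedes number built on the hybrid length scale ``L_Ar^3 = V L^2 / A``.
Everything downstream (experiment planning, spline intersection, the virtual
tank) is an application of this constraint with the appropriate fluid, material
and geometric scale substituted.

All quantities are SI internally: lengths in m, areas in m^2, volumes in m^3,
densities in kg m^-3, viscosities in Pa s, speeds in m s^-1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = [
    "G_STANDARD",
    "InvalidInputError",
    "BuoyantParticleError",
    "InsufficientDataError",
    "OutOfRangeError",
    "NoIntersectionError",
    "FluidSpec",
    "MaterialSpec",
    "ParticleGeometry",
    "SinkingState",
    "ExperimentRecord",
    "reynolds",
    "speed_from_reynolds",
    "archimedes",
    "cd_force_balance",
    "cd_constraint_at_scale",
]

#: Standard gravity, m s^-2.  Configurable everywhere it is used.
G_STANDARD = 9.80665


class InvalidInputError(ValueError):
    """A physically meaningless argument (non-positive length, speed, ...)."""


class BuoyantParticleError(ValueError):
    """Particle not denser than the fluid: no terminal sinking solution."""


class InsufficientDataError(ValueError):
    """Too few data points for the requested operation."""


class OutOfRangeError(ValueError):
    """Argument outside a correlation's or correction's validity range."""


class NoIntersectionError(RuntimeError):
    """Force-balance and empirical drag curves do not cross in the bracket."""


def _require_positive(**kwargs: float) -> None:
    for name, value in kwargs.items():
        if not value > 0:
            raise InvalidInputError(f"{name} must be positive, got {value!r}")


@dataclass(frozen=True)
class FluidSpec:
    """A Newtonian fluid: density (kg m^-3) and dynamic viscosity (Pa s)."""

    density: float
    viscosity: float
    name: str = ""

    def __post_init__(self) -> None:
        _require_positive(density=self.density, viscosity=self.viscosity)


@dataclass(frozen=True)
class MaterialSpec:
    """A solid particle/model material of given density (kg m^-3)."""

    density: float
    name: str = ""

    def __post_init__(self) -> None:
        _require_positive(density=self.density)


@dataclass(frozen=True)
class ParticleGeometry:
    """Size descriptors of a sinking particle.

    Parameters
    ----------
    L : float
        Maximum extent parallel to the sinking direction, m.
    A : float
        Projected frontal area perpendicular to the sinking direction, m^2.
    V : float
        Solid material volume (excluding fluid-filled cavities), m^3.
    shape_label : str
        Free-text shape descriptor (species name, "sphere", ...).
    """

    L: float
    A: float
    V: float
    shape_label: str = ""

    def __post_init__(self) -> None:
        _require_positive(L=self.L, A=self.A, V=self.V)
        if self.V > self.A * self.L * (1 + 1e-12):
            raise InvalidInputError(
                f"V={self.V} exceeds the bounding prism A*L={self.A * self.L}"
            )

    @classmethod
    def sphere(cls, diameter: float, shape_label: str = "sphere") -> "ParticleGeometry":
        """Solid sphere of the given diameter."""
        import math

        _require_positive(diameter=diameter)
        r = diameter / 2.0
        return cls(
            L=diameter,
            A=math.pi * r**2,
            V=4.0 / 3.0 * math.pi * r**3,
            shape_label=shape_label,
        )

    def scaled(self, S: float) -> "ParticleGeometry":
        """Geometrically similar copy at scale factor ``S`` (nominal volume)."""
        _require_positive(S=S)
        return ParticleGeometry(
            L=S * self.L, A=S**2 * self.A, V=S**3 * self.V, shape_label=self.shape_label
        )


@dataclass(frozen=True)
class SinkingState:
    """A mutually consistent (Re, C_D, U) triple for one particle/fluid pair."""

    Re: float
    C_D: float
    U: float

    def __post_init__(self) -> None:
        _require_positive(Re=self.Re, C_D=self.C_D, U=self.U)


@dataclass
class ExperimentRecord:
    """One sunk model: its scale, measured volume/mass and replicate speeds.

    ``Re`` and ``C_D_inf`` are derived later from the replicate speeds via the
    force balance and wall correction; they stay ``None`` until reduced.
    """

    experiment_id: str
    S: float
    volume: float  # measured solid volume, m^3 (mass / model density)
    mass: float  # kg
    replicate_speeds: list[float] = field(default_factory=list)
    Re: float | None = None
    C_D_inf: float | None = None


def reynolds(L: float, U: float, fluid: FluidSpec) -> float:
    """Reynolds number ``Re = L U rho_fluid / mu``."""
    _require_positive(L=L, U=U)
    return L * U * fluid.density / fluid.viscosity


def speed_from_reynolds(Re: float, L: float, fluid: FluidSpec) -> float:
    """Invert the Reynolds number for the speed: ``U = Re mu / (L rho_fluid)``."""
    _require_positive(Re=Re, L=L)
    return Re * fluid.viscosity / (L * fluid.density)


def _delta_rho(particle_material: MaterialSpec, fluid: FluidSpec) -> float:
    d = particle_material.density - fluid.density
    if d <= 0:
        raise BuoyantParticleError(
            f"particle density {particle_material.density} kg/m^3 does not exceed "
            f"fluid density {fluid.density} kg/m^3: the particle will not sink"
        )
    return d


def archimedes(
    geom: ParticleGeometry,
    particle_material: MaterialSpec,
    fluid: FluidSpec,
    g: float = G_STANDARD,
) -> float:
    """Archimedes number ``Ar = g L_Ar^3 rho_f (rho_p - rho_f) / mu^2``.

    The cubed length scale is the hybrid ``L_Ar^3 = V L^2 / A`` that makes the
    force-balance drag coefficient collapse to ``2 Ar / Re^2``.
    """
    _require_positive(g=g)
    drho = _delta_rho(particle_material, fluid)
    l_ar3 = geom.V * geom.L**2 / geom.A
    return g * l_ar3 * fluid.density * drho / fluid.viscosity**2


def cd_force_balance(
    Re: float,
    geom: ParticleGeometry,
    particle_material: MaterialSpec,
    fluid: FluidSpec,
    g: float = G_STANDARD,
) -> float:
    """Drag coefficient required by the terminal force balance at a given Re.

    ``C_D^F(Re) = 2 g V (rho_p - rho_f) L^2 rho_f / (A mu^2 Re^2)``; strictly
    decreasing, scaling exactly as ``Re^-2``.
    """
    _require_positive(Re=Re)
    drho = _delta_rho(particle_material, fluid)
    return (
        2.0
        * g
        * geom.V
        * drho
        * geom.L**2
        * fluid.density
        / (geom.A * fluid.viscosity**2 * Re**2)
    )


def cd_constraint_at_scale(
    Re: float,
    S: float,
    original: ParticleGeometry,
    V_model: float,
    model_material: MaterialSpec,
    working_fluid: FluidSpec,
    g: float = G_STANDARD,
) -> float:
    """Force-balance constraint for a scaled model, in original-test parameters.

    For a geometrically similar model, ``L = S L^O`` and ``A = S^2 A^O``, so the
    explicit powers of ``S`` cancel and only the *measured* model volume carries
    the scale::

        C_D^F = 2 g V_model (rho_model - rho_fluid) (L^O)^2 rho_fluid
                / (A^O mu^2 Re^2)

    ``V_model`` is the measured solid volume of the printed model (mass over
    resin density), not the nominal ``S^3 V^O``.
    """
    _require_positive(Re=Re, S=S, V_model=V_model)
    drho = _delta_rho(model_material, working_fluid)
    return (
        2.0
        * g
        * V_model
        * drho
        * original.L**2
        * working_fluid.density
        / (original.A * working_fluid.viscosity**2 * Re**2)
    )
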