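"""Wall-effect correction for a particle settling on the axis of a cylinder.

The container walls act as an extra source of drag, so the drag coefficient
measured in a tank exceeds the unbounded-domain value the ocean application
needs.  For small particle-to-tank diameter ratio ``lambda = d/D`` and Re up to
about 50, the correction is the classical axial-cylinder series (Bohlin/Faxén
form, as experimentally confirmed for this regime by Fidleris & Whitmore):

    K(lambda) = 1 / (1 - 2.10444 l + 2.08877 l^3 - 0.94813 l^5
                     - 1.372 l^6 + 3.87 l^8 - 4.19 l^10)

with the walls enhancing the drag at fixed Re by the factor K, i.e.
``C_D^walls = K * C_D^inf``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

from .core import InvalidInputError, OutOfRangeError, _require_positive

__all__ = ["WallGeometry", "wall_factor_K", "cd_unbounded", "cd_bounded", "RE_VALIDITY"]

#: Approximate upper Re of validity of the correction; above this a warning is
#: emitted and the correction applied unchanged.
RE_VALIDITY = 50.0

_LAMBDA_MAX = 0.1


@dataclass(frozen=True)
class WallGeometry:
    """Particle diameter (taken as L), tank diameter, and their ratio lambda."""

    particle_diameter: float
    tank_diameter: float

    def __post_init__(self) -> None:
        _require_positive(
            particle_diameter=self.particle_diameter, tank_diameter=self.tank_diameter
        )
        if not self.ratio < 0.5:
            raise InvalidInputError(
                f"lambda = d/D = {self.ratio:.3f} must be < 0.5 for a sensible tank"
            )

    @property
    def ratio(self) -> float:
        """lambda = d / D."""
        return self.particle_diameter / self.tank_diameter


def wall_factor_K(lam: float) -> float:
    """Wall correction factor K(lambda); K(0)=1, strictly increasing.

    Valid for 0 <= lambda <= 0.1; larger ratios need different corrections
    (the series truncation error grows and stronger-confinement formulas
    apply), so they raise instead of silently extrapolating.
    """
    if lam < 0 or lam > _LAMBDA_MAX:
        raise OutOfRangeError(
            f"lambda={lam!r} outside [0, {_LAMBDA_MAX}]; for stronger confinement "
            "use a dedicated high-lambda correction (e.g. Haberman & Sayre tables)"
        )
    f = (
        1.0
        - 2.10444 * lam
        + 2.08877 * lam**3
        - 0.94813 * lam**5
        - 1.372 * lam**6
        + 3.87 * lam**8
        - 4.19 * lam**10
    )
    return 1.0 / f


def _check_re(Re: float | None) -> None:
    if Re is not None and Re > RE_VALIDITY:
        warnings.warn(
            f"wall correction applied at Re={Re:.3g} > {RE_VALIDITY:g}, beyond its "
            "stated validity; treat the corrected value with caution",
            stacklevel=3,
        )


def cd_unbounded(C_D_walls: float, lam: float, Re: float | None = None) -> float:
    """Convert an apparent (in-tank) drag coefficient to the unbounded value.

    ``C_D^inf = C_D^walls / K(lambda)`` at matched Re; always <= the input and
    equal to it at lambda = 0.
    """
    if C_D_walls <= 0:
        raise InvalidInputError(f"C_D_walls must be positive, got {C_D_walls!r}")
    _check_re(Re)
    return C_D_walls / wall_factor_K(lam)


def cd_bounded(C_D_inf: float, lam: float, Re: float | None = None) -> float:
    """Exact inverse of :func:`cd_unbounded`: the in-tank apparent C_D."""
    if C_D_inf <= 0:
        raise InvalidInputError(f"C_D_inf must be positive, got {C_D_inf!r}")
    _check_re(Re)
    return C_D_inf * wall_factor_K(lam)
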