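"""Reference drag-coefficient curves for spheres, plus perturbed variants.

The sphere curve is Morrison's four-term correlation, valid for 0 < Re < 1e6
and tending to the Stokes law 24/Re as Re -> 0.  Perturbed copies (a constant
multiplier and/or a small power-law tilt) serve as ground truths for
non-spherical virtual particles in the closed-loop tests.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from .core import OutOfRangeError

__all__ = ["DragCorrelation", "MORRISON", "morrison_cd", "perturbed_cd"]

# Below this Re the extra Morrison terms are < 1e-6 of 24/Re and the
# (Re/263000)^-7.94 term overflows float64; switch to the analytic Stokes law.
_STOKES_SWITCH = 1e-4


@dataclass(frozen=True)
class DragCorrelation:
    """A named C_D(Re) curve with a validity interval (open at both ends)."""

    name: str
    re_min: float
    re_max: float
    evaluator: Callable[[np.ndarray], np.ndarray]

    def __call__(self, Re):
        Re_arr = np.asarray(Re, dtype=float)
        if np.any(Re_arr <= self.re_min) or np.any(Re_arr >= self.re_max):
            raise OutOfRangeError(
                f"Re={Re!r} outside validity range ({self.re_min}, {self.re_max}) "
                f"of correlation {self.name!r}"
            )
        out = self.evaluator(Re_arr)
        return float(out) if np.isscalar(Re) or Re_arr.ndim == 0 else out


def _morrison_raw(Re: np.ndarray) -> np.ndarray:
    Re = np.asarray(Re, dtype=float)
    stokes = np.divide(24.0, Re, out=np.full_like(Re, np.inf), where=Re > 0)
    with np.errstate(over="ignore"):
        full = (
            stokes
            + 2.6 * (Re / 5.0) / (1.0 + (Re / 5.0) ** 1.52)
            + 0.411 * (Re / 263000.0) ** -7.94 / (1.0 + (Re / 263000.0) ** -8.00)
            + 0.25 * (Re / 1e6) / (1.0 + Re / 1e6)
        )
    return np.where(Re < _STOKES_SWITCH, stokes, full)


MORRISON = DragCorrelation("morrison", 0.0, 1e6, _morrison_raw)


def morrison_cd(Re):
    """Sphere drag coefficient from Morrison's empirical correlation.

    Valid for 0 < Re < 1e6; approaches 24/Re as Re -> 0 and ~0.48 at Re=1000.
    """
    return MORRISON(Re)


def perturbed_cd(
    base: DragCorrelation,
    factor: float = 1.0,
    exponent_shift: float = 0.0,
    name: str | None = None,
) -> DragCorrelation:
    """Curve ``C_D(Re) = factor * base(Re) * Re^exponent_shift``.

    Positivity and strict monotone decrease are validated on a log-spaced
    sample of [1, 100] at construction; a perturbation breaking either raises.
    """
    if not factor > 0:
        raise ValueError(f"factor must be positive, got {factor!r}")

    def _eval(Re: np.ndarray) -> np.ndarray:
        return factor * base.evaluator(Re) * np.asarray(Re, dtype=float) ** exponent_shift

    grid = np.logspace(0.0, 2.0, 200)
    grid = grid[(grid > base.re_min) & (grid < base.re_max)]
    vals = _eval(grid)
    if np.any(vals <= 0):
        raise ValueError("perturbation breaks positivity on Re in [1, 100]")
    if np.any(np.diff(vals) >= 0):
        raise ValueError("perturbation breaks strict monotone decrease on Re in [1, 100]")
    label = name or f"{base.name}*{factor:g}*Re^{exponent_shift:g}"
    return DragCorrelation(label, base.re_min, base.re_max, _eval)
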