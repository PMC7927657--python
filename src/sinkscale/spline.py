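"""Empirical drag-curve inference: shape-constrained spline fits to (Re, C_D).

Experimental data points (wall-corrected drag coefficients at measured
Reynolds numbers) are fitted in (log10 Re, log10 C_D) space, where sphere-like
drag curves are close to power laws.  The fit is a B-spline least-squares
problem with two shape constraints enforced on a dense grid across the data
range: monotone decreasing (y' <= 0) and concave-up (y'' >= 0).  Because a
convex decreasing function of log Re maps through exponentiation and the
concave log to a convex decreasing C_D(Re), the constraints carry over to
linear space.

Two variants are provided, mirroring the cubic-versus-linear convergence
check of the estimation loop:

* ``cubic``  — degree-3 B-spline with three knots (both ends plus one interior
  knot whose position is chosen by a small residual scan), lightly regularized
  so the under-determined 3-point case has a unique smooth solution;
* ``linear`` — degree-1 spline with knots at the data points (interpolating
  when the data are themselves monotone).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import BSpline
from scipy.optimize import minimize

from .core import InsufficientDataError, InvalidInputError

__all__ = ["DragDataPoint", "DragCurve", "fit_drag_spline", "evaluate"]

_N_GRID = 240  # constraint grid density across the data range
_SMOOTH = 1e-8  # relative roughness penalty weight


class FitConstraintWarning(UserWarning):
    """Data not representable under the shape constraints; best feasible fit."""


@dataclass(frozen=True)
class DragDataPoint:
    """One wall-corrected experimental point on the drag curve."""

    Re: float
    C_D: float
    S: float = float("nan")  # scale-factor provenance
    experiment_id: str = ""

    def __post_init__(self) -> None:
        if not self.Re > 0 or not self.C_D > 0:
            raise InvalidInputError(f"Re and C_D must be positive: {self}")


@dataclass
class DragCurve:
    """A fitted empirical C_D^E(Re) curve in log10-log10 space.

    Inside ``data_range`` the B-spline is evaluated; outside, the curve is
    continued linearly in fit space from the boundary value and slope, and
    such evaluations are reported as extrapolated.
    """

    t: np.ndarray  # knot vector (log10 Re)
    c: np.ndarray  # B-spline coefficients (log10 C_D)
    k: int  # spline degree
    data_range: tuple[float, float]  # (Re_min, Re_max) of supporting data
    order: str  # "cubic" | "linear"
    n_points: int
    fit_space: str = "log10"
    residual_rms: float = 0.0  # RMS of log10 residuals at the data
    _spl: BSpline = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.c = np.asarray(self.c, dtype=float)
        self._spl = BSpline(self.t, self.c, self.k, extrapolate=False)

    # -- evaluation ------------------------------------------------------
    def _y(self, x):
        """log10 C_D at x = log10 Re, with linear continuation outside."""
        x = np.asarray(x, dtype=float)
        lo, hi = np.log10(self.data_range)
        d1 = self._spl.derivative()
        y = np.empty_like(x)
        inside = (x >= lo) & (x <= hi)
        y[inside] = self._spl(x[inside])
        below = x < lo
        above = x > hi
        if below.any():
            y[below] = self._spl(lo) + d1(lo) * (x[below] - lo)
        if above.any():
            y[above] = self._spl(hi) + d1(hi) * (x[above] - hi)
        return y

    def evaluate(self, Re):
        """C_D^E at Re (scalar or array); extrapolates linearly in fit space."""
        scalar = np.isscalar(Re)
        Re_arr = np.atleast_1d(np.asarray(Re, dtype=float))
        if np.any(Re_arr <= 0):
            raise InvalidInputError("Re must be positive")
        out = 10.0 ** self._y(np.log10(Re_arr))
        return float(out[0]) if scalar else out

    __call__ = evaluate

    def extrapolates(self, Re) -> bool:
        """True if any requested Re lies outside the supporting data range."""
        Re_arr = np.atleast_1d(np.asarray(Re, dtype=float))
        lo, hi = self.data_range
        return bool(np.any((Re_arr < lo) | (Re_arr > hi)))

    @property
    def knots_re(self) -> np.ndarray:
        """Distinct knot positions on the Re axis."""
        return 10.0 ** np.unique(self.t)

    # -- serialization ---------------------------------------------------
    def to_json(self) -> str:
        return json.dumps(
            {
                "t": self.t.tolist(),
                "c": self.c.tolist(),
                "k": self.k,
                "data_range": list(self.data_range),
                "order": self.order,
                "n_points": self.n_points,
                "fit_space": self.fit_space,
                "residual_rms": self.residual_rms,
            }
        )

    @classmethod
    def from_json(cls, payload: str) -> "DragCurve":
        d = json.loads(payload)
        return cls(
            t=np.asarray(d["t"]),
            c=np.asarray(d["c"]),
            k=d["k"],
            data_range=tuple(d["data_range"]),
            order=d["order"],
            n_points=d["n_points"],
            fit_space=d["fit_space"],
            residual_rms=d["residual_rms"],
        )


def _design(x: np.ndarray, t: np.ndarray, k: int, nu: int = 0) -> np.ndarray:
    """Dense design matrix of the nu-th derivative of the B-spline basis."""
    n = len(t) - k - 1
    B = np.empty((len(x), n))
    for j in range(n):
        cj = np.zeros(n)
        cj[j] = 1.0
        spl = BSpline(t, cj, k)
        B[:, j] = spl(x) if nu == 0 else spl.derivative(nu)(x)
    return B


def _constrained_lsq(
    x: np.ndarray, y: np.ndarray, t: np.ndarray, k: int
) -> tuple[np.ndarray, float]:
    """Least-squares B-spline coefficients under y'<=0, y''>=0 on a grid."""
    B = _design(x, t, k, 0)
    grid = np.linspace(t[k], t[-k - 1], _N_GRID)
    D1 = _design(grid, t, k, 1)
    constraints = [{"type": "ineq", "fun": lambda c: -D1 @ c, "jac": lambda c: -D1}]
    if k >= 2:
        D2 = _design(grid, t, k, 2)
        constraints.append({"type": "ineq", "fun": lambda c: D2 @ c, "jac": lambda c: D2})
        # roughness penalty resolves the under-determined few-point case
        P = _SMOOTH * (D2.T @ D2) / _N_GRID
    else:
        P = _SMOOTH * np.eye(B.shape[1])

    H = B.T @ B + P
    b = B.T @ y

    def obj(c):
        r = B @ c - y
        return 0.5 * float(r @ r) + 0.5 * float(c @ P @ c)

    def jac(c):
        return H @ c - b

    c0 = np.linalg.solve(H + 1e-10 * np.trace(H) * np.eye(len(b)), b)
    res = minimize(
        obj,
        c0,
        jac=jac,
        method="SLSQP",
        constraints=constraints,
        options={"maxiter": 400, "ftol": 1e-14},
    )
    c = res.x
    rms = float(np.sqrt(np.mean((B @ c - y) ** 2)))
    return c, rms


def fit_drag_spline(points: list[DragDataPoint], order: str = "cubic") -> DragCurve:
    """Fit the empirical drag curve C_D^E(Re) to wall-corrected data points.

    Parameters
    ----------
    points : list of DragDataPoint
        At least three points with distinct Re.
    order : {"cubic", "linear"}
        Spline degree variant (see module docstring).

    Raises
    ------
    InsufficientDataError
        Fewer than three points.
    InvalidInputError
        Duplicate Re values or unknown order.
    """
    if order not in ("cubic", "linear"):
        raise InvalidInputError(f"order must be 'cubic' or 'linear', got {order!r}")
    if len(points) < 3:
        raise InsufficientDataError(
            f"need >= 3 drag data points to fit a curve, got {len(points)}"
        )
    Re = np.array([p.Re for p in points], dtype=float)
    Cd = np.array([p.C_D for p in points], dtype=float)
    idx = np.argsort(Re)
    Re, Cd = Re[idx], Cd[idx]
    if np.any(np.diff(Re) <= 0):
        raise InvalidInputError("drag data points must have distinct Re values")

    x = np.log10(Re)
    y = np.log10(Cd)
    lo, hi = x[0], x[-1]

    if order == "linear":
        k = 1
        t = np.r_[lo, x, hi]
        if np.all(np.diff(y) < 0):
            c, rms = y.copy(), 0.0  # interpolating and already feasible
        else:
            warnings.warn(
                "drag data are not monotone decreasing; returning the best "
                "feasible constrained fit",
                FitConstraintWarning,
                stacklevel=2,
            )
            c, rms = _constrained_lsq(x, y, t, k)
    else:
        k = 3
        # "three optimally spaced knots": both ends plus one interior knot,
        # its position picked by a small residual scan
        best = None
        for frac in (0.3, 0.4, 0.5, 0.6, 0.7):
            mid = lo + frac * (hi - lo)
            t = np.r_[[lo] * (k + 1), mid, [hi] * (k + 1)]
            c, rms = _constrained_lsq(x, y, t, k)
            if best is None or rms < best[2]:
                best = (t, c, rms)
        t, c, rms = best
        if rms > 0.02 and np.any(np.diff(y) >= 0):
            warnings.warn(
                "drag data are not monotone decreasing beyond noise; returning "
                "the best feasible constrained fit",
                FitConstraintWarning,
                stacklevel=2,
            )

    return DragCurve(
        t=t,
        c=c,
        k=k,
        data_range=(float(Re[0]), float(Re[-1])),
        order=order,
        n_points=len(points),
        residual_rms=rms,
    )


def evaluate(curve: DragCurve, Re, with_flag: bool = False):
    """Evaluate a fitted curve at Re; optionally also return the extrapolation flag."""
    value = curve.evaluate(Re)
    if with_flag:
        return value, curve.extrapolates(Re)
    return value
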