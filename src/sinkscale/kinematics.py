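"""Settling speed from two-camera centroid tracks, and replicate aggregation.

Each camera sees one horizontal coordinate plus the vertical coordinate of the
sinking model.  Within a central depth window (avoiding the release transient
and bottom end effects), average velocity components are taken as the
least-squares slope of position against timestamp — robust to the variable
frame rate of consumer webcams and identical to a simple displacement/time
ratio for uniform motion.  Per camera the resultant speed is
sqrt(U_horiz^2 + U_z^2); the two cameras are averaged.

Replicate drops of the same model are aggregated by discarding speeds beyond
+/-5% of the median of all replicates and averaging the survivors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import InsufficientDataError, InvalidInputError

__all__ = ["CentroidTrack", "ReplicateSet", "track_velocity", "aggregate_replicates"]

#: Half-width of the replicate filter around the median (inclusive boundary).
MEDIAN_FILTER_FRACTION = 0.05


@dataclass
class CentroidTrack:
    """Timestamped centroid positions from one camera.

    ``vert`` is depth below the release point (m, increasing downward);
    ``horiz`` is the single horizontal coordinate this camera resolves.
    ``depth_window`` bounds the vertical range used for the velocity fit.
    """

    camera_id: int
    timestamps: np.ndarray
    horiz: np.ndarray
    vert: np.ndarray
    depth_window: tuple[float, float]

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.horiz = np.asarray(self.horiz, dtype=float)
        self.vert = np.asarray(self.vert, dtype=float)
        if not (len(self.timestamps) == len(self.horiz) == len(self.vert)):
            raise InvalidInputError("track arrays must have equal length")
        if np.any(np.diff(self.timestamps) <= 0):
            raise InvalidInputError("timestamps must be strictly increasing")
        lo, hi = self.depth_window
        if not lo < hi:
            raise InvalidInputError(f"bad depth window {self.depth_window!r}")


def _component_speeds(track: CentroidTrack) -> tuple[float, float]:
    """Least-squares (horizontal, vertical) velocity components in the window."""
    lo, hi = track.depth_window
    mask = (track.vert >= lo) & (track.vert <= hi)
    if mask.sum() < 2:
        raise InsufficientDataError(
            f"camera {track.camera_id}: fewer than 2 samples inside the depth "
            f"window [{lo}, {hi}]"
        )
    t = track.timestamps[mask]
    t = t - t.mean()  # center for conditioning
    uh = float(np.polyfit(t, track.horiz[mask], 1)[0])
    uz = float(np.polyfit(t, track.vert[mask], 1)[0])
    return uh, uz


def track_velocity(track1: CentroidTrack, track2: CentroidTrack) -> float:
    """Settling speed from a two-camera track pair.

    Per camera, the resultant of the horizontal and vertical least-squares
    velocity components; the two resultants are averaged.
    """
    u1h, u1z = _component_speeds(track1)
    u2h, u2z = _component_speeds(track2)
    r1 = float(np.hypot(u1h, u1z))
    r2 = float(np.hypot(u2h, u2z))
    return 0.5 * (r1 + r2)


@dataclass
class ReplicateSet:
    """Replicate speeds, the kept mask after the median filter, and their mean."""

    speeds: np.ndarray
    kept: np.ndarray
    mean_U: float


def aggregate_replicates(speeds) -> ReplicateSet:
    """Mean settling speed after discarding replicates beyond +/-5% of the median.

    The median is computed over all raw replicates; speeds within (inclusive)
    5% of it are kept, so the median element itself always survives.
    """
    u = np.asarray(list(speeds), dtype=float)
    if u.size == 0:
        raise InsufficientDataError("no replicate speeds")
    if np.any(u <= 0):
        raise InvalidInputError("replicate speeds must be positive")
    med = float(np.median(u))
    # inclusive boundary; the epsilon keeps exact +/-5% values from being
    # dropped by floating-point rounding
    kept = np.abs(u - med) <= MEDIAN_FILTER_FRACTION * med * (1.0 + 1e-9)
    return ReplicateSet(speeds=u, kept=kept, mean_U=float(u[kept].mean()))
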