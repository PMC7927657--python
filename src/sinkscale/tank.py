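"""Virtual settling tank: synthetic experiments for the closed estimation loop.

A virtual particle carries its true geometry, a ground-truth drag curve and a
material.  "Sinking" a scaled model solves the terminal force balance in the
working fluid with the wall-enhanced drag, then emits replicate speeds with
multiplicative lognormal noise and a measured mass reflecting the
printing-volume bias (small models carry proportionally more excess resin:
``V_model = S^3 V^O (1 + c / S)``).  Everything is deterministic under a seed,
with independent substreams per model scale.

Straight-line two-camera tracks can also be generated so the kinematics
pipeline can be exercised end to end.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import (
    G_STANDARD,
    ExperimentRecord,
    FluidSpec,
    InvalidInputError,
    MaterialSpec,
    ParticleGeometry,
    cd_constraint_at_scale,
    speed_from_reynolds,
)
from .controller import _log_bracket_root
from .correlations import DragCorrelation
from .kinematics import CentroidTrack
from .walls import WallGeometry, wall_factor_K

__all__ = ["VirtualParticleTruth", "NoiseModel", "VirtualTank", "sink_model",
           "make_tracks", "true_model_volume"]


@dataclass(frozen=True)
class VirtualParticleTruth:
    """Ground truth for a virtual particle: geometry, drag curve, material."""

    geometry: ParticleGeometry
    drag: DragCorrelation
    material: MaterialSpec  # the original (life-size) particle material


@dataclass(frozen=True)
class NoiseModel:
    """Measurement/fabrication imperfections of the virtual experiment.

    velocity_cv : coefficient of variation of replicate speeds (lognormal,
        mean-one multiplicative noise).
    volume_bias_c : printing bias coefficient; measured model volume is
        ``S^3 V^O (1 + c / S)`` so smaller models are proportionally heavier.
    replicates : drops per model.
    seed : base seed; each model scale gets an independent substream.
    """

    velocity_cv: float = 0.01
    volume_bias_c: float = 0.3
    replicates: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.velocity_cv < 0 or self.volume_bias_c < 0:
            raise InvalidInputError("noise parameters must be non-negative")
        if self.replicates < 1:
            raise InvalidInputError("need at least one replicate")


def true_model_volume(S: float, V_original: float, bias_c: float) -> float:
    """Actual printed volume under the bias rule: S^3 V^O (1 + c/S)."""
    return S**3 * V_original * (1.0 + bias_c / S)


def _rng_for(noise: NoiseModel, S: float) -> np.random.Generator:
    return np.random.default_rng((int(noise.seed), int(round(S * 1e6))))


def sink_model(
    truth: VirtualParticleTruth,
    S: float,
    tank: WallGeometry | float,
    working_fluid: FluidSpec,
    model_material: MaterialSpec,
    noise: NoiseModel,
    g: float = G_STANDARD,
    experiment_id: str = "",
) -> ExperimentRecord:
    """Simulate sinking one scaled model and return its measured record.

    The terminal Reynolds number solves the model force balance against the
    wall-enhanced ground-truth drag, ``C_D^F_tank(Re) = K(lambda) C_D^truth(Re)``;
    replicate speeds are the true terminal speed times lognormal noise.
    """
    if not S > 0:
        raise InvalidInputError(f"S must be positive, got {S!r}")
    geom = truth.geometry
    D = tank.tank_diameter if isinstance(tank, WallGeometry) else float(tank)
    lam = S * geom.L / D
    K = wall_factor_K(lam)
    V_model = true_model_volume(S, geom.V, noise.volume_bias_c)
    mass = V_model * model_material.density

    def f(Re: float) -> float:
        lhs = cd_constraint_at_scale(Re, S, geom, V_model, model_material,
                                     working_fluid, g)
        return np.log(lhs) - np.log(K * truth.drag(Re))

    lo = max(1e-6, truth.drag.re_min * (1 + 1e-9) if truth.drag.re_min > 0 else 1e-6)
    hi = min(1e6, truth.drag.re_max * (1 - 1e-9))
    Re = _log_bracket_root(f, lo, hi)
    U = speed_from_reynolds(Re, S * geom.L, working_fluid)

    if noise.velocity_cv > 0:
        sigma = float(np.sqrt(np.log1p(noise.velocity_cv**2)))
        z = _rng_for(noise, S).standard_normal(noise.replicates)
        speeds = (U * np.exp(sigma * z - 0.5 * sigma**2)).tolist()
    else:
        speeds = [U] * noise.replicates

    return ExperimentRecord(
        experiment_id=experiment_id,
        S=float(S),
        volume=V_model,
        mass=mass,
        replicate_speeds=speeds,
    )


@dataclass
class VirtualTank:
    """An experiment source wrapping :func:`sink_model` for the estimation loop."""

    truth: VirtualParticleTruth
    tank: WallGeometry | float
    working_fluid: FluidSpec
    model_material: MaterialSpec
    noise: NoiseModel
    g: float = G_STANDARD

    def sink(self, S: float, experiment_id: str = "") -> ExperimentRecord:
        return sink_model(
            self.truth, S, self.tank, self.working_fluid, self.model_material,
            self.noise, self.g, experiment_id,
        )


def make_tracks(
    record: ExperimentRecord,
    replicate: int = 0,
    frame_rate: float = 30.0,
    timestamp_jitter: float = 0.0,
    depth_window: tuple[float, float] = (0.19, 0.99),
    total_depth: float = 1.18,
    drift: tuple[float, float] = (0.0, 0.0),
    seed: int = 0,
) -> tuple[CentroidTrack, CentroidTrack]:
    """Straight-line two-camera tracks reproducing one replicate's speed.

    The model descends at constant velocity with optional horizontal drift
    components (camera 1 resolves x, camera 2 resolves y).  ``timestamp_jitter``
    is the standard deviation of the recorded-timestamp error as a fraction of
    the frame interval: positions are sampled at the true times but stamped
    with the jittered ones, as a variable-frame-rate camera would.
    """
    speed = record.replicate_speeds[replicate]
    ux, uy = drift
    uz = float(np.sqrt(max(speed**2 - ux**2 - uy**2, 0.0)))
    if uz <= 0:
        raise InvalidInputError("drift exceeds the replicate speed")
    duration = total_depth / uz
    n = max(int(duration * frame_rate), 8)
    t_true = np.arange(n) / frame_rate
    rng = np.random.default_rng((int(seed), replicate))
    if timestamp_jitter > 0:
        stamps = t_true + timestamp_jitter / frame_rate * rng.standard_normal(n)
        stamps = np.sort(stamps)
        stamps += np.arange(n) * 1e-12  # guarantee strict increase
    else:
        stamps = t_true
    z = uz * t_true
    track1 = CentroidTrack(1, stamps, ux * t_true, z, depth_window)
    track2 = CentroidTrack(2, stamps.copy(), uy * t_true, z.copy(), depth_window)
    return track1, track2
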