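"""CSV/JSON exchange formats for experiments, tracks and results.

Experiments CSV: one row per sunk model with columns ``experiment_id``, ``S``,
``mass_g`` and either replicate speed columns ``speed_1..speed_n`` (m/s) or a
``tracks`` column listing per-replicate two-camera track CSV pairs as
``cam1.csv:cam2.csv`` separated by ``;``.  Track CSV columns:
``experiment_id, camera_id, timestamp_s, horiz_m, vert_m``.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .core import ExperimentRecord, InvalidInputError, MaterialSpec
from .kinematics import CentroidTrack, track_velocity

__all__ = ["read_experiments", "write_experiments", "write_tracks", "read_track",
           "result_to_json"]


def write_tracks(path, experiment_id: str, track: CentroidTrack) -> None:
    df = pd.DataFrame(
        {
            "experiment_id": experiment_id,
            "camera_id": track.camera_id,
            "timestamp_s": track.timestamps,
            "horiz_m": track.horiz,
            "vert_m": track.vert,
        }
    )
    df.to_csv(path, index=False)


def read_track(path, depth_window: tuple[float, float]) -> CentroidTrack:
    df = pd.read_csv(path)
    return CentroidTrack(
        camera_id=int(df["camera_id"].iloc[0]),
        timestamps=df["timestamp_s"].to_numpy(float),
        horiz=df["horiz_m"].to_numpy(float),
        vert=df["vert_m"].to_numpy(float),
        depth_window=depth_window,
    )


def write_experiments(path, records: list[ExperimentRecord]) -> None:
    n_rep = max(len(r.replicate_speeds) for r in records)
    rows = []
    for r in records:
        row = {"experiment_id": r.experiment_id, "S": r.S, "mass_g": r.mass * 1e3}
        for i in range(n_rep):
            row[f"speed_{i + 1}"] = (
                r.replicate_speeds[i] if i < len(r.replicate_speeds) else np.nan
            )
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_experiments(
    path,
    model_material: MaterialSpec,
    depth_window: tuple[float, float] = (0.19, 0.99),
) -> list[ExperimentRecord]:
    """Read measured experiments; model volume is derived as mass / density."""
    df = pd.read_csv(path)
    base = Path(path).parent
    records = []
    speed_cols = [c for c in df.columns if c.startswith("speed")]
    for _, row in df.iterrows():
        mass = float(row["mass_g"]) * 1e-3
        speeds: list[float] = []
        if speed_cols:
            speeds = [float(row[c]) for c in speed_cols if np.isfinite(row[c])]
        if not speeds and "tracks" in df.columns and isinstance(row["tracks"], str):
            for pair in row["tracks"].split(";"):
                p1, p2 = pair.split(":")
                t1 = read_track(base / p1.strip(), depth_window)
                t2 = read_track(base / p2.strip(), depth_window)
                speeds.append(track_velocity(t1, t2))
        if not speeds:
            raise InvalidInputError(
                f"experiment {row['experiment_id']!r} has neither speeds nor tracks"
            )
        records.append(
            ExperimentRecord(
                experiment_id=str(row["experiment_id"]),
                S=float(row["S"]),
                volume=mass / model_material.density,
                mass=mass,
                replicate_speeds=speeds,
            )
        )
    return records


def _jsonify(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {
            f.name: _jsonify(getattr(obj, f.name))
            for f in dataclasses.fields(obj)
            if not f.name.startswith("_")
        }
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, (list, tuple)):
        return [_jsonify(x) for x in obj]
    if isinstance(obj, dict):
        return {k: _jsonify(v) for k, v in obj.items()}
    if hasattr(obj, "to_json"):  # DragCurve
        return json.loads(obj.to_json())
    return obj


def result_to_json(result) -> str:
    """Serialize an EstimationResult (or any dataclass tree) to JSON."""
    return json.dumps(_jsonify(result), indent=2)
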