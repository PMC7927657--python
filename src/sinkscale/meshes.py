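"""Morphometrics from triangulated surface meshes.

Given an STL mesh and a sinking-direction vector, three scalars feed the
estimation pipeline: the solid volume the mesh encloses, the area of the
silhouette projected onto the plane perpendicular to the sinking direction,
and the maximum extent parallel to it.  The silhouette of a concave body is
the union of the projected faces, computed exactly as a polygon union rather
than by sampling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import trimesh
from shapely.geometry import Polygon
from shapely.ops import unary_union

from .core import InvalidInputError, ParticleGeometry

__all__ = [
    "OrientedMesh",
    "NonWatertightMeshError",
    "load_stl",
    "mesh_volume",
    "projected_area",
    "max_length_along",
    "particle_geometry_from_mesh",
]


class NonWatertightMeshError(ValueError):
    """Mesh has boundary edges, so its enclosed volume is undefined."""


@dataclass
class OrientedMesh:
    """A triangulated surface plus a unit sinking-direction vector."""

    mesh: trimesh.Trimesh
    sink_direction: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.sink_direction, dtype=float).ravel()
        if v.shape != (3,):
            raise InvalidInputError("sink_direction must be a 3-vector")
        norm = float(np.linalg.norm(v))
        if norm == 0:
            raise InvalidInputError("sink_direction must be non-zero")
        self.sink_direction = v / norm
        if len(self.mesh.faces) == 0:
            raise InvalidInputError("mesh has no faces")


def load_stl(path, sink_direction=(0.0, 0.0, -1.0)) -> OrientedMesh:
    """Read an STL file (binary or ASCII) into an OrientedMesh."""
    mesh = trimesh.load(path, force="mesh")
    return OrientedMesh(mesh=mesh, sink_direction=np.asarray(sink_direction, float))


def _boundary_edge_count(mesh: trimesh.Trimesh) -> int:
    edges = np.sort(mesh.edges, axis=1)
    _, counts = np.unique(edges, axis=0, return_counts=True)
    return int(np.sum(counts == 1))


def mesh_volume(oriented: OrientedMesh) -> float:
    """Volume enclosed by a watertight mesh (divergence theorem), m^3.

    The absolute value is returned so face winding cannot flip the sign.  The
    mesh's own outer surface defines the solid: internal voids sealed by the
    surface are excluded, aperture-connected lumina are whatever the mesh says
    they are.
    """
    mesh = oriented.mesh
    if not mesh.is_watertight:
        raise NonWatertightMeshError(
            f"mesh is not watertight ({_boundary_edge_count(mesh)} open edges); "
            "repair it before computing a volume"
        )
    return float(abs(mesh.volume))


def _plane_basis(normal: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    helper = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(helper, normal)) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(normal, helper)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(normal, e1)
    return e1, e2


def projected_area(oriented: OrientedMesh) -> float:
    """Area of the mesh silhouette perpendicular to the sinking direction, m^2.

    Each face is projected onto the plane and the union of the resulting
    triangles taken with exact polygon arithmetic; faces edge-on to the
    direction contribute nothing.
    """
    n = oriented.sink_direction
    e1, e2 = _plane_basis(n)
    verts = oriented.mesh.vertices
    uv = np.column_stack([verts @ e1, verts @ e2])
    tris = uv[oriented.mesh.faces]  # (n_faces, 3, 2)
    # signed 2D areas; drop degenerate (edge-on) faces
    a = tris[:, 1] - tris[:, 0]
    b = tris[:, 2] - tris[:, 0]
    signed = 0.5 * (a[:, 0] * b[:, 1] - a[:, 1] * b[:, 0])
    scale = max(np.ptp(uv[:, 0]), np.ptp(uv[:, 1]), 1e-300)
    keep = np.abs(signed) > 1e-12 * scale**2
    if not keep.any():
        warnings.warn("all faces are parallel to the sinking direction; area is zero",
                      stacklevel=2)
        return 0.0
    polys = [Polygon(t) for t in tris[keep]]
    return float(unary_union(polys).area)


def max_length_along(oriented: OrientedMesh) -> float:
    """Maximum vertex extent parallel to the sinking direction, m."""
    proj = oriented.mesh.vertices @ oriented.sink_direction
    return float(proj.max() - proj.min())


def particle_geometry_from_mesh(
    oriented: OrientedMesh, shape_label: str = ""
) -> ParticleGeometry:
    """Bundle (L, A, V) from a mesh into a ParticleGeometry."""
    return ParticleGeometry(
        L=max_length_along(oriented),
        A=projected_area(oriented),
        V=mesh_volume(oriented),
        shape_label=shape_label,
    )
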