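"""Geometric and clinical comparison metrics between chamber reconstructions.

Covers the editing step (spherical exclusion of the mitral valve, pulmonary
veins and appendage before registration), directed and symmetric surface
distance, enclosed volume (reported in ml), surface area, per-vertex area
weights for area-weighted histograms, and the equivalent-wall-thickness
statistic (volume difference between an outer and inner reconstruction per
unit inner surface area).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

from ._triangles import MeshProximity
from .surface_reconstruction import SurfaceMesh, as_mesh

__all__ = [
    "ExclusionRegion",
    "DistanceReport",
    "exclude_regions",
    "surface_distance",
    "enclosed_volume",
    "surface_area",
    "vertex_areas",
    "equivalent_wall_thickness",
]

RegionLabel = Literal["mitral_valve", "pulmonary_vein", "laa", "other"]


@dataclass(frozen=True)
class ExclusionRegion:
    """Spherical editing region (center in mm, radius in mm)."""

    center: np.ndarray
    radius: float
    label: RegionLabel = "other"

    def __post_init__(self) -> None:
        object.__setattr__(self, "center", np.asarray(self.center, float).reshape(3))
        if self.radius <= 0:
            raise ValueError("radius must be positive")


@dataclass(frozen=True)
class DistanceReport:
    per_point: np.ndarray
    mean: float
    sd: float
    direction: Literal["a_to_b", "b_to_a", "symmetric"]


def exclude_regions(mesh: SurfaceMesh, regions: Sequence[ExclusionRegion],
                    cap_holes: bool = False) -> SurfaceMesh:
    """Remove faces touching any exclusion sphere; optionally re-close holes.

    A face is removed when any of its vertices lies inside any region sphere.
    With ``cap_holes`` each resulting boundary loop is closed by a centroid
    fan, restoring watertightness.  If the removal splits the mesh, only the
    largest component is kept (with a warning).
    """
    if not regions:
        raise ValueError("regions must be non-empty")
    V, F = mesh.vertices, mesh.faces
    inside = np.zeros(len(V), bool)
    for reg in regions:
        inside |= np.linalg.norm(V - reg.center, axis=1) < reg.radius
    keep_faces = ~inside[F].any(axis=1)
    F2 = F[keep_faces]
    if len(F2) == 0:
        raise ValueError("exclusion regions removed the entire mesh")
    out = as_mesh(V, F2)
    parts = out.split(only_watertight=False)
    if len(parts) > 1:
        sizes = sorted((len(p.faces) for p in parts), reverse=True)
        if sizes[1] > 0.05 * sizes[0]:
            warnings.warn("exclusion disconnected the mesh; keeping the "
                          "largest component")
        out = max(parts, key=lambda p: len(p.faces))
    else:
        out.remove_unreferenced_vertices()
    if cap_holes:
        out = _cap_boundary_loops(out)
    return out


def _boundary_loops(mesh: SurfaceMesh) -> list[list[int]]:
    """Ordered vertex loops of boundary edges (edges used by a single face)."""
    edges = mesh.edges  # directed, one triple per face
    keys = np.sort(edges, axis=1)
    _, inv, counts = np.unique(keys, axis=0, return_inverse=True, return_counts=True)
    boundary = edges[counts[inv] == 1]
    nxt = {int(a): int(b) for a, b in boundary}
    loops = []
    while nxt:
        start, cur = next(iter(nxt.items()))
        loop = [start]
        while cur != start:
            loop.append(cur)
            cur = nxt.pop(cur)
        nxt.pop(start)
        loops.append(loop)
    return loops


def _cap_boundary_loops(mesh: SurfaceMesh) -> SurfaceMesh:
    loops = _boundary_loops(mesh)
    if not loops:
        return mesh
    V = mesh.vertices.copy()
    F = [mesh.faces]
    for loop in loops:
        centroid = V[loop].mean(axis=0)
        ci = len(V)
        V = np.vstack([V, centroid[None]])
        ring = np.array(loop)
        # boundary edges run a->b in face direction; cap uses b->a to close
        fan = np.column_stack([np.roll(ring, -1), ring,
                               np.full(len(ring), ci)])
        F.append(fan)
    return as_mesh(V, np.vstack(F))


def surface_distance(a: SurfaceMesh, b: SurfaceMesh,
                     direction: Literal["a_to_b", "b_to_a", "symmetric"] = "symmetric",
                     ) -> DistanceReport:
    """Vertex-to-surface distance between two registered meshes.

    ``a_to_b`` measures each vertex of ``a`` against the triangles of ``b``
    (surface points, not only vertices).  The symmetric report averages the
    two directed means and pools both per-point lists.
    """
    if len(a.faces) == 0 or len(b.faces) == 0:
        raise ValueError("empty mesh")

    def directed(src: SurfaceMesh, dst: SurfaceMesh) -> np.ndarray:
        return MeshProximity(dst.vertices, dst.faces).distance(src.vertices)

    if direction == "a_to_b":
        d = directed(a, b)
        return DistanceReport(d, float(d.mean()), float(d.std()), direction)
    if direction == "b_to_a":
        d = directed(b, a)
        return DistanceReport(d, float(d.mean()), float(d.std()), direction)
    d_ab = directed(a, b)
    d_ba = directed(b, a)
    pooled = np.concatenate([d_ab, d_ba])
    mean = 0.5 * (float(d_ab.mean()) + float(d_ba.mean()))
    return DistanceReport(pooled, mean, float(pooled.std()), "symmetric")


def enclosed_volume(mesh: SurfaceMesh) -> float:
    """Enclosed volume of a closed oriented mesh, in ml (1 ml = 1000 mm^3)."""
    if not mesh.is_watertight:
        raise ValueError("mesh is open; close it first (see exclude_regions "
                         "cap_holes=True)")
    tri = mesh.vertices[mesh.faces]
    vol_mm3 = abs(float(np.einsum("ij,ij->", tri[:, 0],
                                  np.cross(tri[:, 1], tri[:, 2])) / 6.0))
    return vol_mm3 / 1000.0


def surface_area(mesh: SurfaceMesh) -> float:
    """Total surface area in mm^2."""
    tri = mesh.vertices[mesh.faces]
    return float(0.5 * np.linalg.norm(
        np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0]), axis=1).sum())


def vertex_areas(mesh: SurfaceMesh) -> np.ndarray:
    """Barycentric area weights: one third of each incident face area."""
    tri = mesh.vertices[mesh.faces]
    fa = 0.5 * np.linalg.norm(
        np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0]), axis=1)
    out = np.zeros(len(mesh.vertices))
    np.add.at(out, mesh.faces.ravel(), np.repeat(fa / 3.0, 3))
    return out


def equivalent_wall_thickness(v_outer: float, v_inner: float,
                              area_inner: float) -> float:
    """Equivalent wall thickness (mm) from volumes (ml) and inner area (mm^2).

    The volume excess of the outer over the inner reconstruction spread
    uniformly over the inner surface.
    """
    if area_inner <= 0:
        raise ValueError("area_inner must be positive")
    if v_outer < v_inner:
        warnings.warn("outer volume smaller than inner volume; "
                      "returning a negative thickness")
    return (v_outer - v_inner) * 1000.0 / area_inner
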