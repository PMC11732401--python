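"""Synthetic phantoms emulating the study's acquisition chain.

Everything the pipeline consumes can be generated here with known ground
truth: closed atrium-like surfaces, axial contour stacks with the acquisition
geometry of thick-slice cine MRI (8 mm spacing, sub-mm in-plane noise), dual
endo/epicardial-layer ultrasound-style point clouds with outliers, and
per-vertex conduction fields whose event rates depend on the distance to an
adjacent structure.  All outputs are deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dataclass_field
from typing import Literal

import numpy as np
import trimesh
from skimage.measure import marching_cubes

from .contours import Contour, ContourSet, SlicePose, make_contour_set, resample_contour
from .field_analysis import VertexField, structure_distance
from .surface_reconstruction import SurfaceMesh, as_mesh

__all__ = [
    "PhantomSpec",
    "CloudSpec",
    "make_phantom",
    "slice_to_contours",
    "sample_cloud",
    "make_fields",
    "make_adjacent_structure",
    "PCP_BASE_RATES",
]

Shape = Literal["sphere", "ellipsoid", "blended_atrium"]

# baseline PCP event rates away from any adjacent structure, 1/s; the LIA
# pattern dominates, in line with its reported clinical prevalence
PCP_BASE_RATES = {"ff": 0.05, "lra": 0.2, "lia": 0.65}

CONTACT_THRESHOLD_MM = 3.0


@dataclass(frozen=True)
class PhantomSpec:
    """Shape family, size (mm) and MRI-style slicing parameters."""

    shape: Shape = "sphere"
    size: tuple[float, ...] = (30.0,)
    slice_spacing: float = 8.0
    in_plane_noise_sd: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.size):
            raise ValueError("sizes must be positive")
        if self.slice_spacing <= 0:
            raise ValueError("slice_spacing must be positive")
        if self.in_plane_noise_sd < 0:
            raise ValueError("in_plane_noise_sd must be >= 0")


@dataclass(frozen=True)
class CloudSpec:
    """Ultrasound-style sampling: dual reflection layers plus stray outliers."""

    n_points: int = 4000
    surface_noise_sd: float = 0.5
    epi_offset: float = 1.9
    epi_fraction: float = 0.0
    outlier_fraction: float = 0.0
    outlier_scale: float = 40.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("epi_fraction", "outlier_fraction"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must be in [0, 1]")


def _smooth_union(fields: list[np.ndarray], k: float) -> np.ndarray:
    stacked = np.stack(fields)
    m = stacked.min(axis=0)
    return m - k * np.log(np.exp(-(stacked - m) / k).sum(axis=0))


def _capsule_field(pts: np.ndarray, a: np.ndarray, b: np.ndarray,
                   r0: float, r1: float) -> np.ndarray:
    """Signed distance to a tapered capsule from a to b (radius r0 -> r1)."""
    ab = b - a
    t = np.clip(((pts - a) @ ab) / (ab @ ab), 0.0, 1.0)
    proj = a + t[:, None] * ab
    return np.linalg.norm(pts - proj, axis=1) - (r0 + t * (r1 - r0))


def make_phantom(spec: PhantomSpec) -> SurfaceMesh:
    """Closed genus-0 phantom surface; deterministic given the spec."""
    if spec.shape == "sphere":
        return trimesh.creation.icosphere(subdivisions=4, radius=spec.size[0])
    if spec.shape == "ellipsoid":
        abc = np.asarray(spec.size if len(spec.size) == 3 else spec.size * 3, float)
        m = trimesh.creation.icosphere(subdivisions=4, radius=1.0)
        return as_mesh(m.vertices * abc, m.faces)
    if spec.shape != "blended_atrium":
        raise ValueError(f"unknown shape {spec.shape!r}")

    abc = np.asarray(spec.size if len(spec.size) == 3 else (30.0, 25.0, 20.0), float)
    scale = float(abc.min())
    # grid covering body + stubs
    span = abc.max() * 1.9
    res = 96
    axes = [np.linspace(-span, span, res)] * 3
    grid = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)

    body = (np.linalg.norm(grid / abc, axis=1) - 1.0) * scale
    fields = [body]
    # four pulmonary-vein stubs: tapered tubes leaving the posterior body
    stub_dirs = np.array([
        (0.55, 0.62, 0.45), (0.62, -0.58, 0.25),
        (-0.72, 0.48, 0.55), (-0.70, -0.58, 0.20),
    ])
    stub_dirs /= np.linalg.norm(stub_dirs, axis=1, keepdims=True)
    stub_radii = ((7.0, 5.0), (5.5, 4.0), (6.0, 4.5), (4.8, 3.5))
    for d, (r0, r1) in zip(stub_dirs, stub_radii):
        start = d * abc * 0.78
        end = d * abc * 1.28
        fields.append(_capsule_field(grid, start, end, r0, r1))
    # lateral pouch standing in for the appendage
    pd = np.array([0.25, 0.93, 0.26])
    pd /= np.linalg.norm(pd)
    fields.append(_capsule_field(grid, pd * abc * 0.7, pd * abc * 1.15, 8.0, 5.0))

    sdf = _smooth_union(fields, k=3.0).reshape(res, res, res)
    h = axes[0][1] - axes[0][0]
    verts, faces, _, _ = marching_cubes(sdf, level=0.0, spacing=(h, h, h))
    verts += np.array([axes[0][0]] * 3)
    mesh = trimesh.Trimesh(vertices=verts, faces=faces, process=True)
    parts = mesh.split(only_watertight=False)
    if len(parts) > 1:
        mesh = max(parts, key=lambda p: len(p.faces))
    if mesh.volume < 0:
        mesh.invert()
    return mesh


def _largest_loop_2d(section, to2d) -> np.ndarray | None:
    loops = section.discrete
    if not loops:
        return None
    best = max(loops, key=lambda loop: np.linalg.norm(
        np.diff(loop, axis=0), axis=1).sum())
    pts = np.asarray(best)
    if np.allclose(pts[0], pts[-1]):
        pts = pts[:-1]
    if len(pts) < 3:
        return None
    return to2d(pts)


def _radial_jitter(points2d: np.ndarray, sd: float, rng: np.random.Generator):
    """In-plane Gaussian jitter applied radially about the loop centroid.

    Radial (rather than isotropic) perturbation keeps noisy contours simple
    polygons; the distance of each vertex to the true boundary is N(0, sd)
    to first order either way.
    """
    if sd == 0:
        return points2d
    c = points2d.mean(axis=0)
    rel = points2d - c
    r = np.linalg.norm(rel, axis=1)
    return c + rel * (1.0 + rng.normal(0.0, sd, len(r)) / r)[:, None]


def slice_to_contours(mesh: SurfaceMesh, spec: PhantomSpec,
                      levels: np.ndarray | None = None,
                      points_per_contour: int = 80) -> ContourSet:
    """Emulate axial MRI contouring of a closed mesh.

    Planes z = z_min + k * spacing (or explicit ``levels``) cut the mesh; the
    largest loop per plane is kept, resampled and jittered in-plane.  A
    mid-height transverse (y-normal) contour is attached for stack alignment,
    and lid points follow the half-spacing centroid rule.
    """
    rng = np.random.default_rng(spec.seed)
    z_min, z_max = mesh.bounds[:, 2]
    if levels is None:
        levels = np.arange(z_min, z_max, spec.slice_spacing)
    contours = []
    for z in levels:
        sec = mesh.section(plane_origin=[0, 0, float(z)], plane_normal=[0, 0, 1])
        if sec is None:
            continue
        pts2d = _largest_loop_2d(sec, lambda p: p[:, :2])
        if pts2d is None:
            continue
        pose = SlicePose(origin=np.array([0.0, 0.0, float(z)]),
                         axis_u=np.array([1.0, 0.0, 0.0]),
                         axis_v=np.array([0.0, 1.0, 0.0]),
                         plane_label="axial")
        contour = resample_contour(Contour(points2d=pts2d, pose=pose),
                                   points_per_contour)
        contours.append(Contour(
            points2d=_radial_jitter(contour.points2d, spec.in_plane_noise_sd, rng),
            pose=pose))
    if len(contours) < 2:
        raise ValueError("fewer than 2 non-empty slices; check spacing vs size")

    y_mid = float(mesh.vertices[:, 1].mean())
    transverse = None
    sec = mesh.section(plane_origin=[0, y_mid, 0], plane_normal=[0, 1, 0])
    if sec is not None:
        # plane frame: u = z-axis, v = x-axis, normal u x v = +y
        pts2d = _largest_loop_2d(sec, lambda p: np.column_stack([p[:, 2], p[:, 0]]))
        if pts2d is not None:
            pose = SlicePose(origin=np.array([0.0, y_mid, 0.0]),
                             axis_u=np.array([0.0, 0.0, 1.0]),
                             axis_v=np.array([1.0, 0.0, 0.0]),
                             plane_label="transverse")
            contour = resample_contour(Contour(points2d=pts2d, pose=pose),
                                       points_per_contour)
            transverse = Contour(
                points2d=_radial_jitter(contour.points2d, spec.in_plane_noise_sd, rng),
                pose=pose)
    return make_contour_set(contours, transverse=transverse)


def sample_cloud(mesh: SurfaceMesh, spec: CloudSpec) -> np.ndarray:
    """Area-weighted surface point cloud with optional epicardial layer.

    A fraction of points is displaced outward along the surface normal by
    ``epi_offset`` (emulating reflections from the outer wall); all points
    get Gaussian noise along the normal; a small fraction is replaced by far
    outliers emulating stray reflections.
    """
    rng = np.random.default_rng(spec.seed)
    pts, fidx = trimesh.sample.sample_surface(
        mesh, spec.n_points, seed=int(rng.integers(2 ** 31)))
    pts = np.asarray(pts, float)
    normals = np.asarray(mesh.face_normals[fidx], float)
    epi = rng.random(spec.n_points) < spec.epi_fraction
    pts = pts + np.where(epi[:, None], spec.epi_offset, 0.0) * normals
    if spec.surface_noise_sd > 0:
        pts = pts + rng.normal(0, spec.surface_noise_sd,
                               (spec.n_points, 1)) * normals
    n_out = int(round(spec.outlier_fraction * spec.n_points))
    if n_out:
        centroid = mesh.vertices.mean(axis=0)
        r_max = float(np.linalg.norm(mesh.vertices - centroid, axis=1).max())
        idx = rng.choice(spec.n_points, n_out, replace=False)
        dirs = rng.normal(size=(n_out, 3))
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        radii = r_max + spec.outlier_scale * (0.5 + rng.random(n_out))
        pts[idx] = centroid + dirs * radii[:, None]
    return pts


def make_adjacent_structure(mesh: SurfaceMesh, gap: float = 1.0,
                            radius: float = 10.0) -> SurfaceMesh:
    """A cylinder alongside the phantom standing in for an adjacent structure.

    Runs parallel to z, offset in +x so its surface comes within ``gap`` mm of
    the phantom at closest approach (an aorta-like neighbour).
    """
    lo, hi = mesh.bounds
    height = float((hi[2] - lo[2]) * 1.3)
    cx = float(hi[0] + gap + radius)
    cy = float(mesh.vertices[:, 1].mean())
    cz = float(mesh.vertices[:, 2].mean())
    cyl = trimesh.creation.cylinder(radius=radius, height=height, sections=48)
    cyl.apply_translation([cx, cy, cz])
    return as_mesh(cyl.vertices, cyl.faces)


def make_fields(mesh: SurfaceMesh, structure: SurfaceMesh,
                effect: float = 3.0, duration_s: float = 60.0,
                seed: int = 0,
                distances: np.ndarray | None = None) -> dict[str, VertexField]:
    """Per-vertex CV and PCP fields with a known contact effect.

    CV fields are smooth low-order angular patterns in [0.2, 1.5] m/s.  PCP
    frequencies are Poisson event counts over ``duration_s`` divided by the
    duration, with the rate multiplied by ``effect`` for vertices within
    3 mm of the adjacent structure.  Precomputed per-vertex ``distances`` to
    the structure may be passed to amortise the proximity query over seeds.
    """
    if effect < 1:
        raise ValueError("effect must be >= 1")
    rng = np.random.default_rng(seed)
    V = mesh.vertices
    if distances is None:
        distances = structure_distance(mesh, structure).distances
    contact = distances <= CONTACT_THRESHOLD_MM

    u = V - V.mean(axis=0)
    u /= np.linalg.norm(u, axis=1, keepdims=True)
    fields: dict[str, VertexField] = {}
    for kind in ("cv_af", "cv_long_cl", "cv_short_cl"):
        a = rng.normal(size=3)
        a /= np.linalg.norm(a)
        b = rng.normal(size=3)
        b /= np.linalg.norm(b)
        base = (0.85 + 0.35 * (u @ a) + 0.2 * ((u @ b) ** 2 - 1.0 / 3.0)
                + rng.normal(0, 0.05, len(V)))
        fields[kind] = VertexField(np.clip(base, 0.2, 1.5), kind)
    for kind, base_rate in PCP_BASE_RATES.items():
        rate = base_rate * np.where(contact, effect, 1.0)
        counts = rng.poisson(rate * duration_s)
        fields[kind] = VertexField(counts / duration_s, kind)
    return fields
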