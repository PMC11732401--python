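"""Endocardial surface reconstruction from sparse contour stacks and point clouds.

Two reconstruction paths are provided, mirroring the two imaging modalities:

* contour path — an initial ruled-surface ("tubular") mesh through the
  resampled contours is iteratively deformed by a thin-plate-spline (TPS)
  field fitted to attractor points sampled on the contours, alternated with
  Laplacian smoothing and interleaved subdivision/decimation, until the mean
  contour-to-mesh distance converges;
* point-cloud path — a grid Poisson indicator fit: oriented normals are
  estimated from local neighbourhoods, splatted onto a regular grid, and the
  Poisson equation for the smoothed indicator field is solved spectrally, with
  the surface extracted by marching cubes.  No smoothing is applied afterwards.

All lengths are millimetres.  Meshes are `trimesh.Trimesh` objects used as a
plain container (vertices/faces); no trimesh processing that merges or
reorders vertices is invoked implicitly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dataclass_field

import numpy as np
import trimesh
from scipy import ndimage
from scipy.fft import dstn, idstn
from scipy.ndimage import map_coordinates
from scipy.sparse import coo_matrix
from skimage.measure import marching_cubes

from ._meshops import butterfly_subdivide, quadric_decimate
from ._triangles import MeshProximity
from .contours import Contour, ContourSet, resample_contour, to_global

__all__ = [
    "SurfaceMesh",
    "AttractorSet",
    "ThinPlateSplineField",
    "ReconstructionConfig",
    "DistanceSummary",
    "as_mesh",
    "build_tubular_mesh",
    "sample_attractors",
    "attractor_targets",
    "tps_fit",
    "apply_tps",
    "laplacian_smooth",
    "reconstruct",
    "contour_to_mesh_distance",
    "poisson_reconstruct",
    "remove_radial_outliers",
]

SurfaceMesh = trimesh.Trimesh


def as_mesh(vertices: np.ndarray, faces: np.ndarray) -> SurfaceMesh:
    """Wrap raw arrays as a mesh without any implicit processing."""
    return trimesh.Trimesh(vertices=np.asarray(vertices, float),
                           faces=np.asarray(faces, int), process=False)


@dataclass(frozen=True)
class AttractorSet:
    """Target points sampled along the contours that pull the mesh outward."""

    points: np.ndarray          # (A, 3) mm, each lying on a contour segment
    source: np.ndarray          # (A,) index of the contour each came from

    def __post_init__(self) -> None:
        object.__setattr__(self, "points", np.asarray(self.points, float).reshape(-1, 3))
        object.__setattr__(self, "source", np.asarray(self.source, int).reshape(-1))
        if len(self.points) != len(self.source):
            raise ValueError("points and source lengths differ")


@dataclass
class ReconstructionConfig:
    """Tunables of the contour-path reconstruction loop.

    ``beta`` is the attractor step length in mm; ``lambda_`` weighs data
    fidelity against bending energy in the TPS fit; smoothing uses weight
    ``smooth_weight`` for ``smooth_iters`` sweeps per outer iteration.
    """

    K: int = 64
    n_attractors: int = 400
    beta: float = 1.0
    lambda_: float = 1e3
    smooth_weight: float = 0.3
    smooth_iters: int = 2
    max_outer_iters: int = 50
    convergence_tol: float = 0.01
    subdivision_interval: int = 3
    decimation_target_faces: int = 6000
    dense_points_per_contour: int = 200

    def __post_init__(self) -> None:
        numeric = ("K", "n_attractors", "beta", "lambda_", "smooth_weight",
                   "smooth_iters", "convergence_tol", "subdivision_interval",
                   "decimation_target_faces", "dense_points_per_contour")
        for name in numeric:
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.max_outer_iters < 0:
            raise ValueError("max_outer_iters must be >= 0")
        if not 0 < self.smooth_weight <= 1:
            raise ValueError("smooth_weight must be in (0, 1]")


# ---------------------------------------------------------------------------
# Initial ruled-surface mesh
# ---------------------------------------------------------------------------

def build_tubular_mesh(cs: ContourSet, K: int) -> SurfaceMesh:
    """Connect consecutive contours with ruled-surface triangle strips.

    Every contour is resampled to K vertices; each ring's index origin is
    rotated to minimise the summed rung length to its predecessor (twist
    minimisation); the extreme rings are closed by triangle fans to the lid
    points.  The result is a closed, consistently oriented, genus-0 mesh.
    """
    if K < 3:
        raise ValueError("K must be >= 3")
    rings = [to_global(resample_contour(c, K)) for c in cs.contours]
    J = len(rings)
    for j in range(1, J):
        prev, cur = rings[j - 1], rings[j]
        costs = [np.sum((np.roll(cur, -r, axis=0) - prev) ** 2) for r in range(K)]
        rings[j] = np.roll(cur, -int(np.argmin(costs)), axis=0)
    vertices = np.vstack(rings + [cs.lid_low[None], cs.lid_high[None]])
    i_low, i_high = J * K, J * K + 1
    faces = []
    nxt = lambda i: (i + 1) % K
    for j in range(J - 1):
        lo, hi = j * K, (j + 1) * K
        for i in range(K):
            faces.append((lo + i, lo + nxt(i), hi + i))
            faces.append((hi + i, lo + nxt(i), hi + nxt(i)))
    top = (J - 1) * K
    for i in range(K):
        faces.append((i_low, nxt(i), i))
        faces.append((i_high, top + i, top + nxt(i)))
    mesh = as_mesh(vertices, np.array(faces))
    if mesh.volume < 0:
        mesh = as_mesh(vertices, np.array(faces)[:, ::-1])
    return mesh


# ---------------------------------------------------------------------------
# Attractors: farthest point sampling along the contours
# ---------------------------------------------------------------------------

def sample_attractors(cs: ContourSet, n: int, seed_index: int = 0,
                      points_per_contour: int | None = None) -> AttractorSet:
    """Greedy farthest-point sampling of attractors from contour vertices.

    The candidate pool is the contour vertices (densely resampled first when
    ``points_per_contour`` is given).  Selection starts at ``seed_index`` and
    repeatedly adds the candidate farthest from the selected set; ties break
    to the lowest candidate index, so the result is fully deterministic.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    contours = cs.contours
    if points_per_contour is not None:
        contours = tuple(resample_contour(c, points_per_contour) for c in contours)
    pools = [to_global(c) for c in contours]
    candidates = np.vstack(pools)
    source = np.concatenate([np.full(len(p), j) for j, p in enumerate(pools)])
    if n > len(candidates):
        raise ValueError(f"n={n} exceeds candidate count {len(candidates)}")
    if not 0 <= seed_index < len(candidates):
        raise ValueError("seed_index out of range")
    chosen = [seed_index]
    min_d = np.linalg.norm(candidates - candidates[seed_index], axis=1)
    for _ in range(n - 1):
        nxt = int(np.argmax(min_d))          # argmax takes the lowest index on ties
        chosen.append(nxt)
        min_d = np.minimum(min_d, np.linalg.norm(candidates - candidates[nxt], axis=1))
    idx = np.array(chosen)
    return AttractorSet(points=candidates[idx], source=source[idx])


def attractor_targets(mesh: SurfaceMesh, attractors: AttractorSet, beta: float):
    """Closest surface points P_i and bounded-step targets Q_i'.

    Each attractor Q_i pulls its closest point on the surface (any point on
    any triangle) one step of length ``beta`` toward itself; an attractor
    closer than ``beta`` captures the surface point entirely, which also
    avoids the vanishing-norm direction.
    """
    if len(mesh.faces) == 0:
        raise ValueError("empty mesh")
    Q = attractors.points
    P, d, _ = MeshProximity(mesh.vertices, mesh.faces).query(Q)
    with np.errstate(invalid="ignore", divide="ignore"):
        step = P + beta * (Q - P) / d[:, None]
    q_prime = np.where(d[:, None] <= beta, Q, step)
    return P, q_prime


# ---------------------------------------------------------------------------
# Thin-plate-spline deformation field
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ThinPlateSplineField:
    """3D TPS deformation F(x) = affine(x) + sum_i c_i * |x - P_i|.

    The |r| kernel is the Green's function of the second-order bending
    functional in three dimensions; ``lambda_`` is the data-term weight, so
    larger values approach pure interpolation of the control displacements.
    """

    control_points: np.ndarray      # (A, 3)
    affine_part: np.ndarray         # (4, 3): row 0 offset, rows 1-3 linear map
    kernel_coefficients: np.ndarray  # (A, 3), orthogonal to [1, x, y, z]
    lambda_: float

    def __call__(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, float).reshape(-1, 3)
        r = np.linalg.norm(x[:, None, :] - self.control_points[None], axis=2)
        ones = np.ones((len(x), 1))
        return np.hstack([ones, x]) @ self.affine_part + r @ self.kernel_coefficients


def tps_fit(P: np.ndarray, q_prime: np.ndarray, lambda_: float) -> ThinPlateSplineField:
    """Fit the regularized TPS mapping P -> Q' with data weight lambda_.

    Solves the square (A+4) bordered kernel system with smoothing parameter
    1/lambda_ added to the kernel diagonal; the side conditions (kernel
    coefficients orthogonal to constants and linear functions) are part of
    the system, so bending energy is finite and affine maps are reproduced
    exactly.
    """
    P = np.asarray(P, float).reshape(-1, 3)
    q_prime = np.asarray(q_prime, float).reshape(-1, 3)
    A = len(P)
    if A < 4:
        raise ValueError("need at least 4 control points")
    if lambda_ <= 0:
        raise ValueError("lambda_ must be positive")
    Ph = np.hstack([np.ones((A, 1)), P])
    if np.linalg.matrix_rank(Ph, tol=1e-8) < 4:
        raise ValueError("control points are coplanar or degenerate; "
                         "the TPS system is rank deficient")
    K = np.linalg.norm(P[:, None, :] - P[None], axis=2)
    M = np.zeros((A + 4, A + 4))
    M[:A, :A] = K + np.eye(A) / lambda_
    M[:A, A:] = Ph
    M[A:, :A] = Ph.T
    rhs = np.zeros((A + 4, 3))
    rhs[:A] = q_prime
    sol = np.linalg.solve(M, rhs)
    return ThinPlateSplineField(control_points=P, affine_part=sol[A:],
                                kernel_coefficients=sol[:A], lambda_=lambda_)


def _face_normals(vertices: np.ndarray, faces: np.ndarray) -> np.ndarray:
    tri = vertices[faces]
    return np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])


def apply_tps(field: ThinPlateSplineField, mesh: SurfaceMesh,
              max_halvings: int = 6) -> SurfaceMesh:
    """Move mesh vertices through the TPS field, guarding orientation.

    The full displacement is rejected and halved (up to ``max_halvings``
    times) whenever it would flip the orientation of any face, approximating
    a diffeomorphic application of the field; if no admissible fraction is
    found the mesh is returned unchanged with a warning.
    """
    V = mesh.vertices
    disp = field(V) - V
    n_old = _face_normals(V, mesh.faces)
    scale = 1.0
    for _ in range(max_halvings + 1):
        V_new = V + scale * disp
        n_new = _face_normals(V_new, mesh.faces)
        if np.all(np.einsum("ij,ij->i", n_old, n_new) > 0):
            return as_mesh(V_new, mesh.faces)
        scale *= 0.5
    warnings.warn("TPS step rejected: face orientation flip persisted "
                  f"after {max_halvings} halvings; mesh unchanged")
    return as_mesh(V, mesh.faces)


def laplacian_smooth(mesh: SurfaceMesh, w: float, iters: int) -> SurfaceMesh:
    """Uniform-umbrella Laplacian smoothing, simultaneous vertex updates.

    Each sweep moves every vertex a fraction ``w`` toward the mean of its
    edge-connected neighbours; connectivity is untouched.
    """
    if not 0 < w <= 1:
        raise ValueError("w must be in (0, 1]")
    V = mesh.vertices.copy()
    edges = mesh.edges_unique
    i = np.concatenate([edges[:, 0], edges[:, 1]])
    j = np.concatenate([edges[:, 1], edges[:, 0]])
    counts = np.bincount(i, minlength=len(V)).astype(float)
    W = coo_matrix((np.ones_like(i, float), (i, j)), shape=(len(V), len(V))).tocsr()
    for _ in range(iters):
        V = V + w * (W @ V / counts[:, None] - V)
    return as_mesh(V, mesh.faces)


# ---------------------------------------------------------------------------
# Contour-to-mesh distance (the reconstruction fidelity metric)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DistanceSummary:
    mean: float
    sd: float
    distances: np.ndarray


def contour_to_mesh_distance(mesh: SurfaceMesh, cs: ContourSet,
                             points_per_contour: int = 150) -> DistanceSummary:
    """Mean/sd Euclidean distance from densely resampled contours to the mesh."""
    if len(mesh.faces) == 0:
        raise ValueError("empty mesh")
    pts = np.vstack([
        to_global(resample_contour(c, max(points_per_contour, len(c.points2d))))
        for c in cs.contours
    ])
    d = MeshProximity(mesh.vertices, mesh.faces).distance(pts)
    return DistanceSummary(mean=float(d.mean()), sd=float(d.std()), distances=d)


# ---------------------------------------------------------------------------
# Full contour-path reconstruction loop
# ---------------------------------------------------------------------------

def reconstruct(cs: ContourSet, cfg: ReconstructionConfig | None = None) -> SurfaceMesh:
    """Iterative attractor/TPS/smoothing reconstruction from a contour stack.

    Outer iterations alternate attractor-driven TPS deformation with
    Laplacian smoothing; on a fixed schedule the mesh is refined by
    interpolating subdivision and brought back to the face budget by quadric
    decimation.  Deformation steps that worsen the mean contour-to-mesh
    distance are rejected (the step length beta is then halved), so the
    fidelity metric is non-increasing over accepted iterations.
    """
    cfg = cfg or ReconstructionConfig()
    spacing = np.diff([c.out_of_plane() for c in cs.contours])
    if len(spacing) and cfg.beta > 2.0 * float(np.mean(spacing)):
        raise ValueError("beta exceeds twice the mean contour spacing")
    mesh = build_tubular_mesh(cs, cfg.K)
    if cfg.max_outer_iters == 0:
        return mesh
    attractors = sample_attractors(cs, cfg.n_attractors, seed_index=0,
                                   points_per_contour=cfg.dense_points_per_contour)
    best = mesh
    best_d = contour_to_mesh_distance(best, cs).mean
    beta = cfg.beta
    # subdivision rounds needed before the face budget is reached
    rounds_planned = 0
    nf = len(mesh.faces)
    while nf < cfg.decimation_target_faces:
        nf *= 4
        rounds_planned += 1
    rounds_done = 0
    converged = False
    for t in range(1, cfg.max_outer_iters + 1):
        if rounds_done < rounds_planned and (t - 1) % cfg.subdivision_interval == 0:
            v, f = butterfly_subdivide(best.vertices, best.faces)
            if len(f) > cfg.decimation_target_faces:
                v, f = quadric_decimate(v, f, cfg.decimation_target_faces)
            best = as_mesh(v, f)
            best_d = contour_to_mesh_distance(best, cs).mean
            rounds_done += 1
        P, q_prime = attractor_targets(best, attractors, beta)
        try:
            field = tps_fit(P, q_prime, cfg.lambda_)
        except ValueError:
            break  # degenerate control configuration; keep best mesh
        m = apply_tps(field, best)
        m = laplacian_smooth(m, cfg.smooth_weight, cfg.smooth_iters)
        d = contour_to_mesh_distance(m, cs).mean
        if d <= best_d:
            improvement = best_d - d
            best, best_d = m, d
            if improvement < cfg.convergence_tol and rounds_done >= rounds_planned:
                converged = True
                break
        else:
            beta *= 0.5
            if beta < 1e-3:
                converged = rounds_done >= rounds_planned
                break
    if not converged:
        warnings.warn(f"reconstruction stopped without meeting the convergence "
                      f"tolerance; final mean contour distance {best_d:.3f} mm")
    areas = best.area_faces
    if np.any(areas <= 1e-9):
        keep = areas > 1e-9
        best = as_mesh(best.vertices, best.faces[keep])
    return best


# ---------------------------------------------------------------------------
# Point-cloud path: grid Poisson indicator fit
# ---------------------------------------------------------------------------

def remove_radial_outliers(points: np.ndarray, n_sigma: float = 3.0) -> np.ndarray:
    """Drop points whose centroid radius deviates more than n_sigma sd.

    Emulates the manual removal of stray reflections from the point cloud
    before surface fitting.
    """
    points = np.asarray(points, float).reshape(-1, 3)
    r = np.linalg.norm(points - points.mean(axis=0), axis=1)
    return points[np.abs(r - r.mean()) <= n_sigma * r.std()]


def _estimate_normals(points: np.ndarray, k: int = 16) -> np.ndarray:
    from scipy.spatial import cKDTree

    tree = cKDTree(points)
    _, idx = tree.query(points, k=k)
    nbrs = points[idx]
    centered = nbrs - nbrs.mean(axis=1, keepdims=True)
    cov = np.einsum("nki,nkj->nij", centered, centered)
    _, vecs = np.linalg.eigh(cov)
    normals = vecs[:, :, 0]                       # smallest-eigenvalue direction
    outward = points - points.mean(axis=0)
    sign = np.sign(np.einsum("ij,ij->i", normals, outward))
    sign[sign == 0] = 1.0
    return normals * sign[:, None]


def _poisson_solve_dirichlet(rhs: np.ndarray, h: float) -> np.ndarray:
    """Solve the Poisson equation on a box with zero boundary via DST-I."""
    n0, n1, n2 = rhs.shape
    coeffs = dstn(rhs, type=1)
    eig = [
        (2.0 * np.cos(np.pi * (np.arange(n) + 1) / (n + 1)) - 2.0) / h ** 2
        for n in (n0, n1, n2)
    ]
    denom = (eig[0][:, None, None] + eig[1][None, :, None] + eig[2][None, None, :])
    coeffs /= denom
    return idstn(coeffs, type=1)


def poisson_reconstruct(cloud: np.ndarray, depth: int = 6) -> SurfaceMesh:
    """Watertight surface from an oriented-by-estimation point cloud.

    A smoothed indicator field is recovered by solving the Poisson equation
    whose right-hand side is the divergence of the splatted normal field (a
    regular-grid, spectral-solver variant of Poisson surface reconstruction);
    the iso-surface at the mean field value over the samples is extracted by
    marching cubes.  No smoothing is applied to the resulting mesh.
    """
    cloud = np.asarray(cloud, float).reshape(-1, 3)
    if len(cloud) < 500:
        raise ValueError("point cloud too sparse: need at least 500 points")
    centered = cloud - cloud.mean(axis=0)
    sv = np.linalg.svd(centered, compute_uv=False)
    if sv[2] < 1e-9 * max(sv[0], 1.0):
        raise ValueError("degenerate point cloud (rank < 3)")
    normals = _estimate_normals(cloud)

    res = 2 ** int(depth)
    lo = cloud.min(axis=0)
    hi = cloud.max(axis=0)
    span = float((hi - lo).max())
    pad = 0.18 * span
    center = 0.5 * (lo + hi)
    h = (span + 2 * pad) / (res - 1)
    origin = center - 0.5 * (res - 1) * h * np.ones(3)

    # trilinear splat of the normal field
    g = (cloud - origin) / h
    base = np.floor(g).astype(int)
    frac = g - base
    vec = np.zeros((3, res, res, res))
    for dx in (0, 1):
        for dy in (0, 1):
            for dz in (0, 1):
                wgt = (np.where(dx, frac[:, 0], 1 - frac[:, 0])
                       * np.where(dy, frac[:, 1], 1 - frac[:, 1])
                       * np.where(dz, frac[:, 2], 1 - frac[:, 2]))
                ix = np.clip(base[:, 0] + dx, 0, res - 1)
                iy = np.clip(base[:, 1] + dy, 0, res - 1)
                iz = np.clip(base[:, 2] + dz, 0, res - 1)
                for axis in range(3):
                    np.add.at(vec[axis], (ix, iy, iz), wgt * normals[:, axis])
    for axis in range(3):
        vec[axis] = ndimage.gaussian_filter(vec[axis], sigma=1.2)

    div = np.zeros((res, res, res))
    for axis in range(3):
        div += np.gradient(vec[axis], h, axis=axis)
    chi = _poisson_solve_dirichlet(div, h)

    level = float(map_coordinates(chi, g.T, order=1).mean())
    verts, faces, _, _ = marching_cubes(chi, level=level, spacing=(h, h, h))
    verts = verts + origin
    mesh = trimesh.Trimesh(vertices=verts, faces=faces, process=True)
    parts = mesh.split(only_watertight=False)
    if len(parts) > 1:
        mesh = max(parts, key=lambda p: len(p.faces))
    if mesh.volume < 0:
        mesh.invert()
    return mesh
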