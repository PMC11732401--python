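"""Rigid co-registration of two chamber reconstructions by generalized ICP.

Generalized ICP models each point with a locally planar covariance (large in
the two tangential directions, epsilon along the surface normal) and finds
the rigid motion minimising the summed Mahalanobis distance between
correspondences, which down-weights sliding along the surface and penalises
motion normal to it.  The MRI-derived mesh is conventionally the moving
source and the ultrasound-derived mesh the fixed target.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree

from .surface_reconstruction import SurfaceMesh, as_mesh

__all__ = [
    "RigidTransform",
    "GicpConfig",
    "generalized_icp",
    "apply_transform",
    "compose",
    "read_transform",
    "write_transform",
]


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid motion x -> R x + t (rotation + translation, mm)."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, float).reshape(3, 3)
        t = np.asarray(self.translation, float).reshape(3)
        if np.abs(R.T @ R - np.eye(3)).max() > 1e-6:
            raise ValueError("rotation is not orthonormal")
        if abs(np.linalg.det(R) - 1.0) > 1e-6:
            raise ValueError("rotation must be proper (det = +1)")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points, float) @ self.rotation.T + self.translation

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -self.rotation.T @ self.translation)

    @property
    def matrix(self) -> np.ndarray:
        M = np.eye(4)
        M[:3, :3] = self.rotation
        M[:3, 3] = self.translation
        return M

    @property
    def angle_deg(self) -> float:
        """Rotation angle magnitude in degrees."""
        c = (np.trace(self.rotation) - 1.0) / 2.0
        return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


def compose(T1: RigidTransform, T2: RigidTransform) -> RigidTransform:
    """(T2 o T1)(x) = R2 (R1 x + t1) + t2."""
    return RigidTransform(T2.rotation @ T1.rotation,
                          T2.rotation @ T1.translation + T2.translation)


def apply_transform(mesh: SurfaceMesh, T: RigidTransform) -> SurfaceMesh:
    """Return a mesh with vertices mapped through T (faces unchanged)."""
    return as_mesh(T.apply(mesh.vertices), mesh.faces)


def write_transform(T: RigidTransform, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump({"rotation": T.rotation.tolist(),
                   "translation_mm": T.translation.tolist()}, fh)


def read_transform(path: str | Path) -> RigidTransform:
    """Read either the JSON form or a plain-text 4x4 homogeneous matrix."""
    path = Path(path)
    text = path.read_text()
    try:
        doc = json.loads(text)
        return RigidTransform(np.array(doc["rotation"]),
                              np.array(doc["translation_mm"]))
    except json.JSONDecodeError:
        M = np.loadtxt(path)
        if M.shape != (4, 4):
            raise ValueError(f"expected a 4x4 matrix in {path}, got {M.shape}")
        return RigidTransform(M[:3, :3], M[:3, 3])


@dataclass
class GicpConfig:
    max_iterations: int = 100
    convergence_tol: float = 1e-5      # mm change in RMS residual
    k_neighbors: int = 20
    covariance_epsilon: float = 1e-3
    max_correspondence_distance: float = 20.0

    def __post_init__(self) -> None:
        for name in ("max_iterations", "convergence_tol", "k_neighbors",
                     "covariance_epsilon", "max_correspondence_distance"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def _planar_covariances(points: np.ndarray, k: int, eps: float) -> np.ndarray:
    """Per-point covariance with the smallest eigenvalue replaced by eps."""
    tree = cKDTree(points)
    _, idx = tree.query(points, k=min(k, len(points)))
    nbrs = points[idx]
    centered = nbrs - nbrs.mean(axis=1, keepdims=True)
    cov = np.einsum("nki,nkj->nij", centered, centered) / max(idx.shape[1] - 1, 1)
    vals, vecs = np.linalg.eigh(cov)
    new_vals = np.ones_like(vals)
    new_vals[:, 0] = eps
    return np.einsum("nij,nj,nkj->nik", vecs, new_vals, vecs)


def _skew(v: np.ndarray) -> np.ndarray:
    return np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])


def _rotation_from_axis_angle(w: np.ndarray) -> np.ndarray:
    theta = np.linalg.norm(w)
    if theta < 1e-12:
        return np.eye(3) + _skew(w)
    axis = w / theta
    K = _skew(axis)
    return np.eye(3) + np.sin(theta) * K + (1 - np.cos(theta)) * (K @ K)


def _pca_initializations(src: np.ndarray, tgt: np.ndarray) -> list[RigidTransform]:
    """Centroid + principal-axes alignments, all 4 proper sign combinations."""
    cs, ct = src.mean(axis=0), tgt.mean(axis=0)
    _, _, Vs = np.linalg.svd(src - cs, full_matrices=False)
    _, _, Vt = np.linalg.svd(tgt - ct, full_matrices=False)
    inits = []
    for s0 in (1.0, -1.0):
        for s1 in (1.0, -1.0):
            S = np.diag([s0, s1, s0 * s1])       # keeps det(R) = +1
            R = Vt.T @ S @ Vs
            if np.linalg.det(R) < 0:
                R = Vt.T @ (-S) @ Vs
            inits.append(RigidTransform(R, ct - R @ cs))
    return inits


def generalized_icp(source: SurfaceMesh, target: SurfaceMesh,
                    cfg: GicpConfig | None = None,
                    return_history: bool = False):
    """Plane-to-plane GICP between the vertex sets of two meshes.

    Returns (RigidTransform mapping source onto target, final RMS residual
    in mm); with ``return_history`` also the per-iteration Mahalanobis cost
    sequence of the selected basin.  The cost is non-increasing over
    iterations: each Gauss-Newton update is accepted only if it lowers the
    freshly evaluated cost, with step halving otherwise.
    """
    cfg = cfg or GicpConfig()
    src = np.asarray(source.vertices, float)
    tgt = np.asarray(target.vertices, float)
    if len(src) == 0 or len(tgt) == 0:
        raise ValueError("empty mesh")
    cov_s = _planar_covariances(src, cfg.k_neighbors, cfg.covariance_epsilon)
    cov_t = _planar_covariances(tgt, cfg.k_neighbors, cfg.covariance_epsilon)
    tree = cKDTree(tgt)

    def evaluate(T: RigidTransform):
        """Correspondences, Mahalanobis cost and RMS under transform T."""
        moved = T.apply(src)
        d, j = tree.query(moved)
        mask = d <= cfg.max_correspondence_distance
        if not np.any(mask):
            raise ValueError(
                "no correspondences within max_correspondence_distance="
                f"{cfg.max_correspondence_distance} mm; increase the threshold")
        p, q = moved[mask], tgt[j[mask]]
        C = cov_t[j[mask]] + T.rotation @ cov_s[mask] @ T.rotation.T
        M = np.linalg.inv(C)
        r = p - q
        cost = float(np.einsum("ni,nij,nj->", r, M, r) / mask.sum())
        rms = float(np.sqrt((d[mask] ** 2).mean()))
        return mask, M, r, p, cost, rms

    def refine(T, state):
        mask, M, r, p, cost, rms = state
        history = [cost]
        for _ in range(cfg.max_iterations):
            # Gauss-Newton step on (translation, rotation-vector) at current
            # T; residual r(dt, w) ~ r + dt + w x p, so J = [I | -[p]x]
            n = len(p)
            J = np.zeros((n, 3, 6))
            J[:, :, :3] = np.eye(3)
            J[:, 0, 4], J[:, 0, 5] = p[:, 2], -p[:, 1]
            J[:, 1, 3], J[:, 1, 5] = -p[:, 2], p[:, 0]
            J[:, 2, 3], J[:, 2, 4] = p[:, 1], -p[:, 0]
            H = np.einsum("nai,nab,nbj->ij", J, M, J)
            g = np.einsum("nai,nab,nb->i", J, M, r)
            try:
                delta = -np.linalg.solve(H + 1e-9 * np.eye(6), g)
            except np.linalg.LinAlgError:
                break
            improved = False
            for _h in range(8):
                dR = _rotation_from_axis_angle(delta[3:])
                T_new = RigidTransform(dR @ T.rotation,
                                       dR @ T.translation + delta[:3])
                state_new = evaluate(T_new)
                if state_new[4] < cost:
                    improved = True
                    break
                delta = delta / 2.0
            if not improved:
                break
            T = T_new
            mask, M, r, p, new_cost, new_rms = state_new
            converged = abs(rms - new_rms) < cfg.convergence_tol
            cost, rms = new_cost, new_rms
            history.append(cost)
            if converged:
                break
        return T, cost, rms, history

    # principal-axes initialisation is ambiguous up to axis signs; refine
    # from all four proper sign combinations and keep the best basin
    best = None
    for T0 in _pca_initializations(src, tgt):
        result = refine(T0, evaluate(T0))
        if best is None or result[1] < best[1]:
            best = result
    T, _, rms, history = best
    if return_history:
        return T, rms, history
    return T, rms
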