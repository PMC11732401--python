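"""Exact closest-point queries against triangle soups.

Two routes are provided: a vectorized brute force over all point/triangle
pairs (the reference), and a KD-tree-accelerated query that inspects only a
candidate subset of triangles per point, with a rigorous fallback to brute
force whenever the candidate bound cannot certify the result.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import cKDTree

__all__ = ["closest_on_triangles", "MeshProximity", "brute_force_closest"]


def _closest_point_triangle(p: np.ndarray, a: np.ndarray, b: np.ndarray,
                            c: np.ndarray) -> np.ndarray:
    """Closest point on triangles (a,b,c) to points p; all shaped (..., 3).

    Region classification after Ericson, vectorized with masks.
    """
    ab = b - a
    ac = c - a
    ap = p - a
    d1 = np.einsum("...i,...i->...", ab, ap)
    d2 = np.einsum("...i,...i->...", ac, ap)
    bp = p - b
    d3 = np.einsum("...i,...i->...", ab, bp)
    d4 = np.einsum("...i,...i->...", ac, bp)
    cp = p - c
    d5 = np.einsum("...i,...i->...", ab, cp)
    d6 = np.einsum("...i,...i->...", ac, cp)

    vc = d1 * d4 - d3 * d2
    vb = d5 * d2 - d1 * d6
    va = d3 * d6 - d5 * d4

    with np.errstate(divide="ignore", invalid="ignore"):
        v_ab = d1 / (d1 - d3)
        w_ac = d2 / (d2 - d6)
        w_bc = (d4 - d3) / ((d4 - d3) + (d5 - d6))
        denom = va + vb + vc
        v_in = vb / denom
        w_in = vc / denom
    v_ab = np.nan_to_num(v_ab)[..., None]
    w_ac = np.nan_to_num(w_ac)[..., None]
    w_bc = np.nan_to_num(w_bc)[..., None]
    v_in = np.nan_to_num(v_in)[..., None]
    w_in = np.nan_to_num(w_in)[..., None]

    out = a + ab * v_in + ac * w_in  # interior by default
    m_edge_bc = (va <= 0) & ((d4 - d3) >= 0) & ((d5 - d6) >= 0)
    out = np.where(m_edge_bc[..., None], b + w_bc * (c - b), out)
    m_edge_ac = (vb <= 0) & (d2 >= 0) & (d6 <= 0)
    out = np.where(m_edge_ac[..., None], a + w_ac * ac, out)
    m_edge_ab = (vc <= 0) & (d1 >= 0) & (d3 <= 0)
    out = np.where(m_edge_ab[..., None], a + v_ab * ab, out)
    m_c = (d6 >= 0) & (d5 <= d6)
    out = np.where(m_c[..., None], c, out)
    m_b = (d3 >= 0) & (d4 <= d3)
    out = np.where(m_b[..., None], b, out)
    m_a = (d1 <= 0) & (d2 <= 0)
    out = np.where(m_a[..., None], a, out)
    return out


def closest_on_triangles(points: np.ndarray, triangles: np.ndarray,
                         chunk: int = 2_000_000):
    """Brute-force closest point over all triangles for each query point.

    Parameters
    ----------
    points : (Q, 3) query points, mm.
    triangles : (M, 3, 3) triangle vertex coordinates.

    Returns
    -------
    closest : (Q, 3), distance : (Q,), face_index : (Q,)
    """
    points = np.asarray(points, float).reshape(-1, 3)
    triangles = np.asarray(triangles, float)
    Q, M = len(points), len(triangles)
    if M == 0:
        raise ValueError("empty triangle set")
    closest = np.empty((Q, 3))
    dist = np.empty(Q)
    fidx = np.empty(Q, dtype=np.intp)
    rows = max(1, chunk // max(M, 1))
    a, b, c = triangles[:, 0], triangles[:, 1], triangles[:, 2]
    for start in range(0, Q, rows):
        p = points[start:start + rows, None, :]
        cand = _closest_point_triangle(p, a[None], b[None], c[None])
        d2 = ((p - cand) ** 2).sum(axis=2)
        j = d2.argmin(axis=1)
        r = np.arange(len(j))
        closest[start:start + rows] = cand[r, j]
        dist[start:start + rows] = np.sqrt(d2[r, j])
        fidx[start:start + rows] = j
    return closest, dist, fidx


def brute_force_closest(points: np.ndarray, triangles: np.ndarray):
    """Alias kept for clarity in tests: the all-triangles reference route."""
    return closest_on_triangles(points, triangles)


class MeshProximity:
    """Accelerated closest-point queries against one triangle mesh.

    Candidate triangles per query come from a KD-tree over triangle centroids;
    a query is certified when the best candidate distance does not exceed the
    distance to the (k+1)-th centroid minus the largest triangle circumradius
    bound, otherwise that point falls back to brute force.
    """

    def __init__(self, vertices: np.ndarray, faces: np.ndarray, k: int = 32):
        self.vertices = np.asarray(vertices, float)
        self.faces = np.asarray(faces, int)
        if len(self.faces) == 0:
            raise ValueError("empty mesh")
        self.triangles = self.vertices[self.faces]
        self.centroids = self.triangles.mean(axis=1)
        # max distance from a centroid to its own triangle's vertices
        self._reach = float(
            np.linalg.norm(self.triangles - self.centroids[:, None, :], axis=2).max()
        )
        self.k = int(min(k, len(self.faces)))
        self._tree = cKDTree(self.centroids)

    def query(self, points: np.ndarray):
        """Return (closest, distance, face_index) for each query point."""
        points = np.asarray(points, float).reshape(-1, 3)
        dc, jc = self._tree.query(points, k=self.k)
        if self.k == 1:
            dc, jc = dc[:, None], jc[:, None]
        tri = self.triangles[jc]  # (Q, k, 3, 3)
        cand = _closest_point_triangle(points[:, None, :], tri[:, :, 0],
                                       tri[:, :, 1], tri[:, :, 2])
        d2 = ((points[:, None, :] - cand) ** 2).sum(axis=2)
        j = d2.argmin(axis=1)
        r = np.arange(len(points))
        best = np.sqrt(d2[r, j])
        closest = cand[r, j]
        fidx = jc[r, j]
        if self.k < len(self.faces):
            # certification: any non-candidate triangle lies at least
            # (k-th centroid distance - reach) away
            uncertain = best > dc[:, -1] - self._reach
            if np.any(uncertain):
                cb, db, fb = closest_on_triangles(points[uncertain], self.triangles)
                closest[uncertain] = cb
                best[uncertain] = db
                fidx[uncertain] = fb
        return closest, best, fidx

    def distance(self, points: np.ndarray) -> np.ndarray:
        return self.query(points)[1]
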