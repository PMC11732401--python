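"""Internal remeshing primitives: interpolating subdivision and decimation.

Both operate on closed, consistently oriented manifold triangle meshes given
as raw (vertices, faces) arrays and return new arrays.
"""

from __future__ import annotations

import heapq
from math import cos, pi

import numpy as np

__all__ = ["butterfly_subdivide", "quadric_decimate"]


def _next_maps(n_vertices: int, faces: np.ndarray) -> list[dict[int, int]]:
    """nxt[a][b] = c for every consistently oriented face (a, b, c)."""
    nxt: list[dict[int, int]] = [dict() for _ in range(n_vertices)]
    for f0, f1, f2 in faces:
        nxt[f0][f1] = f2
        nxt[f1][f2] = f0
        nxt[f2][f0] = f1
    return nxt


def _irregular_weights(K: int) -> np.ndarray:
    if K == 3:
        return np.array([5 / 12, -1 / 12, -1 / 12])
    if K == 4:
        return np.array([3 / 8, 0.0, -1 / 8, 0.0])
    m = np.arange(K)
    return (0.25 + np.cos(2 * pi * m / K) + 0.5 * np.cos(4 * pi * m / K)) / K


def butterfly_subdivide(vertices: np.ndarray, faces: np.ndarray):
    """One round of modified-butterfly (interpolating) 1-to-4 subdivision.

    Existing vertices are kept in place; new edge vertices are placed so that
    the refined mesh approaches a smooth limit surface through the old
    vertices, which lets sparse cross-sections regain the convex bulge between
    slices instead of staying piecewise ruled.
    """
    vertices = np.asarray(vertices, float)
    faces = np.asarray(faces, int)
    n = len(vertices)
    nxt = _next_maps(n, faces)
    valence = np.array([len(d) for d in nxt])

    def ordered_ring(i: int, start: int) -> list[int]:
        ring = [start]
        cur = nxt[i][start]
        while cur != start:
            ring.append(cur)
            cur = nxt[i][cur]
        return ring

    def irregular_point(i: int, j: int) -> np.ndarray:
        ring = ordered_ring(i, j)
        w = _irregular_weights(len(ring))
        return 0.75 * vertices[i] + w @ vertices[ring]

    edge_vertex: dict[tuple[int, int], int] = {}
    new_points: list[np.ndarray] = []
    for a in range(n):
        for b in nxt[a]:
            if a > b:
                continue
            i, j = a, b
            k = nxt[i][j]
            l = nxt[j][i]
            ri, rj = valence[i] == 6, valence[j] == 6
            if ri and rj:
                e1 = nxt[i][k]
                e2 = nxt[k][j]
                e3 = nxt[l][i]
                e4 = nxt[j][l]
                p = (0.5 * (vertices[i] + vertices[j])
                     + 0.125 * (vertices[k] + vertices[l])
                     - 0.0625 * (vertices[e1] + vertices[e2]
                                 + vertices[e3] + vertices[e4]))
            elif ri and not rj:
                p = irregular_point(j, i)
            elif rj and not ri:
                p = irregular_point(i, j)
            else:
                p = 0.5 * (irregular_point(i, j) + irregular_point(j, i))
            edge_vertex[(i, j)] = n + len(new_points)
            new_points.append(p)

    def ev(a: int, b: int) -> int:
        return edge_vertex[(a, b) if a < b else (b, a)]

    new_faces = np.empty((4 * len(faces), 3), dtype=int)
    for t, (i, j, k) in enumerate(faces):
        mij, mjk, mki = ev(i, j), ev(j, k), ev(k, i)
        new_faces[4 * t:4 * t + 4] = [
            (i, mij, mki), (j, mjk, mij), (k, mki, mjk), (mij, mjk, mki),
        ]
    return np.vstack([vertices, np.array(new_points)]), new_faces


# ---------------------------------------------------------------------------
# Quadric edge-collapse decimation
# ---------------------------------------------------------------------------

def _face_quadric(p0, p1, p2) -> np.ndarray:
    nrm = np.cross(p1 - p0, p2 - p0)
    area2 = np.linalg.norm(nrm)
    if area2 < 1e-14:
        return np.zeros((4, 4))
    n = nrm / area2
    plane = np.array([n[0], n[1], n[2], -n @ p0])
    return 0.5 * area2 * np.outer(plane, plane)


def _optimal_position(Q: np.ndarray, vi: np.ndarray, vj: np.ndarray):
    A = Q[:3, :3]
    b = Q[:3, 3]
    try:
        if np.linalg.cond(A) < 1e7:
            return np.linalg.solve(A, -b)
    except np.linalg.LinAlgError:
        pass
    # fallback: best of endpoints and midpoint under the quadric
    candidates = [vi, vj, 0.5 * (vi + vj)]
    costs = [np.array([*c, 1.0]) @ Q @ np.array([*c, 1.0]) for c in candidates]
    return candidates[int(np.argmin(costs))]


def quadric_decimate(vertices: np.ndarray, faces: np.ndarray, target_faces: int):
    """Greedy edge collapse to ~target_faces, preserving manifoldness.

    Collapses are ordered by quadric error with optimal vertex placement;
    candidates violating the link condition or flipping a face normal are
    rejected, so a closed oriented input stays closed and oriented.
    """
    V = np.asarray(vertices, float).copy()
    F = np.asarray(faces, int).copy()
    nf = len(F)
    if nf <= target_faces:
        return V.copy(), F.copy()

    alive_f = np.ones(nf, bool)
    vert_faces: list[set[int]] = [set() for _ in range(len(V))]
    for t, f in enumerate(F):
        for v in f:
            vert_faces[v].add(t)
    quadrics = np.zeros((len(V), 4, 4))
    for t, (a, b, c) in enumerate(F):
        q = _face_quadric(V[a], V[b], V[c])
        quadrics[a] += q
        quadrics[b] += q
        quadrics[c] += q

    stamp = np.zeros(len(V), dtype=int)
    heap: list[tuple[float, int, int, int, int]] = []

    def neighbors(i: int) -> set[int]:
        out: set[int] = set()
        for t in vert_faces[i]:
            out.update(F[t])
        out.discard(i)
        return out

    def push_edges(i: int) -> None:
        for j in neighbors(i):
            a, b = (i, j) if i < j else (j, i)
            Q = quadrics[a] + quadrics[b]
            x = _optimal_position(Q, V[a], V[b])
            h = np.array([*x, 1.0])
            heapq.heappush(heap, (float(h @ Q @ h), a, b, stamp[a], stamp[b]))

    for i in range(len(V)):
        for j in neighbors(i):
            if i < j:
                a, b = i, j
                Q = quadrics[a] + quadrics[b]
                x = _optimal_position(Q, V[a], V[b])
                h = np.array([*x, 1.0])
                heapq.heappush(heap, (float(h @ Q @ h), a, b, stamp[a], stamp[b]))

    n_alive = nf
    while n_alive > target_faces and heap:
        cost, i, j, si, sj = heapq.heappop(heap)
        if stamp[i] != si or stamp[j] != sj:
            continue
        shared = vert_faces[i] & vert_faces[j]
        if len(shared) != 2:  # not an interior manifold edge any more
            continue
        # link condition: common neighbors must be exactly the two opposites
        opposites = set()
        for t in shared:
            opposites.update(F[t])
        opposites -= {i, j}
        if neighbors(i) & neighbors(j) != opposites:
            continue
        Q = quadrics[i] + quadrics[j]
        x = _optimal_position(Q, V[i], V[j])
        # reject collapses that flip or degenerate any surviving face
        ok = True
        for t in (vert_faces[i] | vert_faces[j]) - shared:
            tri = F[t]
            old = V[tri]
            n_old = np.cross(old[1] - old[0], old[2] - old[0])
            new = np.array([x if v in (i, j) else V[v] for v in tri])
            n_new = np.cross(new[1] - new[0], new[2] - new[0])
            if n_old @ n_new <= 1e-12:
                ok = False
                break
        if not ok:
            continue
        # apply collapse j -> i
        V[i] = x
        quadrics[i] = Q
        for t in shared:
            alive_f[t] = False
            n_alive -= 1
            for v in F[t]:
                vert_faces[v].discard(t)
        for t in list(vert_faces[j]):
            F[t][F[t] == j] = i
            vert_faces[i].add(t)
        vert_faces[j] = set()
        stamp[i] += 1
        stamp[j] += 1
        push_edges(i)

    keep = F[alive_f]
    used = np.unique(keep)
    remap = np.full(len(V), -1, dtype=int)
    remap[used] = np.arange(len(used))
    return V[used], remap[keep]
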