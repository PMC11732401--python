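"""Sparse 2D contour stacks and their placement in the global patient frame.

A chamber segmented slice-by-slice is represented as a stack of closed planar
polylines (one per imaging plane) together with the pose of each plane in a
single right-handed global coordinate system (mm).  Two extra "lid" points
beyond the extreme slices allow a closed surface to be built later.

The in-plane resolution of the source images is much finer than the slice
spacing (typically 2.8 mm in-plane vs 8 mm between slices), so the stack is a
sparse, anisotropic sampling of the true endocardial surface.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
from scipy.optimize import minimize
from shapely.geometry import LineString

__all__ = [
    "SlicePose",
    "Contour",
    "ContourSet",
    "read_contours",
    "write_contours",
    "to_global",
    "resample_contour",
    "align_axial_stack",
]

_TOL = 1e-9

PlaneLabel = Literal["axial", "transverse"]


@dataclass(frozen=True)
class SlicePose:
    """Pose of one imaging plane: origin plus two in-plane unit axes (mm)."""

    origin: np.ndarray
    axis_u: np.ndarray
    axis_v: np.ndarray
    plane_label: PlaneLabel = "axial"

    def __post_init__(self) -> None:
        for name in ("origin", "axis_u", "axis_v"):
            vec = np.asarray(getattr(self, name), dtype=float).reshape(3)
            object.__setattr__(self, name, vec)
        if abs(np.linalg.norm(self.axis_u) - 1.0) > _TOL:
            raise ValueError("axis_u must be unit norm")
        if abs(np.linalg.norm(self.axis_v) - 1.0) > _TOL:
            raise ValueError("axis_v must be unit norm")
        if abs(float(self.axis_u @ self.axis_v)) > _TOL:
            raise ValueError("axis_u and axis_v must be orthogonal")
        if self.plane_label not in ("axial", "transverse"):
            raise ValueError(f"unknown plane label {self.plane_label!r}")

    @property
    def normal(self) -> np.ndarray:
        """Unit normal axis_u x axis_v (out-of-plane direction)."""
        return np.cross(self.axis_u, self.axis_v)


@dataclass(frozen=True)
class Contour:
    """A closed, simple polygon lying in one posed slice plane.

    ``points2d`` are (u, v) coordinates in mm within the plane; the closing
    edge from the last point back to the first is implicit.
    """

    points2d: np.ndarray
    pose: SlicePose

    def __post_init__(self) -> None:
        pts = np.asarray(self.points2d, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 3:
            raise ValueError("contour needs >=3 in-plane 2D points")
        seg = np.diff(np.vstack([pts, pts[:1]]), axis=0)
        if np.any(np.linalg.norm(seg, axis=1) <= _TOL):
            raise ValueError("consecutive contour points must be distinct")
        ring = LineString(np.vstack([pts, pts[:1]]))
        if not ring.is_simple:
            raise ValueError("contour polygon is self-intersecting")
        object.__setattr__(self, "points2d", pts)

    @property
    def closed(self) -> bool:
        return True

    @property
    def perimeter(self) -> float:
        pts = self.points2d
        seg = np.diff(np.vstack([pts, pts[:1]]), axis=0)
        return float(np.linalg.norm(seg, axis=1).sum())

    def out_of_plane(self) -> float:
        """Coordinate of the slice plane along its own normal."""
        return float(self.pose.normal @ self.pose.origin)


def to_global(contour: Contour) -> np.ndarray:
    """Map in-plane (u, v) points to global 3D coordinates (order preserved)."""
    pose = contour.pose
    uv = contour.points2d
    return pose.origin + uv[:, :1] * pose.axis_u + uv[:, 1:] * pose.axis_v


def _signed_area(points2d: np.ndarray) -> float:
    x, y = points2d[:, 0], points2d[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def resample_contour(contour: Contour, K: int) -> Contour:
    """Resample to K equally spaced vertices along the closed polyline.

    The first output vertex coincides with the original first vertex and the
    winding is normalized counter-clockwise about the plane normal.
    """
    if K < 3:
        raise ValueError("K must be >= 3")
    pts = contour.points2d
    if _signed_area(pts) < 0:  # normalize winding, keep start vertex first
        pts = np.vstack([pts[:1], pts[1:][::-1]])
    ring = np.vstack([pts, pts[:1]])
    seg_len = np.linalg.norm(np.diff(ring, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg_len)])
    total = cum[-1]
    targets = np.arange(K) * total / K
    idx = np.clip(np.searchsorted(cum, targets, side="right") - 1, 0, len(seg_len) - 1)
    frac = (targets - cum[idx]) / seg_len[idx]
    new = ring[idx] + frac[:, None] * (ring[idx + 1] - ring[idx])
    return Contour(points2d=new, pose=contour.pose)


@dataclass(frozen=True)
class ContourSet:
    """Axially ordered contour stack with lid points and optional transverse slice."""

    contours: tuple[Contour, ...]
    lid_low: np.ndarray
    lid_high: np.ndarray
    transverse: Contour | None = None

    def __post_init__(self) -> None:
        contours = tuple(self.contours)
        if len(contours) < 2:
            raise ValueError("a contour set needs >= 2 contours")
        object.__setattr__(self, "contours", contours)
        object.__setattr__(self, "lid_low", np.asarray(self.lid_low, float).reshape(3))
        object.__setattr__(self, "lid_high", np.asarray(self.lid_high, float).reshape(3))
        coords = np.array([c.out_of_plane() for c in contours])
        if np.any(np.diff(coords) <= 0):
            raise ValueError("contours must be strictly ordered along the stack axis")
        axis = self.stack_axis
        if float(axis @ self.lid_low) >= coords[0]:
            raise ValueError("lid_low must lie below the lowest contour plane")
        if float(axis @ self.lid_high) <= coords[-1]:
            raise ValueError("lid_high must lie above the highest contour plane")

    @property
    def stack_axis(self) -> np.ndarray:
        return self.contours[0].pose.normal

    def global_points(self) -> np.ndarray:
        """All contour vertices (axial stack only) in the global frame."""
        return np.vstack([to_global(c) for c in self.contours])


def default_lids(contours: Sequence[Contour]) -> tuple[np.ndarray, np.ndarray]:
    """Lid points: extreme-contour centroids offset outward by half the slice spacing."""
    coords = np.array([c.out_of_plane() for c in contours])
    half = 0.5 * float(np.median(np.diff(coords)))
    axis = contours[0].pose.normal
    low = to_global(contours[0]).mean(axis=0) - half * axis
    high = to_global(contours[-1]).mean(axis=0) + half * axis
    return low, high


def make_contour_set(
    contours: Sequence[Contour],
    lid_low: np.ndarray | None = None,
    lid_high: np.ndarray | None = None,
    transverse: Contour | None = None,
) -> ContourSet:
    """Assemble a ContourSet, sorting axial slices and filling missing lids."""
    if len(contours) < 2:
        raise ValueError("a contour set needs >= 2 contours")
    ordered = sorted(contours, key=lambda c: c.out_of_plane())
    if lid_low is None or lid_high is None:
        low, high = default_lids(ordered)
        lid_low = low if lid_low is None else lid_low
        lid_high = high if lid_high is None else lid_high
    return ContourSet(tuple(ordered), lid_low, lid_high, transverse)


# ---------------------------------------------------------------------------
# JSON I/O (schema: frame/slices/lid_low/lid_high; lids optional)
# ---------------------------------------------------------------------------

def _require(mapping: dict, key: str, where: str):
    if key not in mapping:
        raise ValueError(f"malformed contour JSON: missing field {key!r} in {where}")
    return mapping[key]


def read_contours(path: str | Path) -> ContourSet:
    """Read a contour-stack JSON file into a validated :class:`ContourSet`."""
    with open(path) as fh:
        try:
            doc = json.load(fh)
        except json.JSONDecodeError as exc:
            raise ValueError(f"malformed contour JSON in {path}: {exc}") from exc
    slices = _require(doc, "slices", "document")
    axial: list[Contour] = []
    transverse: Contour | None = None
    for i, sl in enumerate(slices):
        where = f"slices[{i}]"
        pose = SlicePose(
            origin=_require(sl, "origin", where),
            axis_u=_require(sl, "axis_u", where),
            axis_v=_require(sl, "axis_v", where),
            plane_label=_require(sl, "plane", where),
        )
        pts = np.asarray(_require(sl, "points", where), dtype=float)
        if pts.ndim != 2 or pts.shape[0] < 3:
            raise ValueError(f"contour JSON {where}: needs >=3 points, got {pts.shape}")
        contour = Contour(points2d=pts, pose=pose)
        if pose.plane_label == "transverse":
            transverse = contour
        else:
            axial.append(contour)
    return make_contour_set(
        axial,
        lid_low=np.asarray(doc["lid_low"], float) if "lid_low" in doc else None,
        lid_high=np.asarray(doc["lid_high"], float) if "lid_high" in doc else None,
        transverse=transverse,
    )


def write_contours(cs: ContourSet, path: str | Path) -> None:
    """Write a ContourSet to the JSON schema read by :func:`read_contours`."""
    slices = []
    all_contours = list(cs.contours) + ([cs.transverse] if cs.transverse else [])
    for c in all_contours:
        slices.append(
            {
                "plane": c.pose.plane_label,
                "origin": c.pose.origin.tolist(),
                "axis_u": c.pose.axis_u.tolist(),
                "axis_v": c.pose.axis_v.tolist(),
                "points": c.points2d.tolist(),
            }
        )
    doc = {
        "frame": "mm-global",
        "slices": slices,
        "lid_low": cs.lid_low.tolist(),
        "lid_high": cs.lid_high.tolist(),
    }
    with open(path, "w") as fh:
        json.dump(doc, fh)


# ---------------------------------------------------------------------------
# Axial-stack alignment against a transverse slice
# ---------------------------------------------------------------------------

def _plane_crossings(points3d: np.ndarray, origin: np.ndarray, normal: np.ndarray) -> np.ndarray:
    """Points where a closed 3D polyline crosses the plane (origin, normal)."""
    s = (points3d - origin) @ normal
    ring = np.concatenate([s, s[:1]])
    pts = np.vstack([points3d, points3d[:1]])
    crossings = []
    for a in range(len(s)):
        sa, sb = ring[a], ring[a + 1]
        if sa == 0.0:
            crossings.append(pts[a])
        elif sa * sb < 0:
            t = sa / (sa - sb)
            crossings.append(pts[a] + t * (pts[a + 1] - pts[a]))
    return np.asarray(crossings).reshape(-1, 3)


def _point_to_ring_distance(points2d_query: np.ndarray, ring2d: np.ndarray) -> np.ndarray:
    """Min distance from each 2D query point to a closed 2D polyline."""
    closed = np.vstack([ring2d, ring2d[:1]])
    a, b = closed[:-1], closed[1:]
    ab = b - a
    denom = np.einsum("ij,ij->i", ab, ab)
    out = np.empty(len(points2d_query))
    for k, p in enumerate(points2d_query):
        t = np.clip(np.einsum("ij,ij->i", p - a, ab) / denom, 0.0, 1.0)
        proj = a + t[:, None] * ab
        out[k] = np.sqrt(((p - proj) ** 2).sum(axis=1).min())
    return out


def align_axial_stack(cs: ContourSet, transverse: Contour | None = None) -> ContourSet:
    """In-plane translation of each axial slice to match the transverse contour.

    The transverse contour crosses each axial slice plane at (generically two)
    points; each axial contour is rigidly translated within its plane so that
    its boundary passes as close as possible to those crossing points.  Slices
    whose plane the transverse contour never crosses are left unchanged.  Only
    translation is adjusted — the slice orientation is trusted.
    """
    transverse = transverse if transverse is not None else cs.transverse
    if transverse is None:
        raise ValueError("no transverse contour supplied or stored on the set")
    tg = to_global(transverse)
    new_contours = []
    any_crossing = False
    for contour in cs.contours:
        pose = contour.pose
        crossings = _plane_crossings(tg, pose.origin, pose.normal)
        if len(crossings) == 0:
            new_contours.append(contour)
            continue
        any_crossing = True
        rel = crossings - pose.origin
        targets2d = np.column_stack([rel @ pose.axis_u, rel @ pose.axis_v])

        def objective(t, pts=contour.points2d, tgt=targets2d):
            # tiny ridge term selects the smallest correction when the
            # crossing-point mismatch leaves a flat direction
            return float(_point_to_ring_distance(tgt - t, pts).sum()
                         + 1e-4 * (t @ t))

        res = minimize(objective, x0=np.zeros(2), method="Nelder-Mead",
                       options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 400})
        shift = res.x
        new_contours.append(replace(contour, points2d=contour.points2d + shift))
    if not any_crossing:
        warnings.warn("transverse contour does not cross any axial slice plane; "
                      "stack returned unchanged")
        return cs
    return ContourSet(tuple(new_contours), cs.lid_low, cs.lid_high, transverse)
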