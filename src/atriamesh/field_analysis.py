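"""Per-vertex conduction fields: transfer, histograms, proximity, statistics.

Fields carry one scalar per mesh vertex: conduction velocity (CV, m/s) under
three rhythm protocols, or the frequency (1/s) of pathological conduction
patterns (PCPs) — focal firing (FF), localized rotational activation (LRA)
and localized irregular activity (LIA).  Missing values are NaN and are
pairwise-deleted in statistics.

Proximity analysis measures, for every vertex of the atrial mesh, the
Euclidean distance to the nearest point of an adjacent thoracic structure
(ascending/descending aorta, spine); vertices within the contact threshold
(3 mm by convention, inclusive) are flagged as in contact, and PCP
frequencies are compared between contact and non-contact vertices with the
Mann-Whitney U test.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from itertools import combinations
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._triangles import MeshProximity
from .mesh_metrics import surface_area, vertex_areas
from .surface_reconstruction import SurfaceMesh

__all__ = [
    "VertexField",
    "ProximityResult",
    "GroupComparison",
    "nn_transfer",
    "area_histogram",
    "paired_correlation",
    "structure_distance",
    "contact_mask",
    "combine_contacts",
    "compare_by_contact",
    "paired_t_test",
    "read_field_csv",
    "write_field_csv",
    "write_proximity_csv",
]

FieldKind = Literal["cv_af", "cv_long_cl", "cv_short_cl", "ff", "lra", "lia"]
StructureLabel = Literal["ascending_aorta", "descending_aorta", "spine"]

_CV_KINDS = ("cv_af", "cv_long_cl", "cv_short_cl")
CV_CLIP_DEFAULT = 1.5  # m/s, physiological upper bound applied to CV histograms


@dataclass(frozen=True)
class VertexField:
    """One scalar per mesh vertex; NaN marks a missing measurement."""

    values: np.ndarray
    kind: FieldKind

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, float).reshape(-1)
        finite = vals[np.isfinite(vals)]
        if np.any(finite < 0):
            raise ValueError(f"{self.kind} values must be non-negative")
        object.__setattr__(self, "values", vals)

    @property
    def units(self) -> str:
        return "m s^-1" if self.kind in _CV_KINDS else "s^-1"

    @property
    def is_cv(self) -> bool:
        return self.kind in _CV_KINDS


@dataclass(frozen=True)
class ProximityResult:
    distances: np.ndarray
    structure_label: StructureLabel | str
    contact: np.ndarray | None = None
    threshold: float | None = None


@dataclass(frozen=True)
class GroupComparison:
    median_a: float
    iqr_a: tuple[float, float]
    median_b: float
    iqr_b: tuple[float, float]
    u_statistic: float
    p_value: float


def nn_transfer(field: VertexField, from_mesh: SurfaceMesh,
                to_mesh: SurfaceMesh) -> VertexField:
    """Carry a field between co-registered meshes by nearest vertex."""
    if len(field.values) != len(from_mesh.vertices):
        raise ValueError("field length does not match from_mesh vertex count")
    from scipy.spatial import cKDTree

    _, idx = cKDTree(from_mesh.vertices).query(to_mesh.vertices)
    return VertexField(values=field.values[idx], kind=field.kind)


def area_histogram(field: VertexField, mesh: SurfaceMesh, bins: np.ndarray,
                   clip_max: float | None = None):
    """Area-weighted histogram of a vertex field.

    Each vertex contributes its barycentric surface-area share to the bin
    containing its value.  Values above ``clip_max`` (default 1.5 m/s for CV
    kinds, none for PCP kinds), missing values, and values outside the bin
    range are excluded; their total area is returned alongside so that
    bin areas + excluded area = total surface area exactly.
    """
    bins = np.asarray(bins, float)
    if np.any(np.diff(bins) <= 0):
        raise ValueError("bins must be strictly increasing")
    if clip_max is None and field.is_cv:
        clip_max = CV_CLIP_DEFAULT
    weights = vertex_areas(mesh)
    if len(field.values) != len(weights):
        raise ValueError("field length does not match mesh vertex count")
    vals = field.values
    ok = np.isfinite(vals)
    if clip_max is not None:
        ok &= vals <= clip_max
    ok &= (vals >= bins[0]) & (vals <= bins[-1])
    hist, _ = np.histogram(vals[ok], bins=bins, weights=weights[ok])
    excluded = float(surface_area(mesh) - hist.sum())
    return hist, excluded


def paired_correlation(x: VertexField, y: VertexField,
                       method: Literal["pearson", "spearman"] = "pearson"):
    """Correlation between two fields with Fisher-z 95% CI and two-sided p.

    Spearman is computed by average-rank transform followed by the Pearson
    machinery, so ties are handled with mid-ranks.
    """
    xv, yv = x.values, y.values
    if len(xv) != len(yv):
        raise ValueError("fields have different lengths")
    ok = np.isfinite(xv) & np.isfinite(yv)
    xv, yv = xv[ok], yv[ok]
    n = len(xv)
    if n < 3:
        raise ValueError("need at least 3 paired observations")
    if np.std(xv) == 0 or np.std(yv) == 0:
        raise ValueError("zero variance in one of the inputs")
    if method == "spearman":
        xv, yv = stats.rankdata(xv), stats.rankdata(yv)
    elif method != "pearson":
        raise ValueError(f"unknown method {method!r}")
    r, p = stats.pearsonr(xv, yv)
    z = np.arctanh(np.clip(r, -1 + 1e-15, 1 - 1e-15))
    halfwidth = 1.959963984540054 / np.sqrt(n - 3)
    ci = (float(np.tanh(z - halfwidth)), float(np.tanh(z + halfwidth)))
    return float(r), ci, float(p)


def structure_distance(la_mesh: SurfaceMesh, structure: SurfaceMesh,
                       label: StructureLabel | str = "other") -> ProximityResult:
    """Per-vertex distance from the atrial mesh to the structure's surface."""
    if len(structure.faces) == 0:
        raise ValueError("empty structure mesh")
    d = MeshProximity(structure.vertices, structure.faces).distance(la_mesh.vertices)
    return ProximityResult(distances=d, structure_label=label)


def contact_mask(pr: ProximityResult, threshold: float = 3.0) -> ProximityResult:
    """Flag vertices within the threshold (inclusive) as in contact."""
    return replace(pr, contact=pr.distances <= threshold, threshold=threshold)


def combine_contacts(results: Sequence[ProximityResult]) -> np.ndarray:
    """Union contact rule: in contact with ANY structure counts as contact."""
    masks = []
    for pr in results:
        if pr.contact is None:
            raise ValueError("apply contact_mask before combining")
        masks.append(pr.contact)
    return np.logical_or.reduce(masks)


# ---------------------------------------------------------------------------
# Mann-Whitney U with an exact small-sample branch
# ---------------------------------------------------------------------------

def _exact_mannwhitney_p(x: np.ndarray, y: np.ndarray, u_x: float) -> float:
    """Two-sided permutation p-value of U by full enumeration (ties allowed)."""
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    n1 = len(x)
    offset = n1 * (n1 + 1) / 2.0
    us = np.array([ranks[list(c)].sum() - offset
                   for c in combinations(range(len(pooled)), n1)])
    p_low = float(np.mean(us <= u_x))
    p_high = float(np.mean(us >= u_x))
    return min(1.0, 2.0 * min(p_low, p_high))


def mann_whitney(x: np.ndarray, y: np.ndarray, exact_max_n: int = 20):
    """U statistic of x and a two-sided p-value.

    Pooled sample sizes up to ``exact_max_n`` use the exact permutation
    distribution (full enumeration, valid under ties); larger samples use the
    tie-corrected normal approximation with continuity correction.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    ranks = stats.rankdata(np.concatenate([x, y]))
    u_x = float(ranks[: len(x)].sum() - len(x) * (len(x) + 1) / 2.0)
    if len(x) + len(y) <= exact_max_n:
        p = _exact_mannwhitney_p(x, y, u_x)
    else:
        _, p = stats.mannwhitneyu(x, y, alternative="two-sided",
                                  method="asymptotic", use_continuity=True)
    return u_x, float(p)


def compare_by_contact(field: VertexField, contact: np.ndarray) -> GroupComparison:
    """Compare a field between contact and non-contact vertices.

    Group a is the contact group.  Reports median and IQR (Q1; Q3) per group
    plus the Mann-Whitney U statistic and two-sided p-value.
    """
    contact = np.asarray(contact, bool)
    if len(contact) != len(field.values):
        raise ValueError("contact mask length does not match field")
    ok = np.isfinite(field.values)
    a = field.values[contact & ok]
    b = field.values[~contact & ok]
    if len(a) == 0:
        raise ValueError("contact group is empty")
    if len(b) == 0:
        raise ValueError("non-contact group is empty")
    u, p = mann_whitney(a, b)
    qa = np.percentile(a, [25, 50, 75])
    qb = np.percentile(b, [25, 50, 75])
    return GroupComparison(
        median_a=float(qa[1]), iqr_a=(float(qa[0]), float(qa[2])),
        median_b=float(qb[1]), iqr_b=(float(qb[0]), float(qb[2])),
        u_statistic=u, p_value=p,
    )


def paired_t_test(x: np.ndarray, y: np.ndarray):
    """Paired Student's t-test on per-case values; returns (t, two-sided p)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) != len(y) or len(x) < 2:
        raise ValueError("need equal-length samples with n >= 2")
    diff = x - y
    if np.std(diff, ddof=1) == 0:
        raise ValueError("differences have zero variance; t is undefined")
    res = stats.ttest_rel(x, y)
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

def write_field_csv(field: VertexField, path: str | Path) -> None:
    df = pd.DataFrame({"vertex_index": np.arange(len(field.values)),
                       "value": field.values})
    with open(path, "w") as fh:
        fh.write(f"# kind={field.kind} units={field.units}\n")
        df.to_csv(fh, index=False)


def read_field_csv(path: str | Path, kind: FieldKind | None = None) -> VertexField:
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("#"):
        df = pd.read_csv(path, comment="#")
        if kind is None and "kind=" in first:
            kind = first.split("kind=")[1].split()[0]
    else:
        df = pd.read_csv(path)
    if kind is None:
        raise ValueError("field kind not given and not present in the header")
    order = np.argsort(df["vertex_index"].to_numpy())
    return VertexField(values=df["value"].to_numpy()[order], kind=kind)


def write_proximity_csv(pr: ProximityResult, path: str | Path) -> None:
    if pr.contact is None:
        raise ValueError("apply contact_mask before writing")
    pd.DataFrame({
        "vertex_index": np.arange(len(pr.distances)),
        "distance_mm": pr.distances,
        "contact": pr.contact.astype(int),
    }).to_csv(path, index=False)
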