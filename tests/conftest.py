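"""Shared fixtures: analytic phantoms generated at test time."""

from __future__ import annotations

import numpy as np
import pytest
import trimesh

from atriamesh.contours import Contour, SlicePose, make_contour_set
from atriamesh.phantom import PhantomSpec, make_phantom, slice_to_contours

SPHERE_RADIUS = 30.0
SPHERE_VOLUME_ML = 4.0 / 3.0 * np.pi * SPHERE_RADIUS ** 3 / 1000.0  # 113.097
SPHERE_AREA_MM2 = 4.0 * np.pi * SPHERE_RADIUS ** 2                  # 11309.7


def identity_pose(z: float = 0.0, label: str = "axial") -> SlicePose:
    return SlicePose(origin=np.array([0.0, 0.0, z]),
                     axis_u=np.array([1.0, 0.0, 0.0]),
                     axis_v=np.array([0.0, 1.0, 0.0]),
                     plane_label=label)


def square_contour(side: float, z: float, center=(0.0, 0.0)) -> Contour:
    h = side / 2.0
    cx, cy = center
    pts = np.array([[cx - h, cy - h], [cx + h, cy - h],
                    [cx + h, cy + h], [cx - h, cy + h]])
    return Contour(points2d=pts, pose=identity_pose(z))


def circle_contour(radius: float, z: float, n: int = 64,
                   center=(0.0, 0.0)) -> Contour:
    th = np.linspace(0, 2 * np.pi, n, endpoint=False)
    pts = np.column_stack([center[0] + radius * np.cos(th),
                           center[1] + radius * np.sin(th)])
    return Contour(points2d=pts, pose=identity_pose(z))


@pytest.fixture(scope="session")
def sphere_mesh() -> trimesh.Trimesh:
    return make_phantom(PhantomSpec(shape="sphere", size=(SPHERE_RADIUS,)))


@pytest.fixture(scope="session")
def sphere_spec() -> PhantomSpec:
    return PhantomSpec(shape="sphere", size=(SPHERE_RADIUS,),
                       in_plane_noise_sd=0.0, seed=0)


@pytest.fixture(scope="session")
def sphere_contours(sphere_mesh, sphere_spec):
    return slice_to_contours(sphere_mesh, sphere_spec)


@pytest.fixture(scope="session")
def atrium_mesh() -> trimesh.Trimesh:
    return make_phantom(PhantomSpec(shape="blended_atrium", size=(30.0, 25.0, 20.0)))


@pytest.fixture()
def two_square_stack():
    """Minimal valid contour set: two parallel squares plus default lids."""
    return make_contour_set([square_contour(10.0, 0.0), square_contour(10.0, 8.0)])
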