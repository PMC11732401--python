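"""Tubular meshing, attractors, TPS deformation, smoothing and Poisson fitting."""

import numpy as np
import pytest
import trimesh

from atriamesh._triangles import MeshProximity, brute_force_closest
from atriamesh.contours import make_contour_set
from atriamesh.phantom import CloudSpec, PhantomSpec, make_phantom, sample_cloud
from atriamesh.surface_reconstruction import (
    AttractorSet,
    ReconstructionConfig,
    apply_tps,
    as_mesh,
    attractor_targets,
    build_tubular_mesh,
    contour_to_mesh_distance,
    laplacian_smooth,
    poisson_reconstruct,
    remove_radial_outliers,
    sample_attractors,
    tps_fit,
)
from conftest import SPHERE_VOLUME_ML, circle_contour, square_contour


class TestTubularMesh:
    def test_two_squares_counts(self, two_square_stack):
        mesh = build_tubular_mesh(two_square_stack, 4)
        assert len(mesh.vertices) == 10
        assert len(mesh.faces) == 16
        assert mesh.euler_number == 2
        assert mesh.is_watertight
        assert mesh.is_winding_consistent

    @pytest.mark.parametrize("J", [2, 3, 4, 5])
    @pytest.mark.parametrize("K", [3, 5, 8])
    def test_face_count_formula(self, J, K):
        cs = make_contour_set([square_contour(10.0, 8.0 * j) for j in range(J)])
        mesh = build_tubular_mesh(cs, K)
        assert len(mesh.faces) == 2 * K * (J - 1) + 2 * K
        assert mesh.euler_number == 2
        assert len(mesh.edges) == 3 * len(mesh.faces)  # closed: no boundary

    def test_sphere_stack_vertices_near_sphere(self, sphere_contours, sphere_spec):
        mesh = build_tubular_mesh(sphere_contours, 64)
        r = np.linalg.norm(mesh.vertices, axis=1)
        assert np.abs(r - 30.0).max() < sphere_spec.slice_spacing

    def test_unordered_contours_rejected(self, two_square_stack):
        from atriamesh.contours import ContourSet

        with pytest.raises(ValueError):
            ContourSet(tuple(reversed(two_square_stack.contours)),
                       two_square_stack.lid_low, two_square_stack.lid_high)


def _fps_oracle(candidates: np.ndarray, n: int, seed: int) -> list[int]:
    """Independent exhaustive greedy farthest-point selection."""
    chosen = [seed]
    for _ in range(n - 1):
        best_i, best_d = None, -1.0
        for i in range(len(candidates)):
            d = min(np.linalg.norm(candidates[i] - candidates[j])
                    for j in chosen)
            if d > best_d + 1e-15:
                best_i, best_d = i, d
        chosen.append(best_i)
    return chosen


class TestFarthestPointSampling:
    def test_line_example(self):
        # 11 points on a line: after the seed 0, the far end 10, then midpoint 5
        cs = make_contour_set([square_contour(10.0, 0.0), square_contour(10.0, 8.0)])
        pts = np.column_stack([np.arange(11.0), np.zeros(11), np.zeros(11)])
        chosen = [0]
        min_d = np.linalg.norm(pts - pts[0], axis=1)
        for _ in range(2):
            nxt = int(np.argmax(min_d))
            chosen.append(nxt)
            min_d = np.minimum(min_d, np.linalg.norm(pts - pts[nxt], axis=1))
        assert chosen == [0, 10, 5]

    def test_single_attractor_is_seed(self, two_square_stack):
        att = sample_attractors(two_square_stack, 1, seed_index=2)
        cand = np.vstack([c.points2d for c in two_square_stack.contours])
        assert np.allclose(att.points[0][:2], cand[2])

    def test_matches_exhaustive_oracle(self, sphere_contours):
        att = sample_attractors(sphere_contours, 12, seed_index=3,
                                points_per_contour=20)
        from atriamesh.contours import resample_contour, to_global

        candidates = np.vstack([to_global(resample_contour(c, 20))
                                for c in sphere_contours.contours])
        assert len(candidates) <= 200
        oracle = _fps_oracle(candidates, 12, 3)
        assert np.allclose(att.points, candidates[oracle])

    def test_too_many_attractors_rejected(self, two_square_stack):
        with pytest.raises(ValueError):
            sample_attractors(two_square_stack, 10_000)


class TestAttractorTargets:
    def _flat_mesh(self):
        # two triangles tiling the unit square in z=0
        v = np.array([[0.0, 0, 0], [10, 0, 0], [10, 10, 0], [0, 10, 0]])
        f = np.array([[0, 1, 2], [0, 2, 3]])
        return as_mesh(v, f)

    def test_beta_zero_targets_are_closest_points(self):
        mesh = self._flat_mesh()
        att = AttractorSet(points=np.array([[5.0, 5.0, 5.0]]), source=[0])
        P, Q = attractor_targets(mesh, att, beta=0.0)
        assert np.allclose(P, [[5, 5, 0]])
        assert np.allclose(Q, P)

    def test_unit_step_along_direction(self):
        mesh = self._flat_mesh()
        att = AttractorSet(points=np.array([[5.0, 5.0, 5.0]]), source=[0])
        P, Q = attractor_targets(mesh, att, beta=1.0)
        assert np.allclose(Q, [[5, 5, 1.0]])

    def test_capture_within_beta(self):
        mesh = self._flat_mesh()
        att = AttractorSet(points=np.array([[5.0, 5.0, 0.5]]), source=[0])
        P, Q = attractor_targets(mesh, att, beta=1.0)
        assert np.allclose(Q, att.points)


class TestThinPlateSpline:
    def setup_method(self):
        rng = np.random.default_rng(11)
        self.P = rng.normal(size=(60, 3)) * 20
        self.rng = rng

    def test_rigid_motion_reproduced_exactly(self):
        from scipy.spatial.transform import Rotation

        R = Rotation.from_euler("xyz", [12, -7, 30], degrees=True).as_matrix()
        t = np.array([4.0, -2.0, 7.0])
        f = tps_fit(self.P, self.P @ R.T + t, lambda_=1e3)
        X = self.rng.normal(size=(1000, 3)) * 40
        assert np.abs(f(X) - (X @ R.T + t)).max() < 1e-8
        assert np.abs(f(self.P) - (self.P @ R.T + t)).max() < 1e-8

    def test_side_conditions(self):
        Q = self.P + self.rng.normal(size=self.P.shape) * 3
        f = tps_fit(self.P, Q, lambda_=10.0)
        Ph = np.hstack([np.ones((len(self.P), 1)), self.P])
        assert np.abs(Ph.T @ f.kernel_coefficients).max() < 1e-8

    def test_large_lambda_interpolates(self):
        Q = self.P + self.rng.normal(size=self.P.shape) * 3
        f = tps_fit(self.P, Q, lambda_=1e8)
        assert np.abs(f(self.P) - Q).max() < 1e-4

    def test_small_lambda_tends_to_affine_least_squares(self):
        Q = self.P + self.rng.normal(size=self.P.shape) * 3
        Ph = np.hstack([np.ones((len(self.P), 1)), self.P])
        A, *_ = np.linalg.lstsq(Ph, Q, rcond=None)
        f = tps_fit(self.P, Q, lambda_=1e-9)
        X = self.rng.normal(size=(200, 3)) * 30
        affine = np.hstack([np.ones((200, 1)), X]) @ A
        assert np.abs(f(X) - affine).max() < 1e-5

    def test_residual_monotone_in_lambda(self):
        Q = self.P + self.rng.normal(size=self.P.shape) * 3
        res = [np.sum((tps_fit(self.P, Q, lam)(self.P) - Q) ** 2)
               for lam in (1e-1, 1e1, 1e3, 1e5)]
        assert np.all(np.diff(res) < 0)

    def test_coplanar_points_rejected(self):
        flat = self.P.copy()
        flat[:, 2] = 0.0
        with pytest.raises(ValueError, match="rank|coplanar"):
            tps_fit(flat, flat, lambda_=1.0)


class TestApplyTps:
    def test_identity_field(self, sphere_mesh):
        P = sphere_mesh.vertices[::50]
        f = tps_fit(P, P, lambda_=1e3)
        out = apply_tps(f, sphere_mesh)
        assert np.abs(out.vertices - sphere_mesh.vertices).max() < 1e-6

    def test_translation_field(self, sphere_mesh):
        P = sphere_mesh.vertices[::50]
        f = tps_fit(P, P + np.array([3.0, 0, 0]), lambda_=1e3)
        out = apply_tps(f, sphere_mesh)
        assert np.allclose(out.vertices, sphere_mesh.vertices + [3, 0, 0],
                           atol=1e-6)

    def test_orientation_guard_rejects_flips(self):
        # a huge inward pull on a thin slab would invert faces
        slab = trimesh.creation.box(extents=(20.0, 20.0, 0.5))
        P = slab.vertices[:8]
        target = P * np.array([1.0, 1.0, -1e5])  # flips even at 1/64 scale
        f = tps_fit(P, target, lambda_=1e8)
        with pytest.warns(UserWarning, match="rejected"):
            out = apply_tps(f, as_mesh(slab.vertices, slab.faces))
        tri_old = slab.vertices[slab.faces]
        tri_new = out.vertices[out.faces]
        n_old = np.cross(tri_old[:, 1] - tri_old[:, 0], tri_old[:, 2] - tri_old[:, 0])
        n_new = np.cross(tri_new[:, 1] - tri_new[:, 0], tri_new[:, 2] - tri_new[:, 0])
        assert np.all(np.einsum("ij,ij->i", n_old, n_new) > 0)


class TestLaplacianSmoothing:
    def test_centroid_vertex_fixed(self):
        # apex already at the centroid of its neighbours stays put
        v = np.array([[1.0, 0, 0], [-0.5, 0.9, 0], [-0.5, -0.9, 0],
                      [0.0, 0.0, 0.0]])  # vertex 3 at centroid of 0,1,2
        f = np.array([[0, 1, 3], [1, 2, 3], [2, 0, 3], [0, 2, 1]])
        out = laplacian_smooth(as_mesh(v, f), w=0.5, iters=1)
        assert np.abs(out.vertices[3] - v[3]).max() < 1e-12

    def test_icosphere_shrinks_monotonically(self):
        mesh = trimesh.creation.icosphere(subdivisions=2, radius=1.0)
        mesh = as_mesh(mesh.vertices, mesh.faces)
        radii = [1.0]
        for _ in range(10):
            mesh = laplacian_smooth(mesh, w=0.5, iters=1)
            radii.append(float(np.linalg.norm(mesh.vertices, axis=1).mean()))
        assert np.all(np.diff(radii) < 0)

    def test_tetrahedron_apex_hand_computation(self):
        base = np.array([[1.0, 0, 0], [-0.5, 0.9, 0], [-0.5, -0.9, 0]])
        apex = np.array([0.2, 0.1, 2.0])
        v = np.vstack([base, apex[None]])
        f = np.array([[0, 1, 3], [1, 2, 3], [2, 0, 3], [0, 2, 1]])
        w = 0.4
        out = laplacian_smooth(as_mesh(v, f), w=w, iters=1)
        expected = apex + w * (base.mean(axis=0) - apex)
        assert np.allclose(out.vertices[3], expected, atol=1e-12)

    def test_topology_preserved(self, sphere_mesh):
        out = laplacian_smooth(sphere_mesh, w=0.3, iters=2)
        assert np.array_equal(out.faces, sphere_mesh.faces)
        assert len(out.vertices) == len(sphere_mesh.vertices)


class TestContourToMeshDistance:
    def test_exact_contours_give_zero(self, two_square_stack):
        mesh = build_tubular_mesh(two_square_stack, 4)
        d = contour_to_mesh_distance(mesh, two_square_stack)
        assert d.mean < 1e-9
        assert d.sd < 1e-9

    def test_unit_sphere_vs_radius_two_circle(self):
        unit = trimesh.creation.icosphere(subdivisions=4, radius=1.0)
        cs = make_contour_set([circle_contour(2.0, 0.0, n=100),
                               circle_contour(2.0, 0.1, n=100)],
                              lid_low=[0, 0, -1.0], lid_high=[0, 0, 1.5])
        d = contour_to_mesh_distance(as_mesh(unit.vertices, unit.faces), cs)
        assert abs(d.mean - 1.0) < 5e-3

    def test_accelerated_matches_brute_force(self, atrium_mesh):
        rng = np.random.default_rng(5)
        pts = rng.normal(scale=30.0, size=(100, 3))
        prox = MeshProximity(atrium_mesh.vertices, atrium_mesh.faces)
        c_fast, d_fast, _ = prox.query(pts)
        c_slow, d_slow, _ = brute_force_closest(
            pts, atrium_mesh.vertices[atrium_mesh.faces])
        assert np.abs(d_fast - d_slow).max() < 1e-9
        assert np.abs(c_fast - c_slow).max() < 1e-6


class TestReconstruct:
    def test_zero_iterations_returns_tubular_mesh(self, sphere_contours):
        cfg = ReconstructionConfig(max_outer_iters=0)
        mesh = build_tubular_mesh(sphere_contours, cfg.K)
        rec_cfg = ReconstructionConfig(max_outer_iters=0)
        from atriamesh.surface_reconstruction import reconstruct

        out = reconstruct(sphere_contours, rec_cfg)
        assert np.allclose(out.vertices, mesh.vertices)
        assert np.array_equal(out.faces, mesh.faces)

    def test_beta_validated_against_spacing(self, sphere_contours):
        from atriamesh.surface_reconstruction import reconstruct

        with pytest.raises(ValueError, match="beta"):
            reconstruct(sphere_contours, ReconstructionConfig(beta=100.0))


class TestPoissonReconstruction:
    def test_sphere_volume(self, sphere_mesh):
        cloud = sample_cloud(sphere_mesh, CloudSpec(
            n_points=4000, surface_noise_sd=0.0, seed=1))
        rec = poisson_reconstruct(cloud)
        assert rec.is_watertight
        assert abs(rec.volume / 1000.0 - SPHERE_VOLUME_ML) / SPHERE_VOLUME_ML < 0.05

    def test_outlier_robustness_after_removal(self, sphere_mesh):
        cloud = sample_cloud(sphere_mesh, CloudSpec(
            n_points=4000, surface_noise_sd=0.5, outlier_fraction=0.01, seed=2))
        kept = remove_radial_outliers(cloud)
        assert len(kept) < len(cloud)
        rec = poisson_reconstruct(kept)
        assert abs(rec.volume / 1000.0 - SPHERE_VOLUME_ML) / SPHERE_VOLUME_ML < 0.05

    def test_sparse_cloud_rejected(self):
        rng = np.random.default_rng(0)
        with pytest.raises(ValueError, match="500"):
            poisson_reconstruct(rng.normal(size=(400, 3)))

    def test_degenerate_cloud_rejected(self):
        rng = np.random.default_rng(0)
        flat = rng.normal(size=(600, 3))
        flat[:, 2] = 0.0
        with pytest.raises(ValueError, match="rank|degenerate"):
            poisson_reconstruct(flat)


class TestSubdivision:
    def test_butterfly_keeps_watertight_and_interpolates(self):
        from atriamesh._meshops import butterfly_subdivide

        ico = trimesh.creation.icosphere(subdivisions=1, radius=30.0)
        v, f = butterfly_subdivide(ico.vertices, ico.faces)
        out = as_mesh(v, f)
        assert out.is_watertight
        assert out.euler_number == 2
        assert len(f) == 4 * len(ico.faces)
        # old vertices interpolated exactly
        assert np.abs(v[: len(ico.vertices)] - ico.vertices).max() < 1e-12
        # new vertices bulge toward the smooth limit surface: closer to the
        # sphere than the chord midpoints they refine
        new_r = np.linalg.norm(v[len(ico.vertices):], axis=1)
        assert new_r.min() > 27.0
        assert np.abs(new_r - 30.0).mean() < 1.0

    def test_decimation_reaches_target_and_stays_closed(self):
        from atriamesh._meshops import quadric_decimate

        ico = trimesh.creation.icosphere(subdivisions=4, radius=30.0)
        v, f = quadric_decimate(ico.vertices, ico.faces, 1200)
        out = as_mesh(v, f)
        assert len(f) <= 1205
        assert out.is_watertight
        assert out.euler_number == 2
        # surface position preserved well
        r = np.linalg.norm(v, axis=1)
        assert np.abs(r - 30.0).max() < 0.5
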