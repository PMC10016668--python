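"""Closest-point exactness, Kabsch optimality and ICP convergence."""

from __future__ import annotations

import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation
from trimesh.proximity import closest_point_naive

from castmetric.errors import AlignmentError, DegenerateGeometryError, ParameterError
from castmetric.mesh import TriangleMesh
from castmetric.registration import (
    RigidTransform,
    SpatialIndex,
    closest_point_on_mesh,
    closest_point_on_triangles,
    estimate_rigid_transform,
    icp_align,
    sample_surface_points,
)
from castmetric.synthetic_data import (
    apply_molar_widening,
    apply_rigid_perturbation,
    random_rigid_transform,
)

from conftest import random_triangle_soup


class TestRigidTransform:
    def test_compose_inverse_roundtrip(self):
        rng = np.random.default_rng(0)
        a = random_rigid_transform(rng, 30, 10)
        b = random_rigid_transform(rng, 30, 10)
        pts = rng.uniform(-5, 5, (20, 3))
        np.testing.assert_allclose(
            a.compose(b).apply(pts), a.apply(b.apply(pts)), atol=1e-9
        )
        np.testing.assert_allclose(
            a.inverse().apply(a.apply(pts)), pts, atol=1e-9
        )

    def test_matrix_roundtrip(self):
        rng = np.random.default_rng(1)
        t = random_rigid_transform(rng, 45, 8)
        back = RigidTransform.from_matrix(t.to_matrix())
        np.testing.assert_allclose(back.rotation, t.rotation, atol=1e-12)
        np.testing.assert_allclose(back.translation, t.translation, atol=1e-12)

    def test_improper_rotation_rejected(self):
        with pytest.raises(ParameterError):
            RigidTransform(np.diag([1.0, 1.0, -1.0]), np.zeros(3))


class TestClosestPoint:
    def test_point_above_triangle_interior(self):
        tri = TriangleMesh(
            np.array([[0.0, 0, 0], [10, 0, 0], [0, 10, 0]]), np.array([[0, 1, 2]])
        )
        index = SpatialIndex(tri)
        foot, face, dist = closest_point_on_mesh(np.array([2.0, 2.0, 3.5]), index)
        assert dist == pytest.approx(3.5, abs=1e-12)
        np.testing.assert_allclose(foot, [2.0, 2.0, 0.0], atol=1e-12)
        assert face == 0

    def test_point_beyond_edge_lands_on_edge(self):
        tri = TriangleMesh(
            np.array([[0.0, 0, 0], [10, 0, 0], [0, 10, 0]]), np.array([[0, 1, 2]])
        )
        index = SpatialIndex(tri)
        foot, _, dist = closest_point_on_mesh(np.array([5.0, -4.0, 0.0]), index)
        np.testing.assert_allclose(foot, [5.0, 0.0, 0.0], atol=1e-12)
        assert dist == pytest.approx(4.0, abs=1e-12)

    def test_mesh_vertex_has_zero_distance(self, small_arch):
        index = SpatialIndex(small_arch)
        _, _, dist = closest_point_on_mesh(small_arch.vertices[123], index)
        assert dist < 1e-12

    @pytest.mark.parametrize("n_faces", [37, 160, 450])
    def test_matches_exhaustive_search_exactly(self, n_faces):
        """Tree-accelerated queries equal brute force over every triangle."""
        rng = np.random.default_rng(n_faces)
        soup = random_triangle_soup(rng, n_faces)
        index = SpatialIndex(soup, brute_force_below=0)
        pts = rng.uniform(-3, 13, (100, 3))
        _, _, dist = index.query(pts)
        # oracle 1: exhaustive scan with our kernel
        flat = np.repeat(pts, n_faces, axis=0)
        tris = np.tile(soup.triangles, (len(pts), 1, 1))
        feet = closest_point_on_triangles(flat, tris).reshape(len(pts), n_faces, 3)
        exhaustive = np.linalg.norm(feet - pts[:, None], axis=2).min(axis=1)
        np.testing.assert_allclose(dist, exhaustive, atol=1e-12)
        # oracle 2: independent implementation
        _, naive, _ = closest_point_naive(soup.to_trimesh(), pts)
        np.testing.assert_allclose(dist, naive, atol=1e-9)

    def test_edge_tie_resolves_to_smaller_face_index(self):
        # two faces sharing the edge x=0..10, y=0; query directly above it
        v = np.array([[0.0, 0, 0], [10, 0, 0], [0, 5, 0], [0, -5, 0]])
        mesh = TriangleMesh(v, np.array([[0, 1, 2], [0, 3, 1]]))
        index = SpatialIndex(mesh)
        _, face, dist = closest_point_on_mesh(np.array([5.0, 0.0, 2.0]), index)
        assert dist == pytest.approx(2.0, abs=1e-12)
        assert face == 0


class TestEstimateRigidTransform:
    def test_identity_for_equal_clouds(self):
        pts = np.random.default_rng(0).uniform(-5, 5, (12, 3))
        t = estimate_rigid_transform(pts, pts)
        np.testing.assert_allclose(t.rotation, np.eye(3), atol=1e-12)
        np.testing.assert_allclose(t.translation, np.zeros(3), atol=1e-12)

    def test_exact_recovery_of_known_motion(self):
        rng = np.random.default_rng(4)
        src = rng.uniform(-5, 5, (30, 3))
        truth = random_rigid_transform(rng, 60, 20)
        est = estimate_rigid_transform(src, truth.apply(src))
        np.testing.assert_allclose(est.rotation, truth.rotation, atol=1e-9)
        np.testing.assert_allclose(est.translation, truth.translation, atol=1e-9)

    def test_reflection_rejected_and_still_optimal(self):
        """A mirrored cloud admits no perfect rigid fit; the estimate must be
        a proper rotation and still beat random proper rotations."""
        rng = np.random.default_rng(5)
        src = rng.uniform(-5, 5, (10, 3))
        tgt = src * np.array([1.0, 1.0, -1.0])  # reflection
        est = estimate_rigid_transform(src, tgt)
        assert np.linalg.det(est.rotation) == pytest.approx(1.0, abs=1e-9)
        best = np.mean(np.sum((est.apply(src) - tgt) ** 2, axis=1))
        assert best > 1e-6
        for rot in Rotation.random(1000, rng=np.random.default_rng(6)):
            cand = RigidTransform(rot.as_matrix(), np.zeros(3))
            moved = cand.apply(src)
            shift = (tgt - moved).mean(axis=0)
            residual = np.mean(np.sum((moved + shift - tgt) ** 2, axis=1))
            assert best <= residual + 1e-12

    def test_degenerate_inputs_rejected(self):
        line = np.array([[0.0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]])
        with pytest.raises(DegenerateGeometryError):
            estimate_rigid_transform(line, line + 1.0)
        with pytest.raises(DegenerateGeometryError):
            estimate_rigid_transform(line[:2], line[:2])


class TestIcp:
    def test_self_alignment_is_identity(self, small_arch):
        res = icp_align(small_arch, small_arch, sample_size=2000, seed=0)
        assert res.converged
        assert res.iterations <= 2
        assert res.rms < 1e-9
        np.testing.assert_allclose(res.transform.rotation, np.eye(3), atol=1e-6)

    def test_recovers_rigid_perturbation(self, small_arch):
        rng = np.random.default_rng(8)
        pert = random_rigid_transform(rng, 10, 5)
        test = apply_rigid_perturbation(small_arch, pert)
        res = icp_align(test, small_arch, sample_size=2000, seed=1)
        realigned = res.transform.apply(test.vertices)
        assert np.abs(realigned - small_arch.vertices).max() < 1e-3

    def test_rms_trace_monotone_nonincreasing(self, small_arch):
        rng = np.random.default_rng(9)
        pert = random_rigid_transform(rng, 8, 4)
        deformed = apply_molar_widening(small_arch, 0.05)
        test = apply_rigid_perturbation(deformed, pert)
        res = icp_align(test, small_arch, sample_size=2000, seed=2)
        trace = np.asarray(res.rms_trace)
        assert np.all(np.diff(trace) <= 1e-12)

    def test_matches_nelder_mead_oracle_on_deformed_mesh(self, small_arch):
        """ICP's converged RMS on a fixed probe is within 10% of a direct
        6-parameter rigid-motion optimisation of the same objective (probe
        large enough that the optimiser cannot overfit its 6 DOF)."""
        rng = np.random.default_rng(10)
        pert = random_rigid_transform(rng, 5, 2)
        test = apply_rigid_perturbation(
            apply_molar_widening(small_arch, 0.05), pert
        )
        res = icp_align(test, small_arch, sample_size=2000, seed=3)
        index = SpatialIndex(small_arch)
        probe = sample_surface_points(test, 200, np.random.default_rng(11))

        def rms_for(params: np.ndarray) -> float:
            t = RigidTransform(
                Rotation.from_rotvec(params[:3]).as_matrix(), params[3:]
            )
            _, _, d = index.query(t.apply(probe))
            return float(np.sqrt(np.mean(d**2)))

        x0 = np.concatenate(
            [
                Rotation.from_matrix(res.transform.rotation).as_rotvec(),
                res.transform.translation,
            ]
        )
        oracle = minimize(rms_for, x0, method="Nelder-Mead", options={"maxiter": 800})
        icp_rms = rms_for(x0)
        assert icp_rms <= 1.1 * max(oracle.fun, 1e-12)

    def test_pose_invariance_within_basin(self, small_arch):
        """Different start poses converge to transforms giving the same
        deviations (< 1 µm in mean absolute deviation)."""
        deformed = apply_molar_widening(small_arch, 0.05)
        means = []
        for s in (21, 22):
            pert = random_rigid_transform(np.random.default_rng(s), 10, 5)
            test = apply_rigid_perturbation(deformed, pert)
            res = icp_align(test, small_arch, sample_size=3000, seed=4)
            index = SpatialIndex(small_arch)
            _, _, d = index.query(res.transform.apply(test.vertices))
            means.append(d.mean())
        assert abs(means[0] - means[1]) * 1000 < 1.0  # µm

    def test_unreachable_reference_raises(self, small_arch):
        far = apply_rigid_perturbation(
            small_arch, RigidTransform(np.eye(3), np.array([500.0, 0, 0]))
        )
        with pytest.raises(AlignmentError):
            icp_align(far, small_arch, sample_size=500, coarse_init=False)
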