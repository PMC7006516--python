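"""Geometry primitives: rigid transforms, mirroring, frames, voxelization,
nearest-neighbour queries."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from footshape.geometry import (
    DegenerateFrameError,
    GeometryError,
    PointCloud,
    RigidTransform,
    TransformError,
    TriangleMesh,
    WatertightnessError,
    anatomical_frame_from_landmarks,
    apply_transform,
    frame_to_transform,
    mirror,
    nearest_neighbour_distances,
    voxelize,
)


def rot(axis, deg):
    return Rotation.from_euler(axis, deg, degrees=True).as_matrix()


class TestRigidTransform:
    def test_identity_preserves_cloud(self, random_cloud):
        cloud = random_cloud(20)
        out = apply_transform(cloud, RigidTransform.identity())
        np.testing.assert_array_equal(out.points, cloud.points)

    def test_pure_translation(self):
        cloud = PointCloud([[0, 0, 0], [1, 1, 1], [2, 2, 2], [3, 3, 3]])
        T = RigidTransform.from_rotation_translation(np.eye(3), [1, 2, 3])
        out = apply_transform(cloud, T)
        np.testing.assert_allclose(out.points[0], [1, 2, 3])

    def test_roundtrip_through_analytic_inverse(self, random_cloud):
        cloud = random_cloud(20)
        T = RigidTransform.from_rotation_translation(rot("z", 37.0), [4, -2, 9])
        back = apply_transform(apply_transform(cloud, T), T.inverse())
        np.testing.assert_allclose(back.points, cloud.points, atol=1e-10)

    def test_preserves_pairwise_distances(self, random_cloud):
        cloud = random_cloud(30)
        T = RigidTransform.from_rotation_translation(rot("y", 63.0), [1, 2, 3])
        out = apply_transform(cloud, T)
        d0 = np.linalg.norm(cloud.points[:, None] - cloud.points[None], axis=2)
        d1 = np.linalg.norm(out.points[:, None] - out.points[None], axis=2)
        np.testing.assert_allclose(d0, d1, atol=1e-9)

    @pytest.mark.parametrize(
        "matrix",
        [
            np.diag([-1.0, 1, 1, 1]),                      # reflection
            np.diag([2.0, 0.5, 1, 1]),                     # scaling
            np.array([[1, 0, 0, 0], [0, 1, 0, 0],
                      [0, 0, 1, 0], [0, 0, 0, 2.0]]),      # bad bottom row
        ],
    )
    def test_non_rigid_matrices_rejected(self, matrix):
        with pytest.raises(TransformError):
            RigidTransform(matrix)

    def test_compose_matches_sequential_application(self, random_cloud):
        cloud = random_cloud(10)
        A = RigidTransform.from_rotation_translation(rot("x", 20.0), [1, 0, 0])
        B = RigidTransform.from_rotation_translation(rot("z", -45.0), [0, 5, 0])
        seq = apply_transform(apply_transform(cloud, A), B)
        comp = apply_transform(cloud, B.compose(A))
        np.testing.assert_allclose(seq.points, comp.points, atol=1e-12)


class TestMirror:
    def test_involution(self, random_cloud):
        cloud = random_cloud(15)
        np.testing.assert_array_equal(
            mirror(mirror(cloud, "z"), "z").points, cloud.points
        )

    def test_coordinate_negated(self):
        cloud = PointCloud([[1, 2, 3]] * 4)
        np.testing.assert_array_equal(mirror(cloud, "z").points[0], [1, 2, -3])

    def test_side_flips(self, bone_template):
        tpl, _ = bone_template
        left = mirror(tpl.with_vertices(tpl.vertices), "z")
        assert tpl.side == "right" and left.side == "left"

    def test_mesh_volume_preserved(self, sphere5):
        assert abs(mirror(sphere5, "z").volume - sphere5.volume) < 1e-9
        assert mirror(sphere5, "z").volume > 0

    def test_unknown_axis(self, random_cloud):
        with pytest.raises(GeometryError):
            mirror(random_cloud(), "w")


class TestAnatomicalFrame:
    def test_standard_basis(self):
        f = anatomical_frame_from_landmarks([0, 0, 0], [1, 0, 0], [0, 1, 0])
        np.testing.assert_allclose(f.axes, np.eye(3), atol=1e-12)

    def test_axes_orthonormal_for_arbitrary_triple(self):
        f = anatomical_frame_from_landmarks([1, 2, 3], [4, 0, -1], [-2, 5, 0.5])
        np.testing.assert_allclose(f.axes @ f.axes.T, np.eye(3), atol=1e-12)
        np.testing.assert_allclose(np.cross(f.axes[0], f.axes[1]), f.axes[2],
                                   atol=1e-12)

    def test_equivariance_under_rotation(self):
        pts = [np.array([1.0, 2, 3]), np.array([4.0, 0, -1]),
               np.array([-2.0, 5, 0.5])]
        R = rot("y", 28.0) @ rot("x", -13.0)
        f0 = anatomical_frame_from_landmarks(*pts)
        f1 = anatomical_frame_from_landmarks(*(R @ p for p in pts))
        np.testing.assert_allclose(f1.axes, f0.axes @ R.T, atol=1e-9)

    def test_collinear_rejected(self):
        with pytest.raises(DegenerateFrameError):
            anatomical_frame_from_landmarks([0, 0, 0], [1, 0, 0], [2, 0, 0])

    def test_frame_to_transform_identity_and_translation(self):
        f = anatomical_frame_from_landmarks([0, 0, 0], [1, 0, 0], [0, 1, 0])
        np.testing.assert_allclose(frame_to_transform(f).matrix, np.eye(4),
                                   atol=1e-12)
        f5 = anatomical_frame_from_landmarks([5, 0, 0], [6, 0, 0], [5, 1, 0])
        np.testing.assert_allclose(frame_to_transform(f5).translation,
                                   [-5, 0, 0], atol=1e-12)

    def test_transform_maps_defining_landmarks_canonically(self):
        p0, p1, p2 = [1.0, -2, 3], [4.0, 1, 2], [0.0, 4, 5]
        T = frame_to_transform(anatomical_frame_from_landmarks(p0, p1, p2))
        mapped = T.apply(np.vstack([p0, p1, p2]))
        np.testing.assert_allclose(mapped[0], [0, 0, 0], atol=1e-9)
        assert mapped[1][0] > 0
        np.testing.assert_allclose(mapped[1][1:], [0, 0], atol=1e-9)


class TestVoxelize:
    def test_cube_exact_count(self, unit_cube):
        grid = voxelize(unit_cube, 1.0)
        assert grid.occupied_count == 1000

    def test_cube_volume_converges(self, unit_cube):
        assert abs(voxelize(unit_cube, 0.25).volume - 1000.0) < 1e-9

    def test_sphere_volume_within_5_percent(self, sphere5):
        grid = voxelize(sphere5, 0.5)
        analytic = 4.0 / 3.0 * np.pi * 125.0
        assert abs(grid.volume - analytic) / analytic < 0.05

    def test_non_watertight_rejected(self, unit_cube):
        holey = TriangleMesh(unit_cube.vertices, unit_cube.faces[:-1])
        with pytest.raises(WatertightnessError) as exc:
            voxelize(holey, 1.0)
        assert exc.value.open_edge_count > 0

    def test_bad_voxel_size(self, unit_cube):
        with pytest.raises(GeometryError):
            voxelize(unit_cube, 0.0)


class TestNearestNeighbour:
    def test_self_distances_zero(self, random_cloud):
        cloud = random_cloud(40)
        np.testing.assert_array_equal(
            nearest_neighbour_distances(cloud, cloud), np.zeros(40)
        )

    def test_simple_case(self):
        src = PointCloud([[0, 0, 0]] * 4)
        tgt = PointCloud([[1, 0, 0], [0, 2, 0], [9, 9, 9], [5, 5, 5]])
        np.testing.assert_allclose(
            nearest_neighbour_distances(src, tgt), np.ones(4)
        )

    def test_matches_brute_force(self, random_cloud):
        src = random_cloud(200, seed=11)
        tgt = random_cloud(300, seed=12)
        fast = nearest_neighbour_distances(src, tgt)
        brute = np.linalg.norm(
            src.points[:, None] - tgt.points[None], axis=2
        ).min(axis=1)
        np.testing.assert_allclose(fast, brute, atol=1e-12)


class TestValidation:
    def test_too_few_points_rejected(self):
        with pytest.raises(GeometryError):
            PointCloud([[0, 0, 0], [1, 1, 1], [2, 2, 2]])

    def test_non_finite_rejected(self):
        with pytest.raises(GeometryError):
            PointCloud([[0, 0, 0], [1, 1, 1], [2, 2, 2], [np.nan, 0, 0]])

    def test_face_index_out_of_range(self):
        with pytest.raises(GeometryError):
            TriangleMesh(np.zeros((4, 3)), [[0, 1, 9]])
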