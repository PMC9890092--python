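"""Forward kinematics, joint axis systems and joint-centre fitting."""

import numpy as np
import pytest
from scipy.optimize import minimize

from ossomech._transforms import rotation_about_axis, rotation_part, transform_point
from ossomech.errors import DegenerateInputError, SingularPoseError, ValidationError
from ossomech.kinematics import apply_pose, fit_joint_centre, joint_axis_world, landmark_world
from ossomech.model import Pose

from conftest import make_forelimb_model, make_hinge_model


# ----------------------------------------------------------- centre fitting
class TestFitJointCentre:
    def test_exact_circle_recovered(self):
        ang = np.linspace(0, 2 * np.pi, 8, endpoint=False)
        pts = 0.025 * np.column_stack([np.cos(ang), np.sin(ang), np.zeros(8)])
        fit = fit_joint_centre(pts, mode="circle")
        np.testing.assert_allclose(fit.centre, 0.0, atol=1e-12)
        assert fit.radius == pytest.approx(0.025, abs=1e-12)
        assert fit.rms_residual < 1e-12

    def test_three_points_give_circumscribed_circle(self):
        # circumcentre of a 3-4-5 right triangle is the hypotenuse midpoint
        pts = np.array([[0, 0, 0], [3.0, 0, 0], [0, 4.0, 0]])
        fit = fit_joint_centre(pts, mode="circle")
        np.testing.assert_allclose(fit.centre, [1.5, 2.0, 0.0], atol=1e-9)
        assert fit.radius == pytest.approx(2.5, abs=1e-9)

    def test_noisy_sphere_matches_independent_optimizer(self, rng):
        true_c = np.array([0.01, -0.02, 0.03])
        true_r = 0.04
        dirs = rng.normal(size=(40, 3))
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        pts = true_c + true_r * dirs + rng.normal(scale=0.001, size=(40, 3))
        fit = fit_joint_centre(pts, mode="sphere")
        assert np.linalg.norm(fit.centre - true_c) < 0.001

        # independent oracle: direct minimization of radial variance from the centroid
        def cost(c):
            d = np.linalg.norm(pts - c, axis=1)
            return np.sum((d - d.mean()) ** 2)

        ora = minimize(cost, pts.mean(axis=0), method="Nelder-Mead",
                       options={"xatol": 1e-10, "fatol": 1e-14, "maxiter": 5000})
        assert np.linalg.norm(fit.centre - ora.x) < 1e-4

    @pytest.mark.parametrize("pts,mode", [
        (np.array([[0, 0, 0], [1, 0, 0]]), "circle"),
        (np.array([[0, 0, 0], [1, 0, 0], [2.0, 0, 0]]), "circle"),
        (np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [1.0, 1, 0]]), "sphere"),
    ])
    def test_degenerate_inputs_raise(self, pts, mode):
        with pytest.raises(DegenerateInputError):
            fit_joint_centre(pts, mode=mode)


# ------------------------------------------------------------------- posing
class TestApplyPose:
    def test_reference_pose_is_rest_composition(self, forelimb_model):
        world = apply_pose(forelimb_model, forelimb_model.reference_pose())
        np.testing.assert_allclose(world["scapulocoracoid"], np.eye(4), atol=1e-15)
        np.testing.assert_allclose(world["humerus"][:3, 3], [0.1, 0, 0], atol=1e-15)
        np.testing.assert_allclose(world["antebrachium"][:3, 3], [0.4, 0, 0], atol=1e-15)

    def test_single_hinge_rotates_landmark(self):
        model = make_hinge_model([-0.2, 0.1, 0], [0.15, 0, 0])
        pose = model.reference_pose().with_angle("hinge", "flexion", 90.0)
        lm = landmark_world(model, pose, "dist", "tip")
        np.testing.assert_allclose(lm, [0.0, 0.1, 0.0], atol=1e-12)

    def test_composition_order_matches_matrix_product(self, forelimb_model):
        """Protraction after adduction must equal the explicit product of the
        two axis-angle matrices in the declared proximal-then-floating order."""
        pose = (forelimb_model.reference_pose()
                .with_angle("glenohumeral", "adduction", 90.0)
                .with_angle("glenohumeral", "protraction", 20.0))
        world = apply_pose(forelimb_model, pose)
        a1 = np.array([0.0, 1.0, 0.0])  # proximal (adduction) axis, world @ ref
        f0 = np.array([0.0, 0.0, 1.0])  # floating (protraction) axis, world @ ref
        Q1 = rotation_about_axis(a1, np.deg2rad(90.0))
        Q2 = rotation_about_axis(Q1 @ f0, np.deg2rad(20.0))
        np.testing.assert_allclose(rotation_part(world["humerus"]), Q2 @ Q1, atol=1e-12)

    def test_rigid_invariance_and_proper_rotations(self, forelimb_model, rng):
        ref = apply_pose(forelimb_model, forelimb_model.reference_pose())
        ref_dist = {}
        for seg in forelimb_model.segments:
            names = sorted(seg.landmarks)
            for i, a in enumerate(names):
                for b in names[i + 1:]:
                    ref_dist[(seg.name, a, b)] = np.linalg.norm(
                        seg.landmarks[a] - seg.landmarks[b])
        for _ in range(20):
            pose = Pose({k: rng.uniform(-60, 60) for k in forelimb_model.dof_keys()})
            world = apply_pose(forelimb_model, pose)
            for T in world.values():
                assert abs(np.linalg.det(T[:3, :3]) - 1.0) < 1e-9
            for (seg, a, b), d0 in ref_dist.items():
                pa = landmark_world(forelimb_model, pose, seg, a, world)
                pb = landmark_world(forelimb_model, pose, seg, b, world)
                assert abs(np.linalg.norm(pa - pb) - d0) < 1e-9

    def test_deterministic_and_pure(self, forelimb_model):
        pose = Pose({k: 17.0 for k in forelimb_model.dof_keys()})
        w1 = apply_pose(forelimb_model, pose)
        w2 = apply_pose(forelimb_model, pose)
        for k in w1:
            assert np.array_equal(w1[k], w2[k])

    def test_round_trip_inverse_sequence_restores_reference(self, forelimb_model, rng):
        """Negating the DOF angles and applying them in reverse order (distal
        axis first) about the posed axes undoes the joint rotation exactly."""
        from ossomech.kinematics import joint_rotation

        j = forelimb_model.joint("glenohumeral")
        for _ in range(10):
            pose = forelimb_model.reference_pose()
            for role in ("proximal", "floating", "distal"):
                pose = pose.with_angle("glenohumeral", j.dof(role).name,
                                       rng.uniform(-70, 70))
            world_prox = np.eye(4)
            base = world_prox @ forelimb_model.segment("humerus").rest_transform
            Q = joint_rotation(forelimb_model, "glenohumeral", pose, world_prox, base)
            th = {role: np.deg2rad(pose.angle("glenohumeral", j.dof(role).name))
                  for role in ("proximal", "floating", "distal")}
            a1 = j.dof("proximal").axis_direction
            Q1 = rotation_about_axis(a1, th["proximal"])
            a2 = Q1 @ j.dof("floating").axis_direction
            Q2 = rotation_about_axis(a2, th["floating"])
            a3 = Q2 @ Q1 @ j.dof("distal").axis_direction
            Qrev = (rotation_about_axis(a1, -th["proximal"])
                    @ rotation_about_axis(a2, -th["floating"])
                    @ rotation_about_axis(a3, -th["distal"]))
            np.testing.assert_allclose(Qrev @ Q, np.eye(3), atol=1e-9)

    def test_unknown_dof_rejected(self, forelimb_model):
        pose = forelimb_model.reference_pose()
        bad = Pose({**pose.angles, ("glenohumeral", "wiggle"): 5.0})
        with pytest.raises(ValidationError):
            apply_pose(forelimb_model, bad)


# -------------------------------------------------------------- joint axes
class TestJointAxisWorld:
    def test_reference_directions_unchanged(self, forelimb_model):
        pose = forelimb_model.reference_pose()
        _, d = joint_axis_world(forelimb_model, pose, "glenohumeral", "adduction")
        np.testing.assert_allclose(d, [0, 1, 0], atol=1e-12)
        _, d = joint_axis_world(forelimb_model, pose, "glenohumeral", "medial_rotation")
        np.testing.assert_allclose(d, [1, 0, 0], atol=1e-12)
        _, d = joint_axis_world(forelimb_model, pose, "glenohumeral", "protraction")
        np.testing.assert_allclose(d, [0, 0, 1], atol=1e-12)

    def test_distal_axis_follows_proximal_rotation(self, forelimb_model):
        pose = forelimb_model.reference_pose().with_angle("glenohumeral", "adduction", 30.0)
        _, d = joint_axis_world(forelimb_model, pose, "glenohumeral", "medial_rotation")
        expected = rotation_about_axis([0, 1, 0], np.deg2rad(30.0)) @ np.array([1.0, 0, 0])
        np.testing.assert_allclose(d, expected, atol=1e-12)

    def test_floating_axis_perpendicular_to_companions(self, forelimb_model, rng):
        for _ in range(25):
            pose = Pose({k: rng.uniform(-50, 50) for k in forelimb_model.dof_keys()})
            world = apply_pose(forelimb_model, pose)
            for joint in ("glenohumeral", "elbow"):
                j = forelimb_model.joint(joint)
                _, f = joint_axis_world(forelimb_model, pose, joint,
                                        j.dof("floating").name, world)
                _, a1 = joint_axis_world(forelimb_model, pose, joint,
                                         j.dof("proximal").name, world)
                _, a3 = joint_axis_world(forelimb_model, pose, joint,
                                         j.dof("distal").name, world)
                assert abs(f @ a1) < 1e-9
                assert abs(f @ a3) < 1e-9

    def test_gimbal_degeneracy_raises(self, forelimb_model):
        # 90 deg about the floating axis aligns the proximal and distal axes
        pose = forelimb_model.reference_pose().with_angle("glenohumeral",
                                                          "protraction", 90.0)
        with pytest.raises(SingularPoseError):
            joint_axis_world(forelimb_model, pose, "glenohumeral", "protraction")

    def test_axes_pass_through_posed_centre(self, forelimb_model):
        pose = forelimb_model.reference_pose().with_angle("glenohumeral", "adduction", 45.0)
        pt, _ = joint_axis_world(forelimb_model, pose, "elbow", "flexion")
        world = apply_pose(forelimb_model, pose)
        expected = transform_point(world["humerus"], forelimb_model.joint("elbow").centre)
        np.testing.assert_allclose(pt, expected, atol=1e-12)
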