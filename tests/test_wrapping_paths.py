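"""Cylinder wrapping geometry and strand path lengths."""

import numpy as np
import pytest

from ossomech._transforms import make_transform, rotation_about_axis
from ossomech.errors import InfeasibleAttachmentError
from ossomech.model import WrapCylinder
from ossomech.paths import strand_length
from ossomech.wrapping import solve_wrap_single

from conftest import make_hinge_model

Z_FRAME = make_transform(np.eye(3), np.zeros(3))
SIDE_Y = np.array([0.0, 1.0, 0.0])


def planar_wrap_length(d, r):
    """Closed-form symmetric planar tangent-arc-tangent length."""
    return 2 * np.sqrt(d * d - r * r) + r * (np.pi - 2 * np.arccos(r / d))


class TestSolveWrapSingle:
    def test_symmetric_planar_wrap_closed_form(self):
        res = solve_wrap_single(np.array([-5.0, 0, 0]), np.array([5.0, 0, 0]),
                                Z_FRAME, 1.0, SIDE_Y)
        assert res.wrap_active
        assert res.length == pytest.approx(planar_wrap_length(5.0, 1.0), abs=1e-9)

    def test_non_penetrating_segment_stays_straight(self):
        res = solve_wrap_single(np.array([-5.0, 3, 0]), np.array([5.0, 3, 0]),
                                Z_FRAME, 1.0, SIDE_Y)
        assert not res.wrap_active
        assert res.length == pytest.approx(10.0, abs=1e-12)

    def test_length_continuous_at_grazing_tangency(self):
        eps = 1e-6
        inside = solve_wrap_single(np.array([-5.0, 1 - eps, 0]),
                                   np.array([5.0, 1 - eps, 0]), Z_FRAME, 1.0, SIDE_Y)
        outside = solve_wrap_single(np.array([-5.0, 1 + eps, 0]),
                                    np.array([5.0, 1 + eps, 0]), Z_FRAME, 1.0, SIDE_Y)
        assert inside.wrap_active and not outside.wrap_active
        assert abs(inside.length - outside.length) < 1e-9

    def test_side_hint_selects_deflection_side(self):
        up = solve_wrap_single(np.array([-3.0, 0, 0]), np.array([3.0, 0, 0]),
                               Z_FRAME, 1.0, np.array([0.0, 1.0, 0.0]))
        down = solve_wrap_single(np.array([-3.0, 0, 0]), np.array([3.0, 0, 0]),
                                 Z_FRAME, 1.0, np.array([0.0, -1.0, 0.0]))
        assert up.length == pytest.approx(down.length, abs=1e-12)
        assert up.path[:, 1].max() > 0.5
        assert down.path[:, 1].min() < -0.5

    def test_helical_wrap_with_axial_offset(self):
        # z-offset endpoints: L = hypot(planar length, dz)
        dz = 2.0
        res = solve_wrap_single(np.array([-5.0, 0, 0]), np.array([5.0, 0, dz]),
                                Z_FRAME, 1.0, SIDE_Y)
        assert res.length == pytest.approx(
            np.hypot(planar_wrap_length(5.0, 1.0), dz), abs=1e-9)

    def test_endpoint_inside_cylinder_rejected(self):
        with pytest.raises(InfeasibleAttachmentError):
            solve_wrap_single(np.array([0.5, 0, 0]), np.array([5.0, 0, 0]),
                              Z_FRAME, 1.0, SIDE_Y)

    def test_band_warning_when_arc_leaves_half_length(self):
        with pytest.warns(UserWarning, match="half_length"):
            solve_wrap_single(np.array([-5.0, 0, 9.0]), np.array([5.0, 0, 11.0]),
                              Z_FRAME, 1.0, SIDE_Y, half_length=1.0)

    def test_invariant_under_rigid_motion(self, rng):
        p = np.array([-4.0, 0.2, 0.3])
        q = np.array([4.0, -0.1, -0.5])
        base = solve_wrap_single(p, q, Z_FRAME, 1.0, SIDE_Y)
        R = rotation_about_axis(rng.normal(size=3), 1.1)
        t = rng.normal(size=3)
        T = make_transform(R, t)
        moved = solve_wrap_single(R @ p + t, R @ q + t, T @ Z_FRAME, 1.0, SIDE_Y)
        assert moved.length == pytest.approx(base.length, rel=1e-12)

    def test_uniform_scaling_scales_length(self):
        base = solve_wrap_single(np.array([-5.0, 0, 0.4]), np.array([5.0, 0.2, 0]),
                                 Z_FRAME, 1.0, SIDE_Y)
        k = 3.7
        scaled = solve_wrap_single(np.array([-5.0, 0, 0.4]) * k,
                                   np.array([5.0, 0.2, 0]) * k, Z_FRAME, k, SIDE_Y)
        assert scaled.length == pytest.approx(k * base.length, rel=1e-12)


class TestStrandLength:
    def test_no_obstacles_is_straight_distance(self):
        model = make_hinge_model([-0.2, 0.1, 0.05], [0.15, -0.02, 0.0])
        sp = strand_length(model, model.reference_pose(), model.muscle("MUS").strands[0])
        expected = np.linalg.norm(np.array([-0.2, 0.1, 0.05]) - [0.15, -0.02, 0.0])
        assert sp.length == pytest.approx(expected, abs=1e-12)
        assert not sp.wrap_active

    def test_coaxial_wrap_length_affine_in_angle(self):
        """With a cylinder coaxial to the hinge and the wrap always active,
        dL/dtheta = -radius per radian of positive rotation here, so length
        is affine in the swept angle with slope magnitude = radius."""
        r = 0.03
        cyl = WrapCylinder("cx", "prox", make_transform(np.eye(3), np.zeros(3)),
                           radius=r, half_length=0.5, side=np.array([0.0, 1.0, 0.0]))
        model = make_hinge_model([-0.06, 0.0, 0.0], [0.065, 0.0, 0.0],
                                 cylinders=[cyl], obstacles=["cx"])
        strand = model.muscle("MUS").strands[0]
        thetas = np.arange(-40.0, 41.0, 10.0)
        Ls = []
        for th in thetas:
            pose = model.reference_pose().with_angle("hinge", "flexion", th)
            sp = strand_length(model, pose, strand)
            assert sp.wrap_active
            Ls.append(sp.length)
        slopes = np.diff(Ls) / np.deg2rad(np.diff(thetas))
        np.testing.assert_allclose(np.abs(slopes), r, atol=1e-10)

    def test_two_disjoint_cylinders_decompose(self):
        """Far-apart equal cylinders on one leg: the optimal chain uses the
        common external tangent, so the total length equals the analytic
        tangent + arc + bridge + arc + tangent construction."""
        c1, c2, r = -15.0, 15.0, 1.0
        cylA = WrapCylinder("cA", "prox", make_transform(np.eye(3), [c1, 0, 0]),
                            radius=r, half_length=5.0, side=SIDE_Y)
        cylB = WrapCylinder("cB", "prox", make_transform(np.eye(3), [c2, 0, 0]),
                            radius=r, half_length=5.0, side=SIDE_Y)
        model = make_hinge_model([-30.0, 0.0, 0.0], [30.0, 0.0, 0.0],
                                 cylinders=[cylA, cylB], obstacles=["cA", "cB"])
        sp = strand_length(model, model.reference_pose(), model.muscle("MUS").strands[0])
        # analytic: by symmetry the bridge is the common tangent y = r
        d = 15.0  # endpoint to nearest cylinder centre
        tangent = np.sqrt(d * d - r * r)
        beta = np.arccos(r / d)
        arc = (np.pi / 2.0) - beta + np.pi / 2.0 - np.pi / 2.0  # entry angle to pi/2
        arc = (np.pi - beta) - np.pi / 2.0
        bridge = (c2 - c1)
        expected = 2 * tangent + 2 * r * arc + bridge
        assert sp.length == pytest.approx(expected, rel=1e-9)

    def test_via_points_are_hard_anchors(self):
        model = make_hinge_model([-0.2, 0.0, 0.0], [0.2, 0.0, 0.0])
        strand = model.muscle("MUS").strands[0]
        strand.via_points = [type(strand.origin)("prox", np.array([0.0, 0.1, 0.0]))]
        sp = strand_length(model, model.reference_pose(), strand)
        expected = (np.linalg.norm([0.2, -0.1, 0]) + np.linalg.norm([0.2, 0.1, 0]))
        assert sp.length == pytest.approx(expected, abs=1e-12)

    def test_length_bounded_below_by_chord(self, rng):
        r = 0.5
        cyl = WrapCylinder("c", "prox", make_transform(np.eye(3), np.zeros(3)),
                           radius=r, half_length=5.0, side=SIDE_Y)
        for _ in range(25):
            p = rng.normal(size=3) * 3
            q = rng.normal(size=3) * 3
            if np.hypot(*p[:2]) < r + 0.05 or np.hypot(*q[:2]) < r + 0.05:
                continue
            model = make_hinge_model(p, q, cylinders=[cyl], obstacles=["c"])
            sp = strand_length(model, model.reference_pose(),
                               model.muscle("MUS").strands[0])
            chord = np.linalg.norm(q - p)
            assert sp.length >= chord - 1e-12
            if not sp.wrap_active:
                assert sp.length == pytest.approx(chord, abs=1e-12)

    def test_length_continuous_in_joint_angle(self):
        model = make_hinge_model([-0.2, 0.07, 0.0], [0.18, -0.03, 0.02])
        strand = model.muscle("MUS").strands[0]

        def L(th):
            pose = model.reference_pose().with_angle("hinge", "flexion", th)
            return strand_length(model, pose, strand).length

        for th in np.linspace(-30, 30, 7):
            assert abs(L(th + 1e-6) - L(th)) < 1e-6
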