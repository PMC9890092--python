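"""Tendon-excursion moment arms against analytic oracles, and C_min."""

import numpy as np
import pandas as pd
import pytest
from scipy.integrate import quad

from ossomech._transforms import make_transform, rotation_about_axis
from ossomech.errors import EmptySweepError, MeshError
from ossomech.model import WrapCylinder
from ossomech.momentarms import (
    MomentArmSweep,
    aggregate,
    elbow_protocol,
    glenohumeral_protocol,
    min_shaft_circumference,
    moment_arm_at,
    sweep,
)

from conftest import make_forelimb_model, make_hinge_model


def straight_line_oracle(p0, x0, centre, axis, theta_deg):
    """Analytic lever of a straight strand about a fixed axis: the insertion
    x rotates about the axis; r = ((x - c) x (p0 - x)) . a / |p0 - x|."""
    R = rotation_about_axis(axis, np.deg2rad(theta_deg))
    x = np.asarray(centre) + R @ (np.asarray(x0) - np.asarray(centre))
    v = np.asarray(p0) - x
    return float(np.cross(x - np.asarray(centre), v) @ np.asarray(axis)
                 / np.linalg.norm(v))


class TestMomentArmAt:
    def test_coaxial_wrap_equals_cylinder_radius(self):
        r = 0.03
        cyl = WrapCylinder("cx", "prox", make_transform(np.eye(3), np.zeros(3)),
                           radius=r, half_length=0.5, side=np.array([0.0, 1.0, 0.0]))
        model = make_hinge_model([-0.06, 0.0, 0.0], [0.065, 0.0, 0.0],
                                 cylinders=[cyl], obstacles=["cx"])
        strand = model.muscle("MUS").strands[0]
        for th in (-30.0, 0.0, 25.0):
            pose = model.reference_pose().with_angle("hinge", "flexion", th)
            r_num = moment_arm_at(model, strand, "hinge", "flexion", pose, h_deg=0.5)
            assert abs(abs(r_num) - r) < 1e-8

    def test_straight_strand_matches_cross_product_formula(self, rng):
        for _ in range(15):
            p0 = rng.uniform(-0.3, 0.3, 3)
            x0 = rng.uniform(-0.3, 0.3, 3)
            if abs(straight_line_oracle(p0, x0, np.zeros(3), [0, 0, 1], 0.0)) < 0.02:
                continue
            model = make_hinge_model(p0, x0)
            strand = model.muscle("MUS").strands[0]
            for th in (-20.0, 0.0, 35.0):
                pose = model.reference_pose().with_angle("hinge", "flexion", th)
                r_num = moment_arm_at(model, strand, "hinge", "flexion", pose,
                                      h_deg=0.02)
                r_ora = straight_line_oracle(p0, x0, np.zeros(3), [0, 0, 1], th)
                assert r_num == pytest.approx(r_ora, rel=1e-6, abs=1e-9)

    def test_strand_crossing_axis_has_zero_lever(self):
        # line through the rotation axis: zero common perpendicular
        model = make_hinge_model([-1.0, 0.0, 0.5], [1.0, 0.0, -0.2])
        strand = model.muscle("MUS").strands[0]
        r_num = moment_arm_at(model, strand, "hinge", "flexion",
                              model.reference_pose(), h_deg=0.5)
        assert abs(r_num) < 1e-9

    def test_halving_h_shrinks_truncation_quadratically(self):
        model = make_hinge_model([-0.2, 0.1, 0.0], [0.15, -0.05, 0.02])
        strand = model.muscle("MUS").strands[0]
        pose = model.reference_pose().with_angle("hinge", "flexion", 12.0)
        exact = straight_line_oracle([-0.2, 0.1, 0.0], [0.15, -0.05, 0.02],
                                     np.zeros(3), [0, 0, 1], 12.0)
        e4 = abs(moment_arm_at(model, strand, "hinge", "flexion", pose, h_deg=4.0) - exact)
        e2 = abs(moment_arm_at(model, strand, "hinge", "flexion", pose, h_deg=2.0) - exact)
        assert e2 == pytest.approx(e4 / 4.0, rel=0.15)


class TestSweep:
    def test_glenohumeral_grid_has_17_poses(self, forelimb_model):
        grid = glenohumeral_protocol(forelimb_model)
        assert len(grid.values) == 17
        assert grid.values[0] == -40.0 and grid.values[-1] == 40.0
        assert grid.spacing == 5.0
        assert grid.fixed_context.angle("glenohumeral", "adduction") == 90.0
        assert grid.fixed_context.angle("elbow", "flexion") == 45.0

    def test_elbow_grid_has_19_poses(self, forelimb_model):
        grid = elbow_protocol(forelimb_model)
        assert len(grid.values) == 19
        assert grid.values[0] == 10.0 and grid.values[-1] == 100.0
        assert grid.fixed_context.angle("glenohumeral", "protraction") == 20.0

    def test_strand_unaffected_by_swept_dof_gives_zero(self, forelimb_model):
        # PEC spans only the glenohumeral joint: elbow sweeps leave it rigid
        grid = elbow_protocol(forelimb_model)
        ms = sweep(forelimb_model, forelimb_model.muscle("PEC"), "elbow",
                   "flexion", grid)
        assert np.all(np.abs(ms.data.r_raw_m.to_numpy()) < 1e-12)

    def test_normalization_by_circumference(self, forelimb_model):
        grid = glenohumeral_protocol(forelimb_model)
        ms = sweep(forelimb_model, forelimb_model.muscle("PEC"), "glenohumeral",
                   "protraction", grid)
        np.testing.assert_allclose(
            ms.data.r_norm, ms.data.r_raw_m / forelimb_model.norm_circumference)

    def test_excursion_integral_identity(self, forelimb_model):
        grid = glenohumeral_protocol(forelimb_model)
        ms = sweep(forelimb_model, forelimb_model.muscle("PEC"), "glenohumeral",
                   "protraction", grid)
        g = ms.data
        L = g.length_m.to_numpy()
        resid = (L[-1] - L[0]) + np.trapezoid(g.r_raw_m.to_numpy(),
                                              dx=np.deg2rad(grid.spacing))
        assert abs(resid) < 1e-6


def _manual_sweep(values):
    rows = [dict(strand=s, angle_deg=a, length_m=1.0, r_raw_m=v, r_norm=v,
                 feasible=True, flagged=False)
            for (s, a, v) in values]
    return MomentArmSweep(muscle="M", joint="glenohumeral", dof="protraction",
                          action_pair=("protraction", "retraction"),
                          norm_circumference=1.0, data=pd.DataFrame(rows))


class TestAggregate:
    def test_pooled_mean_min_max(self):
        ms = _manual_sweep([("s", 0, 0.1), ("s", 5, 0.2), ("s", 10, 0.3)])
        agg = aggregate(ms)
        assert (agg.mean, agg.min, agg.max) == (pytest.approx(0.2), 0.1, 0.3)

    def test_three_identical_strands_match_single(self):
        vals = [0.05, 0.15, 0.4]
        single = aggregate(_manual_sweep([("s", 5 * i, v) for i, v in enumerate(vals)]))
        triple = aggregate(_manual_sweep(
            [(lbl, 5 * i, v) for lbl in ("a", "b", "c") for i, v in enumerate(vals)]))
        assert (triple.mean, triple.min, triple.max) == (
            pytest.approx(single.mean), single.min, single.max)

    def test_sign_mixed_values_may_straddle_zero(self):
        agg = aggregate(_manual_sweep([("s", 0, -0.1), ("s", 5, 0.3)]))
        assert agg.mean == pytest.approx(0.1)
        assert agg.min == -0.1 and agg.max == 0.3

    def test_empty_sweep_raises(self):
        ms = _manual_sweep([("s", 0, 0.1)])
        ms.data.loc[:, "feasible"] = False
        with pytest.raises(EmptySweepError):
            aggregate(ms)


class TestMinShaftCircumference:
    def test_circular_cylinder(self):
        import trimesh
        mesh = trimesh.creation.cylinder(radius=0.03, height=0.4, sections=256)
        c = min_shaft_circumference(mesh, [0, 0, 1])
        assert c == pytest.approx(2 * np.pi * 0.03, rel=0.005)

    def test_elliptical_cylinder_matches_quadrature(self):
        import trimesh
        a, b = 0.02, 0.01
        mesh = trimesh.creation.cylinder(radius=1.0, height=0.4, sections=256)
        mesh.apply_scale([a, b, 1.0])
        c = min_shaft_circumference(mesh, [0, 0, 1])
        perimeter, _ = quad(
            lambda t: np.sqrt((a * np.sin(t)) ** 2 + (b * np.cos(t)) ** 2),
            0, 2 * np.pi)
        assert c == pytest.approx(perimeter, rel=0.005)

    def test_open_mesh_rejected(self):
        import trimesh
        tri = trimesh.Trimesh(vertices=[[0, 0, 0], [1, 0, 0], [0, 1, 0]],
                              faces=[[0, 1, 2]])
        with pytest.raises(MeshError, match="watertight"):
            min_shaft_circumference(tri, [0, 0, 1])
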