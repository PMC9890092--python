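"""Forward kinematics of the articulated limb and joint-centre fitting.

Joint rotations follow a Grood–Suntay-style joint coordinate system: the
proximal-parented axis rotates first, then the floating axis, then the
distal-parented axis, all about the single fixed (posed) joint centre.
Angles are degrees at every interface and radians internally.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from ._transforms import (
    rotation_about_axis,
    rotation_part,
    transform_point,
    translation_matrix,
    unit,
)
from .errors import DegenerateInputError, SingularPoseError, ValidationError
from .model import LimbModel, Pose

GIMBAL_TOL_DEG = 0.5  # axes within this of parallel raise SingularPoseError


# --------------------------------------------------------------------- posing
def joint_rotation(model: LimbModel, joint_name: str, pose: Pose,
                   proximal_world: np.ndarray, base_world: np.ndarray) -> np.ndarray:
    """World rotation matrix a joint applies to its distal segment.

    ``base_world`` is the distal segment's world transform before the joint
    rotation (parent world composed with the rest transform).  The rotation
    sequence is intrinsic proximal -> floating -> distal: expressed in world
    matrices, Q = R(a3'', th3) @ R(a2', th2) @ R(a1, th1) where a2' and a3''
    are the floating and distal axes updated by the preceding rotations.
    """
    j = model.joint(joint_name)
    Rp = rotation_part(proximal_world)
    a1 = Rp @ j.dof("proximal").axis_direction
    f0 = Rp @ j.dof("floating").axis_direction
    a3_0 = rotation_part(base_world) @ j.dof("distal").axis_direction

    th = [np.deg2rad(pose.angle(joint_name, j.dof(role).name))
          for role in ("proximal", "floating", "distal")]
    Q1 = rotation_about_axis(a1, th[0])
    a2 = Q1 @ f0
    Q2 = rotation_about_axis(a2, th[1])
    a3 = Q2 @ Q1 @ a3_0
    Q3 = rotation_about_axis(a3, th[2])
    return Q3 @ Q2 @ Q1


def apply_pose(model: LimbModel, pose: Pose, _validate: bool = True) -> dict[str, np.ndarray]:
    """World rigid transform of every segment at ``pose``.

    The root sits at its rest transform (world frame); every joint rotates
    its distal subtree about the posed joint centre. Deterministic and pure.
    """
    if _validate:
        model.validate_pose(pose)
    joints_by_distal = {j.distal_segment: j for j in model.joints}
    world: dict[str, np.ndarray] = {}
    for seg in model.segments_topological():
        parent_world = world[seg.parent] if seg.parent is not None else np.eye(4)
        base = parent_world @ np.asarray(seg.rest_transform, dtype=float)
        j = joints_by_distal.get(seg.name)
        if j is None:
            world[seg.name] = base
            continue
        prox_world = world[j.proximal_segment]
        centre = transform_point(prox_world, j.centre)
        Q = joint_rotation(model, j.name, pose, prox_world, base)
        T = translation_matrix(centre)
        T[:3, :3] = Q
        T[:3, 3] = centre - Q @ centre
        world[seg.name] = T @ base
    return world


def joint_axis_world(model: LimbModel, pose: Pose, joint: str, dof: str,
                     world: dict[str, np.ndarray] | None = None
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Directed line (point on axis, unit direction) of a joint DOF at ``pose``.

    The proximal-parented axis is rigid with the proximal segment, the
    distal-parented axis with the distal segment; the floating axis is the
    (sign-fixed) unit cross product of the two, recomputed every pose.
    """
    j = model.joint(joint)
    d = j.dof_by_name(dof)
    if world is None:
        world = apply_pose(model, pose)
    Tp = world[j.proximal_segment]
    Td = world[j.distal_segment]
    point = transform_point(Tp, j.centre)
    a_prox = rotation_part(Tp) @ j.dof("proximal").axis_direction
    a_dist = rotation_part(Td) @ j.dof("distal").axis_direction
    if d.axis_parent == "proximal":
        return point, unit(a_prox)
    if d.axis_parent == "distal":
        return point, unit(a_dist)
    c = np.cross(a_prox, a_dist)
    if np.linalg.norm(c) < np.sin(np.deg2rad(GIMBAL_TOL_DEG)):
        raise SingularPoseError(
            f"joint {joint!r}: proximal and distal axes within {GIMBAL_TOL_DEG} deg "
            "of parallel (gimbal degeneracy)"
        )
    return point, j.float_sign * unit(c)


def landmark_world(model: LimbModel, pose: Pose, segment: str, landmark: str,
                   world: dict[str, np.ndarray] | None = None) -> np.ndarray:
    if world is None:
        world = apply_pose(model, pose)
    if segment not in world:
        raise ValidationError(f"unknown segment {segment!r}")
    return transform_point(world[segment], model.landmark_in_segment(segment, landmark))


# ------------------------------------------------------------ centre fitting
@dataclass
class JointCentreFit:
    centre: np.ndarray
    radius: float
    rms_residual: float


def fit_joint_centre(points: np.ndarray, mode: str = "circle") -> JointCentreFit:
    """Least-squares joint centre from digitized articular-surface points.

    ``circle`` fits a best plane (total least squares) and then a circle in
    it; ``sphere`` fits a sphere directly.  Both start from an algebraic
    (linear) fit refined by nonlinear least squares on radial residuals.
    """
    P = np.asarray(points, dtype=float)
    if P.ndim != 2 or P.shape[1] != 3:
        raise DegenerateInputError("points must be an (n, 3) array")
    n = P.shape[0]
    if n < 3:
        raise DegenerateInputError(f"need at least 3 points, got {n}")
    centroid = P.mean(axis=0)
    Q = P - centroid
    _, svals, Vt = np.linalg.svd(Q, full_matrices=False)
    scale = svals[0] if svals[0] > 0 else 1.0
    if svals[1] <= 1e-12 * scale:
        raise DegenerateInputError("points are collinear")

    if mode == "sphere":
        if n < 4 or svals[2] <= 1e-12 * scale:
            raise DegenerateInputError("sphere fit requires >= 4 non-coplanar points")
        A = np.column_stack([2.0 * P, np.ones(n)])
        b = np.sum(P * P, axis=1)
        sol, *_ = np.linalg.lstsq(A, b, rcond=None)
        c0 = sol[:3]
        r0 = np.sqrt(max(sol[3] + c0 @ c0, 0.0))

        def resid(x):
            return np.linalg.norm(P - x[:3], axis=1) - x[3]

        fit = least_squares(resid, np.r_[c0, r0])
        centre, radius = fit.x[:3], float(fit.x[3])
        rms = float(np.sqrt(np.mean(resid(fit.x) ** 2)))
        return JointCentreFit(centre=centre, radius=radius, rms_residual=rms)

    if mode != "circle":
        raise ValidationError(f"unknown fit mode {mode!r}")

    # in-plane basis from the best-fit plane (normal = smallest singular vector)
    e1, e2 = Vt[0], Vt[1]
    uv = Q @ np.column_stack([e1, e2])
    A = np.column_stack([2.0 * uv, np.ones(n)])
    b = np.sum(uv * uv, axis=1)
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    c0 = sol[:2]
    r0 = np.sqrt(max(sol[2] + c0 @ c0, 0.0))

    def resid2(x):
        return np.linalg.norm(uv - x[:2], axis=1) - x[2]

    fit = least_squares(resid2, np.r_[c0, r0])
    cx, cy, radius = fit.x
    centre = centroid + cx * e1 + cy * e2
    rms = float(np.sqrt(np.mean(resid2(fit.x) ** 2)))
    return JointCentreFit(centre=centre, radius=float(radius), rms_residual=rms)
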