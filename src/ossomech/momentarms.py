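"""Signed, size-normalized muscle moment arms by tendon excursion.

The moment arm of a strand about a joint DOF is the negative derivative of
its path length with respect to that joint angle (radians): r = -dL/dtheta.
Positive values produce torque toward the DOF's positive-named action.
Moment arms are normalized by the taxon's minimum humeral shaft
circumference C_min, making every downstream statistic dimensionless.

Two standardized pose protocols mirror the study design: a glenohumeral
sweep (-40..+40 deg protraction at 5 deg, humerus adducted 90 deg, elbow at
45 deg flexion) and an elbow sweep (10..100 deg flexion at 5 deg, humerus
adducted 90 deg and protracted 20 deg). Moment arms about every DOF of the
swept joint are evaluated at each pose of the protocol grid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import EmptySweepError, MeshError, OssomechError, ValidationError
from .model import LimbModel, Muscle, MuscleStrand, Pose
from .paths import strand_length

DEFAULT_H_DEG = 2.5  # half the standard 5-degree grid spacing


@dataclass
class PoseGrid:
    """A uniformly spaced sweep of one joint DOF with all others fixed."""

    joint: str
    dof: str
    values: np.ndarray  # degrees, strictly increasing, uniform
    fixed_context: Pose

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1 or len(v) < 2:
            raise ValidationError("grid needs at least two angles")
        dv = np.diff(v)
        if np.any(dv <= 0) or not np.allclose(dv, dv[0]):
            raise ValidationError("grid angles must be strictly increasing and uniform")
        self.values = v

    @property
    def spacing(self) -> float:
        return float(self.values[1] - self.values[0])

    def pose_at(self, angle_deg: float) -> Pose:
        return self.fixed_context.with_angle(self.joint, self.dof, angle_deg)


@dataclass
class MomentArmSweep:
    """Per strand x grid angle path lengths and signed normalized moment arms."""

    muscle: str
    joint: str
    dof: str
    action_pair: tuple[str, str]
    norm_circumference: float
    data: pd.DataFrame  # strand, angle_deg, length_m, r_raw_m, r_norm, feasible, flagged


@dataclass
class MuscleActionSummary:
    """Pooled mean/min/max of r_norm over all strands x grid angles."""

    muscle: str
    joint: str
    dof: str
    action_pair: tuple[str, str]
    mean: float
    min: float
    max: float
    n_pooled: int = 0
    n_infeasible: int = 0


def moment_arm_at(model: LimbModel, strand: MuscleStrand, joint: str, dof: str,
                  pose: Pose, h_deg: float = DEFAULT_H_DEG) -> float:
    """Raw moment arm (m) by central difference of path length, step h (deg).

    Falls back to a one-sided difference with a warning when one neighbour
    pose is infeasible; raises when both are.
    """
    if not h_deg > 0:
        raise ValidationError("h must be positive")
    h_rad = np.deg2rad(h_deg)
    theta = pose.angle(joint, dof)
    sides = {}
    errors = {}
    for sign in (+1, -1):
        try:
            sides[sign] = strand_length(
                model, pose.with_angle(joint, dof, theta + sign * h_deg), strand
            ).length
        except OssomechError as e:
            errors[sign] = e
    if len(sides) == 2:
        return -(sides[+1] - sides[-1]) / (2.0 * h_rad)
    if len(sides) == 1:
        warnings.warn(
            f"one-sided moment-arm difference at {joint}:{dof} theta={theta} "
            f"(neighbour infeasible: {list(errors.values())[0]})",
            stacklevel=2,
        )
        L0 = strand_length(model, pose, strand).length
        (sign, L1), = sides.items()
        return -sign * (L1 - L0) / h_rad
    raise next(iter(errors.values()))


def sweep(model: LimbModel, muscle: Muscle, joint: str, dof: str, grid: PoseGrid,
          h_deg: float | None = None) -> MomentArmSweep:
    """Evaluate one muscle's moment arms about (joint, dof) across a pose grid.

    When (joint, dof) is the swept DOF of the grid, r comes from central
    differences of L on the grid itself (one-sided at the ends).  For the
    other DOFs of the joint, r is evaluated at every grid pose with an
    off-grid central difference of step ``h_deg`` (default: half the grid
    spacing). Per-cell failures are marked infeasible, not fatal.
    """
    j = model.joint(joint)
    d = j.dof_by_name(dof)
    h = h_deg if h_deg is not None else grid.spacing / 2.0
    on_grid = (joint == grid.joint and dof == grid.dof)
    rows = []
    C = model.norm_circumference
    for strand_idx, strand in enumerate(muscle.strands):
        n = len(grid.values)
        L = np.full(n, np.nan)
        feasible = np.zeros(n, dtype=bool)
        signatures: list[tuple | None] = [None] * n
        for k, ang in enumerate(grid.values):
            try:
                sp = strand_length(model, grid.pose_at(ang), strand)
                L[k] = sp.length
                signatures[k] = sp.active_signature()
                feasible[k] = True
            except OssomechError:
                pass
        r = np.full(n, np.nan)
        if on_grid:
            dth = np.deg2rad(grid.spacing)
            for k in range(n):
                if not feasible[k]:
                    continue
                lo, hi = k - 1, k + 1
                if lo >= 0 and hi < n and feasible[lo] and feasible[hi]:
                    r[k] = -(L[hi] - L[lo]) / (2.0 * dth)
                elif hi < n and feasible[hi]:
                    r[k] = -(L[hi] - L[k]) / dth
                elif lo >= 0 and feasible[lo]:
                    r[k] = -(L[k] - L[lo]) / dth
        else:
            for k, ang in enumerate(grid.values):
                if not feasible[k]:
                    continue
                try:
                    r[k] = moment_arm_at(model, strand, joint, dof, grid.pose_at(ang), h_deg=h)
                except OssomechError:
                    feasible[k] = False
                    L[k] = np.nan
        # cells adjacent to a wrap on/off transition are flagged (kept in stats)
        flagged = np.zeros(n, dtype=bool)
        for k in range(n - 1):
            if (signatures[k] is not None and signatures[k + 1] is not None
                    and signatures[k] != signatures[k + 1]):
                flagged[k] = flagged[k + 1] = True
        label = strand.label or f"strand{strand_idx}"
        for k, ang in enumerate(grid.values):
            rows.append(
                dict(strand=label, angle_deg=float(ang), length_m=L[k],
                     r_raw_m=r[k], r_norm=r[k] / C, feasible=bool(feasible[k]),
                     flagged=bool(flagged[k]))
            )
    return MomentArmSweep(
        muscle=muscle.name, joint=joint, dof=dof, action_pair=d.action_pair,
        norm_circumference=C, data=pd.DataFrame(rows),
    )


def aggregate(ms: MomentArmSweep) -> MuscleActionSummary:
    """Pool r_norm over all strands x grid angles into mean/min/max."""
    vals = ms.data.loc[ms.data.feasible & np.isfinite(ms.data.r_norm), "r_norm"].to_numpy()
    n_bad = int((~ms.data.feasible).sum())
    if vals.size == 0:
        raise EmptySweepError(
            f"{ms.muscle} {ms.joint}:{ms.dof}: no feasible cells to aggregate"
        )
    return MuscleActionSummary(
        muscle=ms.muscle, joint=ms.joint, dof=ms.dof, action_pair=ms.action_pair,
        mean=float(vals.mean()), min=float(vals.min()), max=float(vals.max()),
        n_pooled=int(vals.size), n_infeasible=n_bad,
    )


# ------------------------------------------------------------------ protocols
def glenohumeral_protocol(model: LimbModel, joint: str = "glenohumeral",
                          elbow: str = "elbow") -> PoseGrid:
    """Protraction sweep -40..+40 deg at 5 deg; humerus adducted 90 deg,
    long-axis neutral, elbow flexed 45 deg."""
    ctx = model.reference_pose()
    ctx = ctx.with_angle(joint, "adduction", 90.0)
    ctx = ctx.with_angle(elbow, "flexion", 45.0)
    return PoseGrid(joint=joint, dof="protraction",
                    values=np.arange(-40.0, 40.0 + 1e-9, 5.0), fixed_context=ctx)


def elbow_protocol(model: LimbModel, joint: str = "elbow",
                   glenohumeral: str = "glenohumeral") -> PoseGrid:
    """Flexion sweep 10..100 deg at 5 deg; humerus adducted 90 deg and
    protracted 20 deg, long-axis neutral."""
    ctx = model.reference_pose()
    ctx = ctx.with_angle(glenohumeral, "adduction", 90.0)
    ctx = ctx.with_angle(glenohumeral, "protraction", 20.0)
    return PoseGrid(joint=joint, dof="flexion",
                    values=np.arange(10.0, 100.0 + 1e-9, 5.0), fixed_context=ctx)


# ------------------------------------------------- shaft circumference (C_min)
def min_shaft_circumference(mesh, long_axis, n_stations: int = 100,
                            middle_fraction: float = 0.6) -> float:
    """Minimum cross-sectional convex-hull perimeter along a bone shaft.

    Sections perpendicular to ``long_axis`` are sampled at >= ``n_stations``
    stations over the middle ``middle_fraction`` of the shaft; each section's
    circumference is the perimeter of the convex hull of its in-plane points.
    When the model file already declares a circumference scalar this op is
    skipped entirely.
    """
    import trimesh
    from scipy.spatial import ConvexHull

    if isinstance(mesh, (str, bytes)) or hasattr(mesh, "__fspath__"):
        mesh = trimesh.load_mesh(mesh)
    if not isinstance(mesh, trimesh.Trimesh) or len(mesh.vertices) == 0:
        raise MeshError("input is not a usable triangle mesh")
    if not mesh.is_watertight:
        raise MeshError(
            "mesh is not watertight; supply norm_circumference directly in the model file"
        )
    axis = np.asarray(long_axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    t = mesh.vertices @ axis
    lo, hi = t.min(), t.max()
    span = hi - lo
    margin = (1.0 - middle_fraction) / 2.0
    stations = np.linspace(lo + margin * span, hi - margin * span, max(n_stations, 100))
    # in-plane basis
    tmp = np.array([1.0, 0.0, 0.0])
    if abs(axis @ tmp) > 0.9:
        tmp = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(axis, tmp)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(axis, e1)

    best = np.inf
    for s in stations:
        section = mesh.section(plane_origin=axis * s, plane_normal=axis)
        if section is None:
            continue
        pts = np.asarray(section.vertices)
        if len(pts) < 3:
            continue
        uv = np.column_stack([pts @ e1, pts @ e2])
        try:
            hull = ConvexHull(uv)
        except Exception:
            continue
        best = min(best, float(hull.area))  # in 2D, .area is the perimeter
    if not np.isfinite(best):
        raise MeshError("no valid cross-sections found along the declared axis")
    return best
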