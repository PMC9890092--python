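"""Limb model domain types and the JSON document schema.

A :class:`LimbModel` bundles an articulated segment hierarchy, three-axis
joints whose rotation axes are parented to different segments, muscle strands
with wrapping-cylinder obstacles, and the size-normalization scalar (minimum
humeral shaft circumference, metres).

One JSON document describes one taxon::

    {
      "taxon": "Stegosaurus",
      "units": {"length": "m", "angle": "deg"},
      "norm_circumference": 0.42,
      "segments": [...], "joints": [...], "cylinders": [...], "muscles": [...]
    }

Validation raises :class:`~ossomech.errors.ValidationError` with a
JSON-pointer-style path locating the offending element.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np

from ._transforms import is_proper_rotation, make_transform, rotation_part
from .errors import ValidationError

AXIS_PARENTS = ("proximal", "floating", "distal")
ORTHOGONALITY_TOL = 1e-6


@dataclass
class Segment:
    """A rigid body in the segment tree.

    ``rest_transform`` places the segment frame in its parent frame at the
    reference pose (all joint angles zero). The root segment's parent frame
    is the world frame.
    """

    name: str
    parent: str | None
    rest_transform: np.ndarray  # 4x4
    landmarks: dict[str, np.ndarray] = field(default_factory=dict)
    mesh_ref: str | None = None


@dataclass
class DegreeOfFreedom:
    """One rotational degree of freedom of a joint.

    ``action_pair`` names the positive and negative rotation senses
    (right-hand rule about ``axis_direction``).  ``axis_direction`` is
    expressed in the frame of the segment the axis is parented to; for the
    floating axis it is the reference-pose direction in the proximal frame.
    """

    action_pair: tuple[str, str]
    axis_parent: str  # proximal | floating | distal
    axis_direction: np.ndarray

    @property
    def name(self) -> str:
        """DOF identifier: the positive action name."""
        return self.action_pair[0]


@dataclass
class JointAxisSystem:
    """Three rotational axes through a single fixed centre.

    ``centre`` is expressed in the proximal segment frame. Exactly one DOF
    is parented to each of {proximal, floating, distal}.
    """

    name: str
    proximal_segment: str
    distal_segment: str
    centre: np.ndarray
    dof_list: list[DegreeOfFreedom]
    # +1 if cross(proximal_axis, distal_axis) matches the declared floating
    # direction at the reference pose, else -1; set during validation.
    float_sign: float = 1.0

    def dof(self, role: str) -> DegreeOfFreedom:
        for d in self.dof_list:
            if d.axis_parent == role:
                return d
        raise ValidationError(f"joint {self.name!r} has no {role}-parented DOF")

    def dof_by_name(self, name: str) -> DegreeOfFreedom:
        for d in self.dof_list:
            if d.name == name:
                return d
        raise ValidationError(f"joint {self.name!r} has no DOF named {name!r}")

    @property
    def dof_names(self) -> list[str]:
        return [d.name for d in self.dof_list]


@dataclass
class Pose:
    """Joint angle assignment in degrees: ``angles[(joint, dof_name)] = deg``."""

    angles: dict[tuple[str, str], float]

    def angle(self, joint: str, dof: str) -> float:
        return self.angles[(joint, dof)]

    def with_angle(self, joint: str, dof: str, value_deg: float) -> "Pose":
        new = dict(self.angles)
        new[(joint, dof)] = float(value_deg)
        return Pose(new)

    def negated_reversed(self) -> "Pose":
        return Pose({k: -v for k, v in self.angles.items()})


@dataclass
class WrapCylinder:
    """A wrapping obstacle: paths must deflect around its surface.

    ``frame`` places the cylinder in its segment's frame with the cylinder
    axis along local +z. ``side`` is a unit hint (segment frame) selecting
    the deflection side when both tangent solutions exist.
    """

    name: str
    segment: str
    frame: np.ndarray  # 4x4
    radius: float
    half_length: float
    side: np.ndarray


@dataclass
class AttachmentPoint:
    segment: str
    point: np.ndarray


@dataclass
class MuscleStrand:
    """One origin-to-insertion pathway with optional via points and obstacles."""

    label: str  # posterior | midline | anterior | single
    origin: AttachmentPoint
    insertion: AttachmentPoint
    via_points: list[AttachmentPoint] = field(default_factory=list)
    obstacles: list[str] = field(default_factory=list)


@dataclass
class Muscle:
    name: str
    strands: list[MuscleStrand]
    spanned_joints: list[str] = field(default_factory=list)


@dataclass
class LimbModel:
    """Articulated limb model for one taxon.

    ``norm_circumference`` is C_min, the minimum humeral shaft circumference
    in metres, used to render moment arms dimensionless downstream.
    """

    taxon: str
    segments: list[Segment]
    joints: list[JointAxisSystem]
    muscles: list[Muscle] = field(default_factory=list)
    cylinders: list[WrapCylinder] = field(default_factory=list)
    norm_circumference: float = 1.0
    units: dict[str, str] = field(default_factory=lambda: {"length": "m", "angle": "deg"})
    meta: dict = field(default_factory=dict)

    # ------------------------------------------------------------------ access
    def segment(self, name: str) -> Segment:
        try:
            return self._segment_index[name]
        except AttributeError:
            self._build_indices()
            return self._segment_index[name]

    def joint(self, name: str) -> JointAxisSystem:
        try:
            return self._joint_index[name]
        except AttributeError:
            self._build_indices()
            return self._joint_index[name]

    def muscle(self, name: str) -> Muscle:
        for m in self.muscles:
            if m.name == name:
                return m
        raise ValidationError(f"unknown muscle {name!r}")

    def cylinder(self, name: str) -> WrapCylinder:
        for c in self.cylinders:
            if c.name == name:
                return c
        raise ValidationError(f"unknown wrapping cylinder {name!r}")

    def _build_indices(self) -> None:
        self._segment_index = {s.name: s for s in self.segments}
        self._joint_index = {j.name: j for j in self.joints}

    def segments_topological(self) -> list[Segment]:
        """Segments ordered parent-before-child."""
        by_parent: dict[str | None, list[Segment]] = {}
        for s in self.segments:
            by_parent.setdefault(s.parent, []).append(s)
        roots = by_parent.get(None, [])
        out: list[Segment] = []
        stack = list(reversed(roots))
        while stack:
            s = stack.pop()
            out.append(s)
            stack.extend(reversed(by_parent.get(s.name, [])))
        return out

    def reference_pose(self) -> Pose:
        return Pose({(j.name, d.name): 0.0 for j in self.joints for d in j.dof_list})

    def dof_keys(self) -> list[tuple[str, str]]:
        return [(j.name, d.name) for j in self.joints for d in j.dof_list]

    # --------------------------------------------------------------- validation
    def validate(self) -> None:
        """Check all structural invariants; raise ValidationError on failure."""
        self._build_indices()
        if len(self._segment_index) != len(self.segments):
            raise ValidationError("segments: duplicate names")
        roots = [s for s in self.segments if s.parent is None]
        if len(roots) != 1:
            raise ValidationError(f"segments: expected exactly one root, found {len(roots)}")
        for i, s in enumerate(self.segments):
            loc = f"segments[{i}]"
            if s.parent is not None and s.parent not in self._segment_index:
                raise ValidationError(f"{loc}.parent: unknown segment {s.parent!r}")
            R = rotation_part(np.asarray(s.rest_transform, dtype=float))
            if not is_proper_rotation(R, tol=1e-9):
                raise ValidationError(
                    f"{loc}.rest_transform: rotation not orthonormal with det +1"
                )
        if len(self.segments_topological()) != len(self.segments):
            raise ValidationError("segments: graph contains a cycle or unreachable segment")

        for i, j in enumerate(self.joints):
            loc = f"joints[{i}]"
            for ref in (j.proximal_segment, j.distal_segment):
                if ref not in self._segment_index:
                    raise ValidationError(f"{loc}: unknown segment {ref!r}")
            if self._segment_index[j.distal_segment].parent != j.proximal_segment:
                raise ValidationError(
                    f"{loc}: distal segment {j.distal_segment!r} must be a child of "
                    f"proximal segment {j.proximal_segment!r}"
                )
            if len(j.dof_list) != 3:
                raise ValidationError(f"{loc}.dofs: expected exactly 3 DOFs")
            parents = sorted(d.axis_parent for d in j.dof_list)
            if parents != sorted(AXIS_PARENTS):
                raise ValidationError(
                    f"{loc}.dofs: need one DOF per axis parent {AXIS_PARENTS}, got {parents}"
                )
            for k, d in enumerate(j.dof_list):
                n = np.linalg.norm(d.axis_direction)
                if not np.isfinite(n) or abs(n - 1.0) > 1e-6:
                    raise ValidationError(f"{loc}.dofs[{k}].axis_direction: not a unit vector")
        if len({j.name for j in self.joints}) != len(self.joints):
            raise ValidationError("joints: duplicate names")

        for i, c in enumerate(self.cylinders):
            loc = f"cylinders[{i}]"
            if c.segment not in self._segment_index:
                raise ValidationError(f"{loc}.segment: unknown segment {c.segment!r}")
            if not c.radius > 0:
                raise ValidationError(f"{loc}.radius: must be > 0")
            if not c.half_length > 0:
                raise ValidationError(f"{loc}.half_length: must be > 0")
        cyl_names = {c.name for c in self.cylinders}

        for i, m in enumerate(self.muscles):
            for k, s in enumerate(m.strands):
                loc = f"muscles[{i}].strands[{k}]"
                for ap in [s.origin, s.insertion, *s.via_points]:
                    if ap.segment not in self._segment_index:
                        raise ValidationError(f"{loc}: unknown segment {ap.segment!r}")
                if s.origin.segment == s.insertion.segment:
                    raise ValidationError(
                        f"{loc}: origin and insertion must sit on different segments"
                    )
                for name in s.obstacles:
                    if name not in cyl_names:
                        raise ValidationError(f"{loc}.obstacles: unknown cylinder {name!r}")
            if len(m.strands) not in (1, 3):
                raise ValidationError(f"muscles[{i}]: strand count must be 1 or 3")

        if not self.norm_circumference > 0:
            raise ValidationError("norm_circumference: must be > 0")

        self._validate_reference_axes()

    def _validate_reference_axes(self) -> None:
        """At the reference pose the three world axis directions of every joint
        must be mutually perpendicular; fix the floating-axis cross-product sign.
        """
        from .kinematics import apply_pose  # local import: avoids a cycle

        world = apply_pose(self, self.reference_pose(), _validate=False)
        for i, j in enumerate(self.joints):
            Rp = rotation_part(world[j.proximal_segment])
            Rd = rotation_part(world[j.distal_segment])
            a1 = Rp @ j.dof("proximal").axis_direction
            af = Rp @ j.dof("floating").axis_direction
            a3 = Rd @ j.dof("distal").axis_direction
            for u, v, pair in ((a1, af, "proximal/floating"), (a1, a3, "proximal/distal"),
                               (af, a3, "floating/distal")):
                if abs(float(np.dot(u, v))) > ORTHOGONALITY_TOL:
                    raise ValidationError(
                        f"joints[{i}]: {pair} axes not perpendicular at reference pose "
                        f"(|dot| = {abs(float(np.dot(u, v))):.3e})"
                    )
            j.float_sign = 1.0 if float(np.dot(np.cross(a1, a3), af)) >= 0 else -1.0

    def validate_pose(self, pose: Pose) -> None:
        keys = set(self.dof_keys())
        got = set(pose.angles)
        if got != keys:
            missing = sorted(keys - got)
            extra = sorted(got - keys)
            raise ValidationError(f"pose mismatch: missing {missing}, unknown {extra}")
        for k, v in pose.angles.items():
            if not np.isfinite(v):
                raise ValidationError(f"pose angle {k} not finite")

    # ---------------------------------------------------------------- (de)serde
    def to_dict(self) -> dict:
        def tf(T):
            T = np.asarray(T, dtype=float)
            return {"rotation": T[:3, :3].tolist(), "translation": T[:3, 3].tolist()}

        return {
            "taxon": self.taxon,
            "units": dict(self.units),
            "norm_circumference": float(self.norm_circumference),
            "segments": [
                {
                    "name": s.name,
                    "parent": s.parent,
                    "rest_transform": tf(s.rest_transform),
                    "landmarks": {k: np.asarray(v, float).tolist() for k, v in s.landmarks.items()},
                    "mesh_ref": s.mesh_ref,
                }
                for s in self.segments
            ],
            "joints": [
                {
                    "name": j.name,
                    "proximal_segment": j.proximal_segment,
                    "distal_segment": j.distal_segment,
                    "centre": np.asarray(j.centre, float).tolist(),
                    "dofs": [
                        {
                            "action_pair": list(d.action_pair),
                            "axis_parent": d.axis_parent,
                            "axis_direction": np.asarray(d.axis_direction, float).tolist(),
                        }
                        for d in j.dof_list
                    ],
                }
                for j in self.joints
            ],
            "cylinders": [
                {
                    "name": c.name,
                    "segment": c.segment,
                    "frame": tf(c.frame),
                    "radius": float(c.radius),
                    "half_length": float(c.half_length),
                    "side": np.asarray(c.side, float).tolist(),
                }
                for c in self.cylinders
            ],
            "muscles": [
                {
                    "name": m.name,
                    "spanned_joints": list(m.spanned_joints),
                    "strands": [
                        {
                            "label": s.label,
                            "origin": {"segment": s.origin.segment,
                                       "point": np.asarray(s.origin.point, float).tolist()},
                            "insertion": {"segment": s.insertion.segment,
                                          "point": np.asarray(s.insertion.point, float).tolist()},
                            "via_points": [
                                {"segment": v.segment, "point": np.asarray(v.point, float).tolist()}
                                for v in s.via_points
                            ],
                            "obstacles": list(s.obstacles),
                        }
                        for s in m.strands
                    ],
                }
                for m in self.muscles
            ],
            "meta": self.meta,
        }

    @classmethod
    def from_dict(cls, doc: Mapping) -> "LimbModel":
        def tf(d, loc):
            try:
                return make_transform(np.asarray(d["rotation"], float),
                                      np.asarray(d["translation"], float))
            except (KeyError, TypeError, ValueError) as e:
                raise ValidationError(f"{loc}: bad rigid transform ({e})")

        def ap(d, loc):
            try:
                return AttachmentPoint(segment=d["segment"], point=np.asarray(d["point"], float))
            except (KeyError, TypeError, ValueError) as e:
                raise ValidationError(f"{loc}: bad attachment point ({e})")

        try:
            segments = [
                Segment(
                    name=s["name"],
                    parent=s.get("parent"),
                    rest_transform=tf(s["rest_transform"], f"segments[{i}].rest_transform"),
                    landmarks={k: np.asarray(v, float) for k, v in s.get("landmarks", {}).items()},
                    mesh_ref=s.get("mesh_ref"),
                )
                for i, s in enumerate(doc.get("segments", []))
            ]
            joints = [
                JointAxisSystem(
                    name=j["name"],
                    proximal_segment=j["proximal_segment"],
                    distal_segment=j["distal_segment"],
                    centre=np.asarray(j["centre"], float),
                    dof_list=[
                        DegreeOfFreedom(
                            action_pair=tuple(d["action_pair"]),
                            axis_parent=d["axis_parent"],
                            axis_direction=np.asarray(d["axis_direction"], float),
                        )
                        for d in j["dofs"]
                    ],
                )
                for j in doc.get("joints", [])
            ]
            cylinders = [
                WrapCylinder(
                    name=c["name"],
                    segment=c["segment"],
                    frame=tf(c["frame"], f"cylinders[{i}].frame"),
                    radius=float(c["radius"]),
                    half_length=float(c["half_length"]),
                    side=np.asarray(c["side"], float),
                )
                for i, c in enumerate(doc.get("cylinders", []))
            ]
            muscles = [
                Muscle(
                    name=m["name"],
                    spanned_joints=list(m.get("spanned_joints", [])),
                    strands=[
                        MuscleStrand(
                            label=s.get("label", "single"),
                            origin=ap(s["origin"], f"muscles[{i}].strands[{k}].origin"),
                            insertion=ap(s["insertion"], f"muscles[{i}].strands[{k}].insertion"),
                            via_points=[
                                ap(v, f"muscles[{i}].strands[{k}].via_points")
                                for v in s.get("via_points", [])
                            ],
                            obstacles=list(s.get("obstacles", [])),
                        )
                        for k, s in enumerate(m["strands"])
                    ],
                )
                for i, m in enumerate(doc.get("muscles", []))
            ]
        except (KeyError, TypeError) as e:
            raise ValidationError(f"malformed model document: missing field {e}")

        model = cls(
            taxon=doc.get("taxon", "unnamed"),
            segments=segments,
            joints=joints,
            muscles=muscles,
            cylinders=cylinders,
            norm_circumference=float(doc.get("norm_circumference", 1.0)),
            units=dict(doc.get("units", {"length": "m", "angle": "deg"})),
            meta=dict(doc.get("meta", {})),
        )
        model.validate()
        return model

    @classmethod
    def from_json(cls, path: str | Path) -> "LimbModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    def copy(self) -> "LimbModel":
        return LimbModel.from_dict(self.to_dict())

    def landmark_in_segment(self, segment: str, name: str) -> np.ndarray:
        seg = self.segment(segment)
        if name not in seg.landmarks:
            raise ValidationError(f"segment {segment!r} has no landmark {name!r}")
        return np.asarray(seg.landmarks[name], dtype=float)
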