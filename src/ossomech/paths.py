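"""Muscle strand routing: via-point anchors and obstacle-set wrapping.

A strand runs origin -> via points -> insertion. Via points are hard anchors;
between consecutive anchors (a "leg") the path is the shortest route around
that leg's wrapping cylinders, found by fixed-point iteration: each cylinder
is repeatedly re-solved against the neighbouring tangent points until the
total length stabilizes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._transforms import transform_point
from .errors import ConvergenceError
from .kinematics import apply_pose
from .model import LimbModel, MuscleStrand, Pose
from .wrapping import WrapResult, cylinder_side_local, cylinder_world_frame, solve_wrap_single

MAX_ITERATIONS = 100
REL_TOL = 1e-10


@dataclass
class LegSolution:
    anchors: tuple[np.ndarray, np.ndarray]
    length: float
    points: np.ndarray  # polyline including anchors
    active: dict[str, bool] = field(default_factory=dict)  # per cylinder name
    band_exceeded: bool = False


@dataclass
class StrandPath:
    length: float
    points: np.ndarray  # full polyline origin..insertion
    legs: list[LegSolution]

    @property
    def wrap_active(self) -> bool:
        return any(any(leg.active.values()) for leg in self.legs)

    def active_signature(self) -> tuple:
        """Hashable wrap on/off state across legs, for transition flagging."""
        return tuple(
            (i, name, on) for i, leg in enumerate(self.legs)
            for name, on in sorted(leg.active.items())
        )


def _solve_leg(A: np.ndarray, B: np.ndarray, cylinders: list, frames: list[np.ndarray],
               sides: list[np.ndarray]) -> LegSolution:
    n = len(cylinders)
    if n == 0:
        length = float(np.linalg.norm(B - A))
        return LegSolution(anchors=(A, B), length=length, points=np.vstack([A, B]))

    results: list[WrapResult | None] = [None] * n
    prev_len = np.inf
    length = np.inf
    for it in range(MAX_ITERATIONS):
        for i in range(n):
            left = A
            for j in range(i - 1, -1, -1):
                if results[j] is not None and results[j].wrap_active:
                    left = results[j].exit
                    break
            right = B
            for j in range(i + 1, n):
                if results[j] is not None and results[j].wrap_active:
                    right = results[j].entry
                    break
            results[i] = solve_wrap_single(
                left, right, frames[i], cylinders[i].radius, sides[i],
                half_length=cylinders[i].half_length,
            )
        # walk the chain for the total length
        length = 0.0
        prev = A
        pts = [A]
        for i in range(n):
            res = results[i]
            if not res.wrap_active:
                continue
            length += float(np.linalg.norm(res.entry - prev))
            length += res.arc_length
            pts.extend(res.path[1:-1])
            prev = res.exit
        length += float(np.linalg.norm(B - prev))
        pts.append(B)
        if prev_len < np.inf and abs(length - prev_len) <= REL_TOL * max(length, 1e-300):
            break
        prev_len = length
    else:
        raise ConvergenceError(
            f"wrapping fixed point did not converge in {MAX_ITERATIONS} iterations",
            diagnostics={
                "last_length": length,
                "previous_length": prev_len,
                "cylinders": [c.name for c in cylinders],
            },
        )
    return LegSolution(
        anchors=(A, B),
        length=length,
        points=np.vstack(pts),
        active={c.name: bool(results[i].wrap_active) for i, c in enumerate(cylinders)},
        band_exceeded=any(r.band_exceeded for r in results),
    )


def strand_length(model: LimbModel, pose: Pose, strand: MuscleStrand,
                  world: dict[str, np.ndarray] | None = None) -> StrandPath:
    """Total path length (m) and world polyline of one strand at ``pose``."""
    if world is None:
        world = apply_pose(model, pose)
    anchors = [transform_point(world[a.segment], a.point)
               for a in (strand.origin, *strand.via_points, strand.insertion)]
    cylinders = [model.cylinder(name) for name in strand.obstacles]
    frames = [cylinder_world_frame(c, world) for c in cylinders]
    sides = [cylinder_side_local(c) for c in cylinders]

    legs = [
        _solve_leg(anchors[i], anchors[i + 1], cylinders, frames, sides)
        for i in range(len(anchors) - 1)
    ]
    points = np.vstack([legs[0].points] + [leg.points[1:] for leg in legs[1:]])
    return StrandPath(length=float(sum(leg.length for leg in legs)), points=points, legs=legs)
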