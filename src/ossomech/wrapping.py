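"""Single-cylinder obstacle wrapping: tangent - helical geodesic - tangent.

The cylinder is infinite for tangency math. In cylinder-local coordinates
(axis = +z) the planar problem decides whether the straight segment between
the projected endpoints penetrates the circle; if so the shortest path is a
tangent line, a circular arc traversed in the hint-selected direction, and a
second tangent line, with the axial (z) coordinate distributed linearly over
planar arc length, making the on-cylinder portion a helix. The total length
then has the closed form hypot(t1 + r*phi + t2, dz).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from ._transforms import invert, transform_point
from .errors import InfeasibleAttachmentError

_SURFACE_TOL = 1e-12


class WrapBandWarning(UserWarning):
    """The wrap arc leaves the declared +/- half_length band of a cylinder."""


@dataclass
class WrapResult:
    path: np.ndarray  # (k, 3) world-frame polyline including endpoints
    length: float
    wrap_active: bool
    entry: np.ndarray | None = None  # world touch points when active
    exit: np.ndarray | None = None
    arc_length: float = 0.0  # helical on-cylinder length
    arc_angle: float = 0.0
    band_exceeded: bool = field(default=False)


def _tangent_angles(a2d: np.ndarray, r: float, s: int) -> tuple[float, float, float]:
    """(touch angle entering with wrap sense s, distance d, tangent length)."""
    d = float(np.hypot(a2d[0], a2d[1]))
    alpha = float(np.arctan2(a2d[1], a2d[0]))
    beta = float(np.arccos(np.clip(r / d, -1.0, 1.0)))
    return alpha, d, beta


def solve_wrap_single(
    p_world: np.ndarray,
    q_world: np.ndarray,
    frame_world: np.ndarray,
    radius: float,
    side_local: np.ndarray,
    half_length: float | None = None,
    arc_step_deg: float = 5.0,
) -> WrapResult:
    """Shortest path from p to q around one cylinder (world frame in/out).

    ``frame_world`` places the cylinder (local axis = +z) in the world;
    ``side_local`` is the deflection hint in cylinder-local coordinates (only
    its xy part matters). Raises InfeasibleAttachmentError when an endpoint
    lies strictly inside the cylinder.
    """
    Tinv = invert(np.asarray(frame_world, dtype=float))
    p = transform_point(Tinv, p_world)
    q = transform_point(Tinv, q_world)
    r = float(radius)

    for name, pt in (("p", p), ("q", q)):
        if np.hypot(pt[0], pt[1]) < r - 1e-9:
            raise InfeasibleAttachmentError(
                f"endpoint {name} lies inside wrapping cylinder (planar distance "
                f"{np.hypot(pt[0], pt[1]):.6g} < radius {r:.6g})"
            )

    P, Q = p[:2], q[:2]
    # planar distance from the segment PQ to the cylinder axis
    d = Q - P
    seg_len2 = float(d @ d)
    t = 0.0 if seg_len2 == 0.0 else float(np.clip(-(P @ d) / seg_len2, 0.0, 1.0))
    closest = P + t * d
    if np.linalg.norm(closest) >= r - _SURFACE_TOL:
        length = float(np.linalg.norm(q_world - p_world))
        return WrapResult(path=np.vstack([p_world, q_world]), length=length, wrap_active=False)

    # wrap: evaluate both senses, pick the one whose arc midpoint matches the hint
    side_xy = np.asarray(side_local, dtype=float)[:2]
    candidates = []
    for s in (+1, -1):
        aP, dP, bP = _tangent_angles(P, r, s)
        aQ, dQ, bQ = _tangent_angles(Q, r, s)
        th1 = aP + s * bP  # touch leaving P, continuing in sense s
        th2 = aQ - s * bQ  # touch leaving the cylinder toward Q
        phi = (s * (th2 - th1)) % (2.0 * np.pi)
        mid_angle = th1 + s * (phi / 2.0)
        mid = np.array([np.cos(mid_angle), np.sin(mid_angle)])
        score = float(mid @ side_xy)
        candidates.append((s, th1, th2, phi, dP, bP, dQ, bQ, score))
    best = max(candidates, key=lambda c: (c[-1], c[0]))  # tie at 0 -> s=+1 first
    s, th1, th2, phi, dP, bP, dQ, bQ, _ = best

    t1 = float(np.sqrt(max(dP * dP - r * r, 0.0)))
    t2 = float(np.sqrt(max(dQ * dQ - r * r, 0.0)))
    planar = t1 + r * phi + t2
    dz = q[2] - p[2]
    length = float(np.hypot(planar, dz))

    # z at the touch points: linear in planar arc length
    z1 = p[2] + dz * (t1 / planar) if planar > 0 else p[2]
    z2 = p[2] + dz * ((t1 + r * phi) / planar) if planar > 0 else q[2]

    band_exceeded = False
    if half_length is not None and (abs(z1) > half_length or abs(z2) > half_length):
        band_exceeded = True
        warnings.warn(
            "wrap arc leaves the +/- half_length band of the cylinder",
            WrapBandWarning,
            stacklevel=2,
        )

    n_arc = max(2, int(np.ceil(np.rad2deg(phi) / arc_step_deg)) + 1)
    angles = th1 + s * np.linspace(0.0, phi, n_arc)
    zs = np.linspace(z1, z2, n_arc)
    arc_local = np.column_stack([r * np.cos(angles), r * np.sin(angles), zs])
    F = np.asarray(frame_world, dtype=float)
    arc_world = np.array([transform_point(F, pt) for pt in arc_local])
    path = np.vstack([p_world, arc_world, q_world])

    return WrapResult(
        path=path,
        length=length,
        wrap_active=True,
        entry=arc_world[0],
        exit=arc_world[-1],
        arc_length=float(np.hypot(r * phi, z2 - z1)),
        arc_angle=float(phi),
        band_exceeded=band_exceeded,
    )


def cylinder_world_frame(cyl, world_transforms) -> np.ndarray:
    """World placement of a cylinder rigid with its segment."""
    return np.asarray(world_transforms[cyl.segment], dtype=float) @ np.asarray(cyl.frame, float)


def cylinder_side_local(cyl) -> np.ndarray:
    """Deflection hint re-expressed in cylinder-local coordinates (pose-free)."""
    R = np.asarray(cyl.frame, dtype=float)[:3, :3]
    return R.T @ np.asarray(cyl.side, dtype=float)
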