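"""Osteological correlates of moment arms.

Measures the in-plane displacement of a bony landmark (e.g. the apex of the
deltopectoral crest) from a joint centre, normalized by minimum humeral
shaft circumference, and regresses per-taxon mean moment arms on those
displacements by ordinary least squares. Taxa can carry a data-driven
exclusion flag (with a reason); the regression is reported both with and
without the excluded taxa. Reduced major axis slopes are available behind a
flag for users who prefer a symmetric error model.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import statsmodels.api as sm

from ._transforms import invert, transform_point
from .errors import UndefinedCorrelationError, ValidationError
from .kinematics import apply_pose
from .model import LimbModel

PLANES = {"XY": (0, 1), "XZ": (0, 2), "YZ": (1, 2)}


@dataclass
class OsteoMeasurement:
    taxon: str
    landmark: str
    joint: str
    plane: tuple[str, str]  # (segment, "XY" | "XZ" | "YZ")
    displacement: float  # dimensionless (length / C_min)
    excluded: bool = False
    exclusion_reason: str = ""


def planar_displacement(model: LimbModel, landmark: tuple[str, str], joint: str,
                        plane: tuple[str, str]) -> float:
    """Normalized in-plane distance of a landmark from a joint centre.

    Both points are expressed in the frame of ``plane[0]`` at the reference
    pose, projected onto the named coordinate plane of that segment, and the
    Euclidean in-plane distance is divided by C_min.
    """
    plane_segment, plane_name = plane
    if plane_name not in PLANES:
        raise ValidationError(
            f"undeclared plane {plane_name!r}: expected one of {sorted(PLANES)}"
        )
    world = apply_pose(model, model.reference_pose())
    if plane_segment not in world:
        raise ValidationError(f"unknown plane segment {plane_segment!r}")
    lm_world = transform_point(world[landmark[0]],
                               model.landmark_in_segment(landmark[0], landmark[1]))
    j = model.joint(joint)
    centre_world = transform_point(world[j.proximal_segment], j.centre)
    to_plane = invert(world[plane_segment])
    lm = transform_point(to_plane, lm_world)
    ct = transform_point(to_plane, centre_world)
    i0, i1 = PLANES[plane_name]
    d = float(np.hypot(lm[i0] - ct[i0], lm[i1] - ct[i1]))
    return d / model.norm_circumference


@dataclass
class FitStats:
    slope: float
    intercept: float
    r: float
    r_squared: float
    n_used: int


@dataclass
class OsteoCorrelation:
    """Regression of mean moment arm on osteometric displacement.

    ``included`` excludes the flagged taxa (the headline trendline);
    ``all_taxa`` refits with every taxon for comparison.
    """

    included: FitStats
    all_taxa: FitStats
    excluded_taxa: list[str]

    def summary(self) -> str:
        def fmt(tag, f):
            return (f"  {tag}: m = {f.slope:.4g} d + {f.intercept:.4g}   "
                    f"r = {f.r:.4f}   r^2 = {f.r_squared:.4f}   n = {f.n_used}")

        return "\n".join([
            "OLS fit of mean moment arm (m) on normalized displacement (d)",
            fmt("excluding flagged", self.included),
            fmt("all taxa        ", self.all_taxa),
            f"  excluded: {self.excluded_taxa or 'none'}",
        ])


def _fit(d: np.ndarray, m: np.ndarray, rma: bool) -> FitStats:
    if len(d) < 3:
        raise ValidationError("need >= 3 taxa for a correlation")
    if np.ptp(d) == 0:
        raise UndefinedCorrelationError("zero variance in osteometric displacement")
    res = sm.OLS(m, sm.add_constant(d)).fit()
    r = float(np.corrcoef(d, m)[0, 1])
    slope = float(res.params[1])
    intercept = float(res.params[0])
    if rma:
        slope = float(np.sign(r) * np.std(m, ddof=1) / np.std(d, ddof=1))
        intercept = float(np.mean(m) - slope * np.mean(d))
    return FitStats(slope=slope, intercept=intercept, r=r,
                    r_squared=float(r * r), n_used=len(d))


def correlate(d: Mapping[str, float] | pd.Series, m: Mapping[str, float] | pd.Series,
              exclusions: Iterable[str] = (), rma: bool = False) -> OsteoCorrelation:
    """Regress per-taxon mean moment arms ``m`` on displacements ``d``.

    ``exclusions`` lists taxa omitted from the headline fit (reported
    separately); a second fit including all taxa is always returned.
    """
    d = pd.Series(d, dtype=float)
    m = pd.Series(m, dtype=float)
    common = [t for t in d.index if t in m.index]
    if len(common) < len(d) or len(common) < len(m):
        raise ValidationError("taxa in d and m do not match")
    excluded = sorted(set(exclusions) & set(common))
    kept = [t for t in common if t not in set(excluded)]
    return OsteoCorrelation(
        included=_fit(d[kept].to_numpy(), m[kept].to_numpy(), rma),
        all_taxa=_fit(d[common].to_numpy(), m[common].to_numpy(), rma),
        excluded_taxa=excluded,
    )
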