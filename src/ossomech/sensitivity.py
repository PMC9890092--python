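"""Variant protocols and qualitative rank-consistency checks.

Three variant kinds probe how summed moment arms depend on modelling
choices:

* ``pose-adduction`` — splayed (75 deg) or tucked (115 deg) humeral
  adduction replacing the base 90 deg in every sweep context;
* ``scapular-slope`` — the scapulocoracoid rotated about the mediolateral
  axis through the glenohumeral centre to a steeper declared slope (the
  glenoid stays fixed in space, keeping glenohumeral geometry comparable);
* ``elbow-axis-translation`` — the elbow joint centre translated along the
  epicondyle-to-epicondyle chord to a stated fraction of condyle width
  (this leaves the extension-flexion axis, which runs along that chord,
  unchanged as a line).

Consistency across variants is summarized by deterministic per-variant taxon
rankings, Kendall's tau against the base set, explicit rank inversions, and
overlap flags for per-taxon value envelopes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import kendalltau

from ._transforms import rotation_about_line, transform_point
from .errors import ValidationError
from .kinematics import apply_pose
from .model import LimbModel
from .momentarms import PoseGrid
from .summaries import ActionSummaryTable

VARIANT_KINDS = ("pose-adduction", "scapular-slope", "elbow-axis-translation")


@dataclass
class VariantSpec:
    kind: str
    parameter: float

    def __post_init__(self):
        if self.kind not in VARIANT_KINDS:
            raise ValidationError(f"unknown variant kind {self.kind!r}")
        if self.kind == "elbow-axis-translation" and not 0.0 < self.parameter < 1.0:
            raise ValidationError("condyle fraction must lie in (0, 1)")


def make_variant(model: LimbModel, protocol: PoseGrid, spec: VariantSpec,
                 glenohumeral: str = "glenohumeral", elbow: str = "elbow",
                 mediolateral_axis=(0.0, 0.0, 1.0)) -> tuple[LimbModel, PoseGrid]:
    """Return a (model, protocol) pair with one variant applied.

    The base model/protocol are never mutated. ``pose-adduction`` edits only
    the protocol context; the other kinds edit only the model.
    """
    if spec.kind == "pose-adduction":
        ctx = protocol.fixed_context.with_angle(glenohumeral, "adduction",
                                                float(spec.parameter))
        return model, PoseGrid(joint=protocol.joint, dof=protocol.dof,
                               values=protocol.values.copy(), fixed_context=ctx)

    variant = model.copy()

    if spec.kind == "scapular-slope":
        if "scapular_slope_deg" not in model.meta:
            raise ValidationError(
                "scapular-slope variant requires meta['scapular_slope_deg'] in the model"
            )
        base_slope = float(model.meta["scapular_slope_deg"])
        delta = np.deg2rad(float(spec.parameter) - base_slope)
        gh = variant.joint(glenohumeral)
        scap = variant.segment(gh.proximal_segment)
        # rotate the scapulocoracoid rest placement about the mediolateral
        # axis through the (parent-frame) glenohumeral centre
        centre_parent = transform_point(scap.rest_transform, gh.centre)
        rot = rotation_about_line(centre_parent, np.asarray(mediolateral_axis, float), delta)
        scap.rest_transform = rot @ np.asarray(scap.rest_transform, dtype=float)
        variant.meta["scapular_slope_deg"] = float(spec.parameter)
        variant.validate()
        return variant, protocol

    # elbow-axis-translation
    cl = model.meta.get("condyle_landmarks")
    if not cl:
        raise ValidationError(
            "elbow-axis-translation requires meta['condyle_landmarks'] = "
            "{'segment', 'lateral', 'medial'}"
        )
    ej = variant.joint(elbow)
    seg = cl["segment"]
    lat = variant.landmark_in_segment(seg, cl["lateral"])
    med = variant.landmark_in_segment(seg, cl["medial"])
    if seg != ej.proximal_segment:
        # express the chord in the joint's proximal frame at reference
        world = apply_pose(variant, variant.reference_pose())
        from ._transforms import invert
        to_prox = invert(world[ej.proximal_segment])
        lat = transform_point(to_prox, transform_point(world[seg], lat))
        med = transform_point(to_prox, transform_point(world[seg], med))
    chord = med - lat
    width = np.linalg.norm(chord)
    if width == 0:
        raise ValidationError("condyle landmarks coincide")
    u = chord / width
    c = np.asarray(ej.centre, dtype=float)
    off_chord = (c - lat) - ((c - lat) @ u) * u  # keep any off-chord offset
    ej.centre = lat + float(spec.parameter) * width * u + off_chord
    variant.validate()
    return variant, protocol


def _rank(values, taxa) -> list[str]:
    """Taxa ordered by value descending; ties broken by taxon name."""
    return [t for _, t in sorted(zip(values, taxa), key=lambda p: (-p[0], p[1]))]


def rank_consistency(tables: dict[str, ActionSummaryTable], action: str,
                     base: str = "base") -> dict:
    """Compare qualitative taxon orderings of one summed action across variants.

    Returns per-variant rankings, Kendall's tau vs the base set, the explicit
    list of inverted taxon pairs, and per-taxon min-max envelopes across
    variants with pairwise overlap flags.
    """
    if base not in tables:
        raise ValidationError(f"base table {base!r} not among {sorted(tables)}")
    taxa = sorted(tables[base].taxa)
    for name, t in tables.items():
        if sorted(t.taxa) != taxa:
            raise ValidationError(f"variant {name!r} has different taxa than base")

    values = {name: t.column(action).reindex(taxa) for name, t in tables.items()}
    base_rank = _rank(values[base].to_numpy(), taxa)
    base_pos = {t: i for i, t in enumerate(base_rank)}

    report = {"action": action, "taxa": taxa, "rankings": {}, "tau": {},
              "inversions": {}, "envelopes": {}, "overlap_pairs": []}
    for name in tables:
        rk = _rank(values[name].to_numpy(), taxa)
        pos = {t: i for i, t in enumerate(rk)}
        tau = kendalltau([base_pos[t] for t in taxa], [pos[t] for t in taxa]).statistic
        inversions = [
            (a, b)
            for i, a in enumerate(taxa) for b in taxa[i + 1:]
            if (base_pos[a] - base_pos[b]) * (pos[a] - pos[b]) < 0
        ]
        report["rankings"][name] = rk
        report["tau"][name] = float(tau)
        report["inversions"][name] = inversions

    env = {t: (min(float(values[n][t]) for n in tables),
               max(float(values[n][t]) for n in tables)) for t in taxa}
    report["envelopes"] = env
    for i, a in enumerate(taxa):
        for b in taxa[i + 1:]:
            lo = max(env[a][0], env[b][0])
            hi = min(env[a][1], env[b][1])
            if lo <= hi:
                report["overlap_pairs"].append((a, b))
    return report
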