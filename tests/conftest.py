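"""Shared fixtures: minimal articulated models built programmatically."""

import numpy as np
import pytest

from ossomech.model import (
    AttachmentPoint,
    DegreeOfFreedom,
    JointAxisSystem,
    LimbModel,
    Muscle,
    MuscleStrand,
    Segment,
)
from ossomech._transforms import make_transform


def make_hinge_model(origin_point, insertion_point, cylinders=(), obstacles=(),
                     centre=(0.0, 0.0, 0.0)):
    """Two-segment model with a single three-DOF joint at ``centre``.

    The proximal-parented axis is world z and carries the DOF named
    ``flexion``; sweeping it is a pure hinge. One muscle "MUS" runs from the
    proximal to the distal segment.
    """
    segments = [
        Segment("prox", None, make_transform(np.eye(3), np.zeros(3))),
        Segment("dist", "prox", make_transform(np.eye(3), np.zeros(3)),
                landmarks={"tip": np.array([0.1, 0.0, 0.0])}),
    ]
    joints = [JointAxisSystem(
        name="hinge", proximal_segment="prox", distal_segment="dist",
        centre=np.asarray(centre, float),
        dof_list=[
            DegreeOfFreedom(("flexion", "extension"), "proximal", np.array([0.0, 0.0, 1.0])),
            DegreeOfFreedom(("adduction", "abduction"), "floating", np.array([0.0, 1.0, 0.0])),
            DegreeOfFreedom(("medial_rotation", "lateral_rotation"), "distal",
                            np.array([1.0, 0.0, 0.0])),
        ],
    )]
    muscles = [Muscle("MUS", strands=[MuscleStrand(
        label="single",
        origin=AttachmentPoint("prox", np.asarray(origin_point, float)),
        insertion=AttachmentPoint("dist", np.asarray(insertion_point, float)),
        obstacles=list(obstacles),
    )])]
    model = LimbModel(taxon="hinge-test", segments=segments, joints=joints,
                      muscles=muscles, cylinders=list(cylinders),
                      norm_circumference=0.1)
    model.validate()
    return model


def make_forelimb_model(taxon="testosaur", pec_origin=(0.05, -0.18, 0.02),
                        elbow_floating=("adduction", "abduction"),
                        elbow_floating_axis=(0.0, 1.0, 0.0)):
    """Scapulocoracoid -> humerus -> antebrachium with the standard joint
    layout: glenohumeral (abd-add proximal, long-axis distal, pro-retr
    floating) and elbow (ext-flex proximal through the epicondyles, long-axis
    distal, abd-add floating)."""
    segments = [
        Segment("scapulocoracoid", None, make_transform(np.eye(3), np.zeros(3)),
                landmarks={"acromion": np.array([0.03, 0.06, -0.02])}),
        Segment("humerus", "scapulocoracoid",
                make_transform(np.eye(3), np.array([0.1, 0.0, 0.0])),
                landmarks={
                    "dpc_apex": np.array([0.08, -0.03, 0.015]),
                    "lateral_epicondyle": np.array([0.3, 0.0, 0.03]),
                    "medial_epicondyle": np.array([0.3, 0.0, -0.03]),
                }),
        Segment("antebrachium", "humerus",
                make_transform(np.eye(3), np.array([0.3, 0.0, 0.0])),
                landmarks={"olecranon": np.array([-0.035, 0.02, 0.0])}),
    ]
    joints = [
        JointAxisSystem(
            name="glenohumeral", proximal_segment="scapulocoracoid",
            distal_segment="humerus", centre=np.array([0.1, 0.0, 0.0]),
            dof_list=[
                DegreeOfFreedom(("adduction", "abduction"), "proximal",
                                np.array([0.0, 1.0, 0.0])),
                DegreeOfFreedom(("protraction", "retraction"), "floating",
                                np.array([0.0, 0.0, 1.0])),
                DegreeOfFreedom(("medial_rotation", "lateral_rotation"), "distal",
                                np.array([1.0, 0.0, 0.0])),
            ],
        ),
        JointAxisSystem(
            name="elbow", proximal_segment="humerus",
            distal_segment="antebrachium", centre=np.array([0.3, 0.0, 0.03]),
            dof_list=[
                DegreeOfFreedom(("flexion", "extension"), "proximal",
                                np.array([0.0, 0.0, 1.0])),
                DegreeOfFreedom(tuple(elbow_floating), "floating",
                                np.asarray(elbow_floating_axis, float)),
                DegreeOfFreedom(("medial_rotation", "lateral_rotation"), "distal",
                                np.array([1.0, 0.0, 0.0])),
            ],
        ),
    ]
    muscles = [
        Muscle("PEC", spanned_joints=["glenohumeral"], strands=[MuscleStrand(
            label="single",
            origin=AttachmentPoint("scapulocoracoid", np.asarray(pec_origin, float)),
            insertion=AttachmentPoint("humerus", np.array([0.08, -0.03, 0.015])),
        )]),
        Muscle("TRL", spanned_joints=["elbow"], strands=[MuscleStrand(
            label="single",
            origin=AttachmentPoint("humerus", np.array([0.2, 0.04, 0.0])),
            insertion=AttachmentPoint("antebrachium", np.array([-0.035, 0.02, 0.0])),
        )]),
    ]
    model = LimbModel(
        taxon=taxon, segments=segments, joints=joints, muscles=muscles,
        norm_circumference=0.2,
        meta={"scapular_slope_deg": 50.0,
              "condyle_landmarks": {"segment": "humerus",
                                    "lateral": "lateral_epicondyle",
                                    "medial": "medial_epicondyle"}},
    )
    model.validate()
    return model


@pytest.fixture
def forelimb_model():
    return make_forelimb_model()


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
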