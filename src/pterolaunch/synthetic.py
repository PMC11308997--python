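"""Synthetic models and sequences for testing and as the packaged stand-in.

Three tiers of generator live here:

* analytic toys (:func:`make_hinge_toy`, :func:`make_pulley_toy`) whose
  moment arms have closed forms, used to verify the virtual-work pipeline
  against independent oracles;
* the packaged reference model (:func:`make_quadruped_toy` /
  :func:`reference_model`): a trunk, one forelimb (3-DOF shoulder, elbow,
  wrist, wing-metacarpal and first-wing-phalanx joints) and one hindlimb
  (3-DOF hip, knee), carrying the full packaged muscle roster, plus the
  three one-second take-off sequences.

Every joint of the reference model carries three rotational coordinates
(long-axis rotation about X, extension about Y, adduction about Z); the
distal joints are driven only in flexion–extension by the sequences.

All attachment coordinates are SYNTHETIC stand-ins: dimensions loosely
echo a 5 m-wingspan animal (humerus ~0.25 m) so magnitudes are plausible,
but no anatomical claim attaches to any coordinate.  The specimen-derived
geometry the roster describes is not redistributable; user-supplied model
files slot in through :mod:`pterolaunch.modelio` unchanged.
"""

from __future__ import annotations

import math
from typing import Callable, Dict, List, Optional, Tuple

import numpy as np

from .geometry import forward_kinematics, route_path
from .kinematics import KeyPose, KinematicSequence, build_takeoff_sequence
from .model import (
    Coordinate,
    Joint,
    MusclePathDef,
    MuscleSpec,
    PathPoint,
    Segment,
    SkeletalModel,
    WrapCylinder,
    complete_pose,
)
from .roster import TABLE_ROWS, RosterRow
from .transforms import RigidTransform

_ROLE_BY_AXIS = {
    "x": ("long_axis_rotation", np.array([1.0, 0.0, 0.0])),
    "y": ("flexion_extension", np.array([0.0, 1.0, 0.0])),
    "z": ("abduction_adduction", np.array([0.0, 0.0, 1.0])),
}

_SUFFIX = {"x": "rot", "y": "ext", "z": "add"}


def _three_dof(
    joint: str, ranges: Optional[Dict[str, Tuple[float, float]]] = None
) -> Tuple[List[str], List[Coordinate]]:
    """Three coordinates in X->Y->Z rotation order for one joint."""
    order, coords = [], []
    for ax in ("x", "y", "z"):
        role, axis = _ROLE_BY_AXIS[ax]
        name = f"{joint}_{_SUFFIX[ax]}"
        order.append(name)
        kw = {}
        if ranges and ax in ranges:
            kw["range"] = ranges[ax]
        coords.append(Coordinate(name=name, joint=joint, axis_role=role, axis=axis, **kw))
    return order, coords


# ---------------------------------------------------------------------------
# Analytic toys
# ---------------------------------------------------------------------------


def make_hinge_toy(
    a=(-1.0, 0.0, 0.0), b=(1.0, 0.0, 0.0)
) -> Tuple[SkeletalModel, Callable[[float], float]]:
    """Single z-axis hinge with one straight MTU, plus its analytic MA(q).

    The muscle runs from point ``a`` fixed on the base to point ``b`` on
    the rotating arm.  L(q)^2 = |a|^2 + |b|^2 - 2 a.Rz(q) b, so the
    virtual-work arm has closed form MA(q) = (a . Rz'(q) b) / L(q); for
    the default attachments this reduces to sin(q/2).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if np.allclose(a, 0) or np.allclose(b, 0):
        raise ValueError("attachment offsets must be non-zero")
    role, axis = _ROLE_BY_AXIS["z"]
    coord = Coordinate(name="hinge_add", joint="hinge", axis_role=role, axis=axis)
    model = SkeletalModel(
        name="hinge_toy",
        segments=[Segment("base"), Segment("arm", parent_joint="hinge")],
        joints=[
            Joint(
                name="hinge",
                parent_segment="base",
                child_segment="arm",
                location_in_parent=np.zeros(3),
                location_in_child=np.zeros(3),
                rotation_order=["hinge_add"],
                coordinates=[coord],
            )
        ],
        muscles=[
            MuscleSpec(
                code="HM",
                name="hinge muscle",
                group="pectoral",
                n_lines=1,
                take_off_relevant=True,
                origin_inference="I",
                insertion_inference="I",
                lines=[
                    MusclePathDef(
                        points=[
                            PathPoint("base", a, kind="origin"),
                            PathPoint("arm", b, kind="insertion"),
                        ]
                    )
                ],
            )
        ],
        analysis_coordinates=["hinge_add"],
    )

    def analytic_ma(q: float) -> float:
        c, s = math.cos(q), math.sin(q)
        Rb = np.array([c * b[0] - s * b[1], s * b[0] + c * b[1], b[2]])
        dRb = np.array([-s * b[0] - c * b[1], c * b[0] - s * b[1], 0.0])
        L = float(np.linalg.norm(a - Rb))
        return float(a @ dRb) / L

    return model, analytic_ma


def make_pulley_toy(
    radius: float = 0.05,
) -> Tuple[SkeletalModel, Tuple[float, float]]:
    """Hinge with a coaxial wrap cylinder: the classic pulley geometry.

    While the muscle path is in contact with the cylinder the tendon-
    excursion arm equals the cylinder radius exactly (dL/dq = ±r), which
    is the packaged expectation.  Returns the model and the contact
    q-interval (determined by scanning wrap activation).
    """
    if radius <= 0:
        raise ValueError("radius must be > 0")
    y_off = -0.6 * radius
    reach = max(1.0, 3.0 * radius)
    a = np.array([-reach, y_off, 0.0])
    b = np.array([reach, y_off, 0.0])
    role, axis = _ROLE_BY_AXIS["z"]
    coord = Coordinate(name="hinge_add", joint="hinge", axis_role=role, axis=axis)
    wrap = WrapCylinder(
        segment="base",
        pose_in_segment=RigidTransform.identity(),
        radius=radius,
        length=4.0 * radius,
        wrap_side="+",
        applies_between=(0, 1),
    )
    model = SkeletalModel(
        name="pulley_toy",
        segments=[Segment("base"), Segment("arm", parent_joint="hinge")],
        joints=[
            Joint(
                name="hinge",
                parent_segment="base",
                child_segment="arm",
                location_in_parent=np.zeros(3),
                location_in_child=np.zeros(3),
                rotation_order=["hinge_add"],
                coordinates=[coord],
            )
        ],
        muscles=[
            MuscleSpec(
                code="PM",
                name="pulley muscle",
                group="pectoral",
                n_lines=1,
                take_off_relevant=True,
                origin_inference="I",
                insertion_inference="I",
                lines=[
                    MusclePathDef(
                        points=[
                            PathPoint("base", a, kind="origin"),
                            PathPoint("arm", b, kind="insertion"),
                        ],
                        wraps=[wrap],
                    )
                ],
            )
        ],
        analysis_coordinates=["hinge_add"],
    )

    # scan for the contact interval around q = 0
    path = model.muscles[0].lines[0]
    qs = np.linspace(-0.5, 0.5, 501)
    active = []
    for q in qs:
        tf = forward_kinematics(model, {"hinge_add": float(q)})
        try:
            routed = route_path(model, tf, path, mtu="PM")
            active.append(routed.wrap_active[0])
        except Exception:
            active.append(False)
    idx = np.flatnonzero(active)
    if idx.size == 0:
        raise RuntimeError("pulley toy generated without wrap contact")
    return model, (float(qs[idx[0]]), float(qs[idx[-1]]))


# ---------------------------------------------------------------------------
# Reference stand-in model
# ---------------------------------------------------------------------------

# segment lengths (m), loosely scaled to a 5 m wingspan
_SEGMENT_LENGTHS = {
    "humerus": 0.25,
    "forearm": 0.40,
    "carpometacarpus": 0.25,
    "wing_phalanx_1": 0.60,
    "wing_phalanx_2": 0.50,
    "femur": 0.22,
    "tibia": 0.30,
}

# joint -> (parent segment, location in parent frame)
_JOINT_PLACEMENTS = {
    "shoulder": ("trunk", (0.0, 0.0, 0.15)),
    "elbow": ("humerus", (0.25, 0.0, 0.0)),
    "wrist": ("forearm", (0.40, 0.0, 0.0)),
    "wing_metacarpal": ("carpometacarpus", (0.25, 0.0, 0.0)),
    "wing_phalanx_1": ("wing_phalanx_1", (0.60, 0.0, 0.0)),
    "hip": ("trunk", (-0.35, -0.05, 0.08)),
    "knee": ("femur", (0.22, 0.0, 0.0)),
}

_JOINT_CHILD = {
    "shoulder": "humerus",
    "elbow": "forearm",
    "wrist": "carpometacarpus",
    "wing_metacarpal": "wing_phalanx_1",
    "wing_phalanx_1": "wing_phalanx_2",
    "hip": "femur",
    "knee": "tibia",
}

# Range-of-motion limits shipped with the stand-in (radians).  Ball joints
# (shoulder, hip) get a wide symmetric range; the distal joints are
# functionally hinge-like, so their long-axis and ab/adduction DOFs are
# restricted to small excursions while flexion-extension stays wide.
_BALL_RANGE = {"x": (-2.6, 2.6), "y": (-2.6, 2.6), "z": (-2.6, 2.6)}
_HINGE_RANGE = {"x": (-0.25, 0.25), "y": (-2.6, 2.6), "z": (-0.25, 0.25)}
_JOINT_RANGES = {
    "shoulder": _BALL_RANGE,
    "hip": _BALL_RANGE,
    "elbow": _HINGE_RANGE,
    "wrist": _HINGE_RANGE,
    "wing_metacarpal": _HINGE_RANGE,
    "wing_phalanx_1": _HINGE_RANGE,
    "knee": _HINGE_RANGE,
}

ANALYSIS_COORDINATES = [
    "shoulder_rot", "shoulder_ext", "shoulder_add",
    "elbow_ext", "wrist_ext", "wing_metacarpal_ext", "wing_phalanx_1_ext",
    "hip_rot", "hip_ext", "hip_add",
    "knee_ext",
]

# synthetic attachment plan: code -> (origin seg, origin pos, [vias], insertion seg, insertion pos)
# positions are metres in segment frames; +X runs distally along each limb segment
_ATTACHMENTS: Dict[str, tuple] = {
    "SCM":   ("trunk", (0.05, -0.02, 0.02), [], "trunk", (0.25, 0.00, 0.03)),
    "SC":    ("trunk", (0.05, -0.03, 0.03), [], "trunk", (0.02, -0.01, 0.10)),
    "LD":    ("trunk", (-0.15, 0.05, 0.05), [], "humerus", (0.12, 0.03, 0.00)),
    "TM":    ("trunk", (-0.10, 0.04, 0.10), [], "humerus", (0.08, 0.03, 0.00)),
    "DS":    ("trunk", (-0.02, 0.06, 0.12), [], "humerus", (0.05, 0.025, 0.01)),
    "SHA":   ("trunk", (0.02, 0.03, 0.12), [], "humerus", (0.04, 0.02, 0.01)),
    "SHP":   ("trunk", (-0.04, 0.04, 0.13), [], "humerus", (0.07, 0.02, -0.01)),
    "SUBS":  ("trunk", (-0.05, 0.00, 0.10), [], "humerus", (0.06, 0.015, -0.02)),
    "TR-S":  ("trunk", (-0.02, 0.03, 0.14), [], "forearm", (-0.04, 0.02, -0.01)),
    "TR-C":  ("trunk", (0.00, -0.02, 0.13), [], "forearm", (-0.04, 0.015, -0.01)),
    # triceps heads hook behind the elbow: posterior (-z) course over the
    # trochlea-like cylinder, engaging in deep flexion
    "TR-M":  ("humerus", (0.10, 0.02, -0.020), [], "forearm", (-0.012, 0.02, -0.028)),
    "TR-L":  ("humerus", (0.10, 0.02, -0.018), [], "forearm", (-0.012, 0.015, -0.027)),
    "PECT":  ("trunk", (0.00, -0.08, 0.05), [], "humerus", (0.05, -0.02, 0.00)),
    "SUPC":  ("trunk", (0.03, -0.06, 0.10), [], "humerus", (0.04, -0.015, 0.01)),
    "CB":    ("trunk", (-0.01, -0.05, 0.11), [], "humerus", (0.06, -0.02, 0.005)),
    "BI":    ("trunk", (0.02, -0.04, 0.12), [], "forearm", (0.03, -0.015, 0.00)),
    "BR":    ("humerus", (0.12, -0.02, 0.00), [], "forearm", (0.04, -0.01, 0.00)),
    "HR":    ("humerus", (0.05, -0.01, 0.01), [], "forearm", (0.05, -0.005, 0.012)),
    "FDL":   ("humerus", (0.24, -0.03, 0.00), [("forearm", (0.20, -0.02, 0.00)),
              ("carpometacarpus", (0.12, -0.015, 0.00))], "wing_phalanx_1", (0.03, -0.015, 0.00)),
    "FDL-U": ("forearm", (0.15, -0.02, 0.00), [("carpometacarpus", (0.12, -0.015, 0.00))],
              "wing_phalanx_1", (0.03, -0.014, 0.002)),
    "EDL":   ("humerus", (0.24, 0.03, 0.00), [("forearm", (0.20, 0.02, 0.00)),
              ("carpometacarpus", (0.12, 0.015, 0.00))], "wing_phalanx_1", (0.03, 0.015, 0.00)),
    "FCU":   ("humerus", (0.24, -0.03, -0.01), [], "carpometacarpus", (0.03, -0.015, 0.005)),
    "FCR":   ("humerus", (0.24, -0.03, 0.01), [], "carpometacarpus", (0.02, -0.012, 0.008)),
    "ECU":   ("humerus", (0.24, 0.03, -0.01), [], "carpometacarpus", (0.05, 0.015, -0.005)),
    "ECR":   ("humerus", (0.24, 0.03, 0.01), [], "carpometacarpus", (0.02, 0.012, 0.008)),
    "SUP":   ("humerus", (0.23, 0.02, 0.015), [], "forearm", (0.30, 0.01, 0.01)),
    "PT":    ("humerus", (0.24, -0.03, 0.005), [], "forearm", (0.20, -0.01, -0.01)),
    "PQ":    ("forearm", (0.25, -0.01, 0.00), [], "forearm", (0.35, -0.012, 0.005)),
    "FDB":   ("carpometacarpus", (0.05, -0.01, 0.00), [], "wing_phalanx_1", (0.02, -0.01, 0.00)),
    "EDB":   ("carpometacarpus", (0.05, 0.01, 0.00), [], "wing_phalanx_1", (0.02, 0.01, 0.00)),
    "ADD":   ("trunk", (-0.38, -0.10, 0.02), [], "femur", (0.10, -0.02, -0.01)),
    "IFM":   ("trunk", (-0.30, 0.00, 0.06), [], "femur", (0.03, 0.02, 0.01)),
    "PIFE":  ("trunk", (-0.40, -0.09, 0.04), [], "femur", (0.03, -0.01, 0.02)),
    "PIFI":  ("trunk", (-0.30, -0.02, 0.05), [], "femur", (0.02, 0.015, 0.00)),
    "AMB":   ("trunk", (-0.33, -0.09, 0.06), [], "tibia", (0.03, 0.02, 0.00)),
    "ITB":   ("trunk", (-0.30, 0.00, 0.07), [], "tibia", (0.03, 0.02, 0.005)),
    "FTE":   ("trunk", (-0.42, -0.02, 0.06), [], "tibia", (0.05, -0.02, 0.005)),
    "FTI-I": ("trunk", (-0.42, -0.08, 0.03), [], "tibia", (0.06, -0.02, 0.00)),
    "FTI-II": ("trunk", (-0.43, -0.03, 0.05), [], "tibia", (0.06, -0.02, 0.005)),
    "ILF":   ("trunk", (-0.43, -0.01, 0.06), [], "tibia", (0.07, -0.015, 0.01)),
    "CFB":   ("trunk", (-0.45, -0.04, 0.04), [], "femur", (0.06, -0.015, 0.01)),
    "FMTE":  ("femur", (0.05, 0.01, 0.01), [("femur", (0.20, 0.025, 0.005))],
              "tibia", (0.03, 0.025, 0.00)),
    "FMTI":  ("femur", (0.05, 0.01, -0.01), [("femur", (0.20, 0.025, -0.005))],
              "tibia", (0.03, 0.024, -0.005)),
}

#: muscles carrying a wrap cylinder in the stand-in geometry, and at which joint
_WRAPPED = {"TR-M": "elbow", "TR-L": "elbow"}

_WRAP_RADIUS = 0.018
_WRAP_LENGTH = 0.12


def _elbow_wrap() -> WrapCylinder:
    # cylinder axis along the elbow's flexion (Y) axis: rotate local z -> y
    Rx = RigidTransform.from_axis_angle((1.0, 0.0, 0.0), -math.pi / 2.0)
    pose = RigidTransform(Rx.R, np.array([0.25, 0.0, 0.0]))
    return WrapCylinder(
        segment="humerus",
        pose_in_segment=pose,
        radius=_WRAP_RADIUS,
        length=_WRAP_LENGTH,
        wrap_side="-",
        applies_between=(0, 1),
    )


def _build_muscle(row: RosterRow, rng: np.random.Generator) -> MuscleSpec:
    oseg, opos, vias, iseg, ipos = _ATTACHMENTS[row.code]
    lines: List[MusclePathDef] = []
    for i in range(row.n_lines):
        spread = (i - (row.n_lines - 1) / 2.0) * 0.012
        jitter = rng.normal(0.0, 0.001, size=(2 + len(vias), 3))
        pts = [
            PathPoint(oseg, np.asarray(opos) + np.array([0.0, spread * 0.4, spread])
                      + jitter[0], kind="origin")
        ]
        for k, (vseg, vpos) in enumerate(vias):
            pts.append(PathPoint(vseg, np.asarray(vpos) + jitter[1 + k], kind="via"))
        pts.append(
            PathPoint(iseg, np.asarray(ipos) + np.array([0.0, spread * 0.2, spread * 0.5])
                      + jitter[-1], kind="insertion")
        )
        wraps = []
        if row.code in _WRAPPED:
            w = _elbow_wrap()
            w.applies_between = (len(pts) - 2, len(pts) - 1)
            wraps.append(w)
        lines.append(MusclePathDef(points=pts, wraps=wraps))
    return MuscleSpec(
        code=row.code,
        name=row.name,
        group=row.group,
        n_lines=row.n_lines,
        take_off_relevant=row.take_off_relevant,
        origin_inference=row.origin_inference,
        insertion_inference=row.insertion_inference,
        lines=lines,
        origin_description=row.origin_description + " [synthetic stand-in coordinates]",
        insertion_description=row.insertion_description + " [synthetic stand-in coordinates]",
    )


def reference_model(seed: int = 0) -> SkeletalModel:
    """The packaged stand-in model: full skeleton tree plus the full roster."""
    rng = np.random.default_rng(seed)
    segments = [Segment("trunk")]
    joints = []
    for jname, (parent, loc) in _JOINT_PLACEMENTS.items():
        child = _JOINT_CHILD[jname]
        order, coords = _three_dof(jname, _JOINT_RANGES[jname])
        joints.append(
            Joint(
                name=jname,
                parent_segment=parent,
                child_segment=child,
                location_in_parent=np.asarray(loc),
                location_in_child=np.zeros(3),
                rotation_order=order,
                coordinates=coords,
            )
        )
        segments.append(Segment(child, parent_joint=jname))
    muscles = [_build_muscle(row, rng) for row in TABLE_ROWS]
    return SkeletalModel(
        name="ornithocheiraean_standin",
        segments=segments,
        joints=joints,
        muscles=muscles,
        analysis_coordinates=list(ANALYSIS_COORDINATES),
    )


# ---------------------------------------------------------------------------
# Default key poses for the three take-off styles
# ---------------------------------------------------------------------------

# Joint-space key-pose tables (radians).  PACKAGE DEFAULTS: plausible
# joint-space shapes for each style's phase structure, not measured angles.
_KEY_POSES: Dict[str, List[Tuple[float, str, Dict[str, float]]]] = {
    "bipedal_burst": [
        (0.00, "deepest crouch", dict(
            hip_ext=-1.0, hip_add=0.15, hip_rot=0.1, knee_ext=-1.2,
            shoulder_ext=-0.8, shoulder_add=0.3, shoulder_rot=-0.2,
            elbow_ext=-1.5, wrist_ext=-1.0, wing_metacarpal_ext=-1.7,
            wing_phalanx_1_ext=-0.5)),
        (0.40, "ankle lifted", dict(
            hip_ext=-0.5, hip_add=0.10, hip_rot=0.05, knee_ext=-0.6,
            shoulder_ext=-0.7, shoulder_add=0.25, shoulder_rot=-0.15,
            elbow_ext=-1.4, wrist_ext=-0.9, wing_metacarpal_ext=-1.6,
            wing_phalanx_1_ext=-0.4)),
        (0.70, "fully digitigrade", dict(
            hip_ext=-0.15, hip_add=0.05, knee_ext=-0.2,
            shoulder_ext=-0.3, shoulder_add=0.0, shoulder_rot=-0.05,
            elbow_ext=-0.8, wrist_ext=-0.5, wing_metacarpal_ext=-0.9,
            wing_phalanx_1_ext=-0.2)),
        (1.00, "launch", dict(
            hip_ext=0.30, hip_add=-0.05, hip_rot=-0.05, knee_ext=0.25,
            shoulder_ext=0.5, shoulder_add=-0.4, shoulder_rot=0.1,
            elbow_ext=0.3, wrist_ext=0.2, wing_metacarpal_ext=0.0,
            wing_phalanx_1_ext=0.2)),
    ],
    "bipedal_countermotion": [
        (0.00, "bipedal stance", dict(
            hip_ext=-0.2, hip_add=0.05, knee_ext=-0.25,
            shoulder_ext=-0.5, shoulder_add=0.2, elbow_ext=-1.2,
            wrist_ext=-0.8, wing_metacarpal_ext=-1.4, wing_phalanx_1_ext=-0.4)),
        (0.30, "mid countermotion", dict(
            hip_ext=-0.6, hip_add=0.10, hip_rot=0.05, knee_ext=-0.8,
            shoulder_ext=-0.6, shoulder_add=0.25, elbow_ext=-1.55,
            wrist_ext=-0.9, wing_metacarpal_ext=-1.5, wing_phalanx_1_ext=-0.45)),
        (0.55, "deepest countermotion", dict(
            hip_ext=-0.9, hip_add=0.12, hip_rot=0.08, knee_ext=-1.1,
            shoulder_ext=-0.5, shoulder_add=0.15, elbow_ext=-1.0,
            wrist_ext=-0.6, wing_metacarpal_ext=-1.1, wing_phalanx_1_ext=-0.3)),
        (1.00, "launch", dict(
            hip_ext=0.30, hip_add=-0.05, hip_rot=-0.05, knee_ext=0.30,
            shoulder_ext=0.5, shoulder_add=-0.4, shoulder_rot=0.1,
            elbow_ext=0.3, wrist_ext=0.2, wing_metacarpal_ext=0.0,
            wing_phalanx_1_ext=0.2)),
    ],
    "quadrupedal": [
        (0.00, "quadrupedal stance", dict(
            shoulder_ext=-0.4, shoulder_add=0.2, elbow_ext=-0.9,
            wrist_ext=-1.2, wing_metacarpal_ext=-1.5, wing_phalanx_1_ext=-0.4,
            hip_ext=-0.4, hip_add=0.08, knee_ext=-0.5)),
        (0.35, "deepest crouch", dict(
            shoulder_ext=-0.7, shoulder_add=0.3, shoulder_rot=-0.1,
            elbow_ext=-1.6, wrist_ext=-1.3, wing_metacarpal_ext=-1.6,
            wing_phalanx_1_ext=-0.45,
            hip_ext=-0.9, hip_add=0.12, hip_rot=0.08, knee_ext=-1.0)),
        (0.55, "hindlimb liftoff", dict(
            shoulder_ext=-0.5, shoulder_add=0.2, elbow_ext=-1.0,
            wrist_ext=-1.0, wing_metacarpal_ext=-1.3, wing_phalanx_1_ext=-0.35,
            hip_ext=-0.2, hip_add=0.05, knee_ext=0.10)),
        (0.65, "vault complete", dict(
            shoulder_ext=-0.2, shoulder_add=0.1, elbow_ext=-0.6,
            wrist_ext=-0.7, wing_metacarpal_ext=-0.9, wing_phalanx_1_ext=-0.25,
            hip_ext=0.40, hip_add=-0.02, hip_rot=-0.10, knee_ext=-0.30)),
        (1.00, "launch", dict(
            shoulder_ext=0.60, shoulder_add=-0.3, shoulder_rot=0.15,
            elbow_ext=0.40, wrist_ext=0.10, wing_metacarpal_ext=0.30,
            wing_phalanx_1_ext=0.30,
            hip_ext=0.50, hip_add=-0.05, hip_rot=-0.15, knee_ext=-0.60)),
    ],
}


def default_key_poses(model: SkeletalModel, style: str) -> List[KeyPose]:
    """The packaged synthetic key poses for one style, as complete poses."""
    if style not in _KEY_POSES:
        raise ValueError(f"unknown take-off style '{style}'")
    return [
        KeyPose(pose=complete_pose(model, angles), time_fraction=frac, label=label)
        for frac, label, angles in _KEY_POSES[style]
    ]


def make_quadruped_toy(
    seed: int = 0,
) -> Tuple[SkeletalModel, Dict[str, KinematicSequence]]:
    """The packaged reference model plus its three take-off sequences.

    Deterministic given ``seed``: identical seeds produce byte-identical
    models and sequences.
    """
    model = reference_model(seed)
    sequences = {
        style: build_takeoff_sequence(model, style, default_key_poses(model, style))
        for style in ("bipedal_burst", "bipedal_countermotion", "quadrupedal")
    }
    return model, sequences
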