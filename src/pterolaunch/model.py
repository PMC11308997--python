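"""Domain types for the musculoskeletal model.

The skeleton is a tree of rigid segments linked by joints whose rotational
coordinates follow fixed axis conventions: positive X rotation is long-axis
rotation (pronation), positive Y rotation is extension, positive Z rotation
is adduction.  Muscles are carried as muscle–tendon units (MTUs): ordered
attachment points (origin, optional via points, insertion) plus optional
wrapping cylinders that deflect the line of action around bone.

A :class:`Pose` is simply a ``dict`` mapping coordinate names to angles in
radians.  Angles are radians everywhere inside the package; degrees appear
only at file boundaries with explicit unit tags.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Dict, Iterator, List, Optional, Sequence, Tuple

import numpy as np

from .transforms import RigidTransform

logger = logging.getLogger(__name__)

Pose = Dict[str, float]

#: axis roles, in the rotation order applied at each joint (X -> Y -> Z)
AXIS_ROLES = ("long_axis_rotation", "flexion_extension", "abduction_adduction")

#: extant-phylogenetic-bracket inference grades for soft-tissue reconstruction
EPB_LEVELS = ("I", "I'", "II", "II'")

FULL_CIRCLE = (-math.pi, math.pi)


@dataclass
class Segment:
    """A rigid body in the kinematic tree."""

    name: str
    parent_joint: Optional[str] = None  # None marks the root
    fixed_offset: RigidTransform = field(default_factory=RigidTransform.identity)


@dataclass
class Coordinate:
    """One rotational generalized coordinate of a joint."""

    name: str
    joint: str
    axis_role: str
    axis: np.ndarray
    range: Tuple[float, float] = FULL_CIRCLE
    sign_convention: str = ""

    def __post_init__(self) -> None:
        self.axis = np.asarray(self.axis, dtype=float).reshape(3)
        self.range = (float(self.range[0]), float(self.range[1]))


@dataclass
class Joint:
    """A joint with 1–3 rotational coordinates applied in ``rotation_order``."""

    name: str
    parent_segment: str
    child_segment: str
    location_in_parent: np.ndarray
    location_in_child: np.ndarray
    rotation_order: List[str]
    coordinates: List[Coordinate]

    def __post_init__(self) -> None:
        self.location_in_parent = np.asarray(self.location_in_parent, dtype=float).reshape(3)
        self.location_in_child = np.asarray(self.location_in_child, dtype=float).reshape(3)


@dataclass
class PathPoint:
    """A muscle attachment or via point, fixed in a segment's frame."""

    segment: str
    local_position: np.ndarray
    kind: str = "via"  # origin | via | insertion

    def __post_init__(self) -> None:
        self.local_position = np.asarray(self.local_position, dtype=float).reshape(3)


@dataclass
class WrapCylinder:
    """A cylindrical wrapping surface fixed in a segment's frame.

    The cylinder axis is the local +Z axis of ``pose_in_segment`` and the
    surface is valid over z in [-length/2, +length/2].  ``wrap_side`` picks
    the travel sense around the axis: '+' wraps counter-clockwise about
    local +Z from entry to exit tangent point, '-' clockwise.  The wrap
    applies only to the straight sub-segment between the two consecutive
    path points named by ``applies_between``.
    """

    segment: str
    pose_in_segment: RigidTransform
    radius: float
    length: float
    wrap_side: str  # '+' or '-'
    applies_between: Tuple[int, int]


@dataclass
class MusclePathDef:
    """One MTU line of action: ordered path points plus wrap objects."""

    points: List[PathPoint]
    wraps: List[WrapCylinder] = field(default_factory=list)


@dataclass
class MuscleSpec:
    """A muscle roster row: anatomy metadata plus its MTU line definitions.

    ``n_lines`` is the MTU multiplicity — broad muscles are carried as
    several lines of action whose moment arms are averaged downstream.
    Origin/insertion inference levels are extant-phylogenetic-bracket
    grades (I, I', II, II'); they are carried as data only.
    """

    code: str
    name: str
    group: str  # pectoral | pelvic
    n_lines: int
    take_off_relevant: bool
    origin_inference: str
    insertion_inference: str
    lines: List[MusclePathDef] = field(default_factory=list)
    origin_description: str = ""
    insertion_description: str = ""


@dataclass
class SkeletalModel:
    """The full model: segment tree, joints, muscle roster, reported coordinates."""

    segments: List[Segment]
    joints: List[Joint]
    muscles: List[MuscleSpec]
    analysis_coordinates: List[str] = field(default_factory=list)
    name: str = "model"

    # ---- lookup helpers -------------------------------------------------
    def segment_map(self) -> Dict[str, Segment]:
        return {s.name: s for s in self.segments}

    def joint_map(self) -> Dict[str, Joint]:
        return {j.name: j for j in self.joints}

    def coordinate_map(self) -> Dict[str, Coordinate]:
        return {c.name: c for j in self.joints for c in j.coordinates}

    def muscle_map(self) -> Dict[str, MuscleSpec]:
        return {m.code: m for m in self.muscles}

    def root_segment(self) -> Segment:
        roots = [s for s in self.segments if s.parent_joint is None]
        if len(roots) != 1:
            raise ValueError(f"model has {len(roots)} root segments, expected exactly 1")
        return roots[0]

    def iter_mtus(self) -> Iterator[Tuple[str, int, MusclePathDef]]:
        """Yield (muscle code, line index, path definition) for every MTU."""
        for m in self.muscles:
            for i, line in enumerate(m.lines):
                yield m.code, i, line

    def mtu_id(self, code: str, line_index: int) -> str:
        m = self.muscle_map()[code]
        return code if m.n_lines == 1 else f"{code}.{line_index + 1}"


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------


def validate_model(model: SkeletalModel) -> List[str]:
    """Check every structural invariant; return one diagnostic per violation.

    An empty list means the model is well formed.  Violations are reported
    as human-readable strings, never raised.
    """
    diags: List[str] = []
    seg_names = [s.name for s in model.segments]
    seg_set = set(seg_names)
    if len(seg_set) != len(seg_names):
        dupes = {n for n in seg_names if seg_names.count(n) > 1}
        diags.append(f"duplicate segment names: {sorted(dupes)}")

    roots = [s for s in model.segments if s.parent_joint is None]
    if len(roots) != 1:
        diags.append(f"expected exactly one root segment, found {len(roots)}")

    joint_names = [j.name for j in model.joints]
    if len(set(joint_names)) != len(joint_names):
        diags.append("duplicate joint names")

    jmap = {j.name: j for j in model.joints}
    for s in model.segments:
        if s.parent_joint is not None and s.parent_joint not in jmap:
            diags.append(f"segment '{s.name}' references unknown joint '{s.parent_joint}'")

    for j in model.joints:
        for ref in (j.parent_segment, j.child_segment):
            if ref not in seg_set:
                diags.append(f"joint '{j.name}' references unknown segment '{ref}'")
        if not 1 <= len(j.coordinates) <= 3:
            diags.append(f"joint '{j.name}' has {len(j.coordinates)} coordinates (need 1-3)")
        if sorted(j.rotation_order) != sorted(c.name for c in j.coordinates):
            diags.append(f"joint '{j.name}' rotation_order does not match its coordinates")
        for c in j.coordinates:
            if abs(np.linalg.norm(c.axis) - 1.0) > 1e-9:
                diags.append(f"coordinate '{c.name}': non-unit axis {c.axis.tolist()}")
            if not c.range[0] < c.range[1]:
                diags.append(f"coordinate '{c.name}': empty range {c.range}")
            if c.axis_role not in AXIS_ROLES:
                diags.append(f"coordinate '{c.name}': unknown axis role '{c.axis_role}'")

    # tree check: walking parents from every segment must reach the root
    # without revisiting a segment (acyclic, connected)
    if len(roots) == 1 and not any(d.startswith("joint") or "unknown joint" in d for d in diags):
        for s in model.segments:
            seen = set()
            cur = s
            while cur.parent_joint is not None:
                if cur.name in seen:
                    diags.append(f"cycle in segment tree at '{cur.name}'")
                    break
                seen.add(cur.name)
                parent_name = jmap[cur.parent_joint].parent_segment
                nxt = next((x for x in model.segments if x.name == parent_name), None)
                if nxt is None:
                    break
                cur = nxt

    coord_names = [c.name for j in model.joints for c in j.coordinates]
    if len(set(coord_names)) != len(coord_names):
        diags.append("duplicate coordinate names")
    coord_set = set(coord_names)
    for cname in model.analysis_coordinates:
        if cname not in coord_set:
            diags.append(f"analysis coordinate '{cname}' not defined by any joint")

    codes = [m.code for m in model.muscles]
    if len(set(codes)) != len(codes):
        dupes = {c for c in codes if codes.count(c) > 1}
        diags.append(f"duplicate muscle codes: {sorted(dupes)}")
    for m in model.muscles:
        if m.group not in ("pectoral", "pelvic"):
            diags.append(f"muscle '{m.code}': unknown group '{m.group}'")
        for lvl, which in ((m.origin_inference, "origin"), (m.insertion_inference, "insertion")):
            if lvl not in EPB_LEVELS:
                diags.append(f"muscle '{m.code}': invalid {which} inference level '{lvl}'")
        if m.n_lines < 1:
            diags.append(f"muscle '{m.code}': n_lines must be >= 1")
        if m.lines and len(m.lines) != m.n_lines:
            diags.append(
                f"muscle '{m.code}': n_lines={m.n_lines} but {len(m.lines)} path definitions"
            )
        for i, line in enumerate(m.lines):
            if len(line.points) < 2:
                diags.append(f"muscle '{m.code}' line {i}: fewer than 2 path points")
                continue
            if line.points[0].kind != "origin" or line.points[-1].kind != "insertion":
                diags.append(
                    f"muscle '{m.code}' line {i}: path must start at origin and end at insertion"
                )
            if any(p.kind != "via" for p in line.points[1:-1]):
                diags.append(f"muscle '{m.code}' line {i}: interior points must be via points")
            for p in line.points:
                if p.segment not in seg_set:
                    diags.append(
                        f"muscle '{m.code}' line {i}: path point references "
                        f"unknown segment '{p.segment}'"
                    )
            for w in line.wraps:
                if w.segment not in seg_set:
                    diags.append(
                        f"muscle '{m.code}' line {i}: wrap references unknown segment '{w.segment}'"
                    )
                if w.radius <= 0:
                    diags.append(f"muscle '{m.code}' line {i}: wrap radius must be > 0")
                if w.length <= 0:
                    diags.append(f"muscle '{m.code}' line {i}: wrap length must be > 0")
                if w.wrap_side not in ("+", "-"):
                    diags.append(f"muscle '{m.code}' line {i}: wrap_side must be '+' or '-'")
                a, b = w.applies_between
                if b != a + 1 or a < 0 or b >= len(line.points):
                    diags.append(
                        f"muscle '{m.code}' line {i}: wrap applies_between {w.applies_between} "
                        "is not a valid consecutive point pair"
                    )
    return diags


def count_mtus(model: SkeletalModel, group: str, take_off_only: bool = False) -> int:
    """Total MTU line count for a muscle group.

    Sums ``n_lines`` over muscles in ``group``; with ``take_off_only`` the
    muscles flagged as not directly related to the take-offs are excluded.
    """
    if group not in ("pectoral", "pelvic"):
        raise ValueError(f"unknown muscle group '{group}'")
    total = 0
    for m in model.muscles:
        if m.group != group:
            continue
        if take_off_only and not m.take_off_relevant:
            continue
        total += m.n_lines
    return total


def clamp_pose(pose: Pose, model: SkeletalModel) -> Pose:
    """Clamp angles to their coordinate ranges; clamping is logged, never silent."""
    cmap = model.coordinate_map()
    out: Pose = {}
    for name, q in pose.items():
        c = cmap.get(name)
        if c is None:
            out[name] = q
            continue
        lo, hi = c.range
        qc = min(max(q, lo), hi)
        if qc != q:
            logger.warning(
                "clamped coordinate %s from %.6f to %.6f rad (range [%.6f, %.6f])",
                name, q, qc, lo, hi,
            )
        out[name] = qc
    return out


def complete_pose(model: SkeletalModel, values: Optional[Pose] = None) -> Pose:
    """A pose with every model coordinate present, defaulting to zero."""
    pose = {c.name: 0.0 for j in model.joints for c in j.coordinates}
    if values:
        for k, v in values.items():
            if k not in pose:
                raise KeyError(f"unknown coordinate '{k}'")
            pose[k] = float(v)
    return pose
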