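"""Muscle moment arms by the virtual-work (tendon-excursion) method.

The moment arm of an MTU about a generalized coordinate q is MA = -dL/dq,
where L is the muscle–tendon length: a muscle whose length shortens as q
increases generates positive generalized torque about q.  The derivative
is taken by central finite difference (default step 1e-4 rad), falling
back to a one-sided difference (logged) at coordinate range boundaries.

``hinge_moment_arm_oracle`` is an independent geometric check for straight
single-joint lines of action: the signed perpendicular distance from the
joint axis to the line of action.  The two routes must agree to finite-
difference tolerance; the oracle never substitutes for the virtual-work
computation in the pipeline.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np

from .geometry import forward_kinematics, path_length, route_path
from .model import MusclePathDef, Pose, SkeletalModel
from .transforms import RigidTransform

logger = logging.getLogger(__name__)

DEFAULT_FD_STEP = 1e-4  # radians


@dataclass
class MomentArmTrace:
    """Per-frame moment arms of one MTU about one coordinate (metres).

    ``wrap_transition_frames`` flags frames adjacent to a change in wrap
    activation, where the moment arm may be discontinuous; values are
    reported as computed, never smoothed.
    """

    mtu: str
    coordinate: str
    times: np.ndarray
    values: np.ndarray
    wrap_transition_frames: List[int] = field(default_factory=list)


def moment_arm(
    model: SkeletalModel,
    pose: Pose,
    path: MusclePathDef,
    coordinate: str,
    step: float = DEFAULT_FD_STEP,
    mtu: str = "?",
) -> float:
    """Virtual-work moment arm of one MTU line about one coordinate."""
    if step <= 0:
        raise ValueError("finite-difference step must be > 0")
    coord = model.coordinate_map().get(coordinate)
    if coord is None:
        raise KeyError(f"unknown coordinate '{coordinate}'")
    q = pose[coordinate]
    lo, hi = coord.range
    q_hi = min(q + step, hi)
    q_lo = max(q - step, lo)
    if q_hi - q_lo <= 0:
        raise ValueError(f"coordinate '{coordinate}' range too narrow for FD step {step}")
    if q_hi < q + step or q_lo > q - step:
        logger.warning(
            "one-sided finite difference for %s at q=%.6f (range [%.6f, %.6f])",
            coordinate, q, lo, hi,
        )
    pose_hi = dict(pose)
    pose_hi[coordinate] = q_hi
    pose_lo = dict(pose)
    pose_lo[coordinate] = q_lo
    L_hi = path_length(model, pose_hi, path, mtu=mtu)
    L_lo = path_length(model, pose_lo, path, mtu=mtu)
    return -(L_hi - L_lo) / (q_hi - q_lo)


def _descendants(model: SkeletalModel, joint_name: str) -> Set[str]:
    """Segments distal to a joint (the child segment and everything below it)."""
    jmap = model.joint_map()
    children: Dict[str, List[str]] = {}
    for j in model.joints:
        children.setdefault(j.parent_segment, []).append(j.child_segment)
    out: Set[str] = set()
    stack = [jmap[joint_name].child_segment]
    while stack:
        s = stack.pop()
        if s in out:
            continue
        out.add(s)
        stack.extend(children.get(s, []))
    return out


def mtu_spans_coordinate(model: SkeletalModel, path: MusclePathDef, coordinate: str) -> bool:
    """True iff rotating the coordinate can change the MTU's routed geometry."""
    coord = model.coordinate_map()[coordinate]
    sub = _descendants(model, coord.joint)
    segs = {p.segment for p in path.points} | {w.segment for w in path.wraps}
    return bool(segs & sub) and bool(segs - sub)


def world_coordinate_axis(
    model: SkeletalModel, pose: Pose, coordinate: str
) -> Tuple[np.ndarray, np.ndarray]:
    """World-space (point on axis, unit axis direction) of a coordinate.

    For intrinsic rotation order the instantaneous axis of the k-th
    coordinate is pre-rotated by the joint rotations preceding it.
    """
    coord = model.coordinate_map()[coordinate]
    joint = model.joint_map()[coord.joint]
    transforms = forward_kinematics(model, pose)
    Xp = transforms[joint.parent_segment]
    c_world = Xp.apply(joint.location_in_parent)
    R_pre = np.eye(3)
    cmap = {c.name: c for c in joint.coordinates}
    for cname in joint.rotation_order:
        if cname == coordinate:
            break
        cc = cmap[cname]
        R_pre = R_pre @ RigidTransform.from_axis_angle(cc.axis, pose[cname]).R
    axis_world = Xp.R @ R_pre @ coord.axis
    return c_world, axis_world / np.linalg.norm(axis_world)


def hinge_moment_arm_oracle(
    model: SkeletalModel,
    pose: Pose,
    path: MusclePathDef,
    coordinate: str,
) -> float:
    """Signed perpendicular-distance moment arm for a straight one-joint MTU.

    Valid only for an unwrapped two-point line of action crossing exactly
    the joint owning ``coordinate``: the moment of a unit muscle tension
    applied at the distal attachment, about the world-space joint axis,
    ((p - c) x u) . a, signed to match the virtual-work convention.
    """
    if path.wraps or len(path.points) != 2:
        raise ValueError("oracle requires a straight, unwrapped two-point path")
    coord = model.coordinate_map()[coordinate]
    sub = _descendants(model, coord.joint)
    in_sub = [p.segment in sub for p in path.points]
    if in_sub[0] == in_sub[1]:
        raise ValueError("oracle requires the path to cross exactly the coordinate's joint")
    transforms = forward_kinematics(model, pose)
    pts = [transforms[p.segment].apply(p.local_position) for p in path.points]
    distal, proximal = (pts[0], pts[1]) if in_sub[0] else (pts[1], pts[0])
    u = proximal - distal
    norm = np.linalg.norm(u)
    if norm == 0:
        raise ValueError("degenerate zero-length line of action")
    u = u / norm
    c_world, axis_world = world_coordinate_axis(model, pose, coordinate)
    return float(np.cross(distal - c_world, u) @ axis_world)


def trace_sequence(
    model: SkeletalModel,
    sequence,
    mtus: Optional[Sequence[Tuple[str, int]]] = None,
    coordinates: Optional[Sequence[str]] = None,
    n_frames: int = 101,
    step: float = DEFAULT_FD_STEP,
) -> List[MomentArmTrace]:
    """Moment-arm traces over a take-off sequence.

    Evaluates every (MTU, coordinate) pair at ``n_frames`` equally spaced
    times on [0, 1].  MTUs that do not span a coordinate's joint get an
    identically-zero trace without finite differencing.
    """
    if n_frames < 2:
        raise ValueError("n_frames must be >= 2")
    if coordinates is None:
        coordinates = list(model.analysis_coordinates)
    mmap = model.muscle_map()
    if mtus is None:
        mtus = [(code, i) for code, i, _ in model.iter_mtus()]
    paths = {(code, i): mmap[code].lines[i] for code, i in mtus}
    spans = {
        (key, c): mtu_spans_coordinate(model, p, c)
        for key, p in paths.items()
        for c in coordinates
    }

    times = np.linspace(0.0, 1.0, n_frames)
    values = {
        (key, c): np.zeros(n_frames) for key in paths for c in coordinates
    }
    wrap_patterns: Dict[Tuple[str, int], List[Tuple[bool, ...]]] = {k: [] for k in paths}

    for fi, t in enumerate(times):
        pose = sequence.pose_at(t)
        base_tf = forward_kinematics(model, pose)
        for key, p in paths.items():
            routed = route_path(model, base_tf, p, mtu=model.mtu_id(*key))
            wrap_patterns[key].append(tuple(routed.wrap_active))
        for c in coordinates:
            coord = model.coordinate_map()[c]
            q = pose[c]
            lo, hi = coord.range
            q_hi, q_lo = min(q + step, hi), max(q - step, lo)
            pose_hi = dict(pose)
            pose_hi[c] = q_hi
            pose_lo = dict(pose)
            pose_lo[c] = q_lo
            tf_hi = forward_kinematics(model, pose_hi)
            tf_lo = forward_kinematics(model, pose_lo)
            for key, p in paths.items():
                if not spans[(key, c)]:
                    continue
                mtu_name = model.mtu_id(*key)
                L_hi = route_path(model, tf_hi, p, mtu=mtu_name).length
                L_lo = route_path(model, tf_lo, p, mtu=mtu_name).length
                values[(key, c)][fi] = -(L_hi - L_lo) / (q_hi - q_lo)

    out: List[MomentArmTrace] = []
    for key in paths:
        transitions = [
            fi
            for fi in range(1, n_frames)
            if wrap_patterns[key][fi] != wrap_patterns[key][fi - 1]
        ]
        flagged = sorted({f for fi in transitions for f in (fi - 1, fi)})
        for c in coordinates:
            out.append(
                MomentArmTrace(
                    mtu=model.mtu_id(*key),
                    coordinate=c,
                    times=times.copy(),
                    values=values[(key, c)].copy(),
                    wrap_transition_frames=list(flagged),
                )
            )
    return out
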