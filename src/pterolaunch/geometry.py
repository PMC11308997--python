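"""Forward kinematics and muscle-path routing.

Path routing implements the obstacle-set construction for a single
cylindrical wrap per flanking-point pair: if the straight sub-segment
between the two flanking points penetrates the cylinder, it is replaced by
a tangent line to the surface, the shortest geodesic over the surface on
the requested side, and a tangent line off again.  Lengths are computed in
closed form from the tangent construction (the cylinder is unrolled to a
plane, where the geodesic is a straight line); the discretised arc in the
output polyline is for inspection and plotting only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List

import numpy as np

from .model import MusclePathDef, Pose, SkeletalModel, WrapCylinder
from .transforms import RigidTransform

WorldTransforms = Dict[str, RigidTransform]

ARC_SAMPLES = 32  # polyline resolution of a wrapped arc (display only)


class PathRoutingError(ValueError):
    """Raised when a muscle path cannot be routed (e.g. attachment inside a wrap)."""


def joint_rotation(joint, pose: Pose) -> RigidTransform:
    """Intrinsic rotation of a joint at the given pose, in rotation_order."""
    cmap = {c.name: c for c in joint.coordinates}
    R = RigidTransform.identity()
    for cname in joint.rotation_order:
        c = cmap[cname]
        q = pose[cname]
        R = R @ RigidTransform.from_axis_angle(c.axis, q)
    return R


def forward_kinematics(model: SkeletalModel, pose: Pose) -> WorldTransforms:
    """World transform of every segment frame at one pose.

    Child placement: X_child = X_parent ∘ T(loc_in_parent) ∘ R(q) ∘
    T(-loc_in_child) ∘ fixed_offset.  The traversal is order-independent
    because the model is a tree.
    """
    for j in model.joints:
        for c in j.coordinates:
            if c.name not in pose:
                raise KeyError(f"pose is missing coordinate '{c.name}'")

    smap = model.segment_map()
    jmap = model.joint_map()
    out: WorldTransforms = {}

    def resolve(seg_name: str) -> RigidTransform:
        if seg_name in out:
            return out[seg_name]
        seg = smap[seg_name]
        if seg.parent_joint is None:
            X = seg.fixed_offset
        else:
            j = jmap[seg.parent_joint]
            Xp = resolve(j.parent_segment)
            X = (
                Xp
                @ RigidTransform.from_translation(j.location_in_parent)
                @ joint_rotation(j, pose)
                @ RigidTransform.from_translation(-j.location_in_child)
                @ seg.fixed_offset
            )
        out[seg_name] = X
        return X

    for s in model.segments:
        resolve(s.name)
    return out


@dataclass
class RoutedPath:
    """A routed MTU line of action at one pose: world polyline and length."""

    mtu: str
    vertices: List[np.ndarray] = field(default_factory=list)
    wrap_active: List[bool] = field(default_factory=list)
    length: float = 0.0


def _wrap_segment(
    p1: np.ndarray,
    p2: np.ndarray,
    wrap: WrapCylinder,
    cyl_world: RigidTransform,
    mtu: str,
):
    """Route one straight sub-segment past one cylinder.

    Returns (length, world polyline [excluding p1], active flag).
    Everything happens in the cylinder's local frame where the axis is +Z.
    """
    inv = cyl_world.inverse()
    a = inv.apply(p1)
    b = inv.apply(p2)
    r = wrap.radius
    a2, b2 = a[:2], b[:2]
    d1, d2 = np.linalg.norm(a2), np.linalg.norm(b2)
    if d1 <= r or d2 <= r:
        raise PathRoutingError(
            f"MTU '{mtu}': path point lies inside wrap cylinder "
            f"(radial distances {d1:.4f}, {d2:.4f} vs radius {r:.4f})"
        )

    # distance from cylinder axis to the projected chord (closed segment)
    ab = b2 - a2
    denom = float(ab @ ab)
    tproj = 0.0 if denom == 0.0 else float(np.clip(-(a2 @ ab) / denom, 0.0, 1.0))
    closest = a2 + tproj * ab
    if np.linalg.norm(closest) >= r:
        # chord clears the surface: keep the straight line
        return float(np.linalg.norm(p2 - p1)), [p2], False

    s = +1.0 if wrap.wrap_side == "+" else -1.0
    alpha1 = math.atan2(a2[1], a2[0])
    alpha2 = math.atan2(b2[1], b2[0])
    beta1 = math.acos(r / d1)
    beta2 = math.acos(r / d2)
    theta1 = alpha1 + s * beta1
    theta2 = alpha2 - s * beta2
    delta = (s * (theta2 - theta1)) % (2.0 * math.pi)

    l1 = math.sqrt(d1 * d1 - r * r)
    l2 = math.sqrt(d2 * d2 - r * r)
    arc = r * delta
    planar = l1 + arc + l2
    dz = b[2] - a[2]
    length = math.hypot(planar, dz)

    # z of the tangent points: uniform slope along the unrolled path
    z_t1 = a[2] + dz * l1 / planar
    z_t2 = a[2] + dz * (l1 + arc) / planar
    half = wrap.length / 2.0
    for z_t, tag in ((z_t1, "entry"), (z_t2, "exit")):
        if abs(z_t) > half:
            raise PathRoutingError(
                f"MTU '{mtu}': {tag} tangent point at z={z_t:.4f} falls outside the "
                f"wrap cylinder's valid extent ±{half:.4f}"
            )

    verts_local = []
    for k in range(ARC_SAMPLES + 1):
        f = k / ARC_SAMPLES
        th = theta1 + s * delta * f
        z = z_t1 + (z_t2 - z_t1) * f
        verts_local.append(np.array([r * math.cos(th), r * math.sin(th), z]))
    verts = [cyl_world.apply(v) for v in verts_local] + [p2]
    return length, verts, True


def route_path(
    model: SkeletalModel,
    transforms: WorldTransforms,
    path: MusclePathDef,
    mtu: str = "?",
) -> RoutedPath:
    """Route one MTU line through its via points and wrap objects at one pose."""
    pts = [transforms[p.segment].apply(p.local_position) for p in path.points]
    wrap_by_pair = {w.applies_between[0]: w for w in path.wraps}

    routed = RoutedPath(mtu=mtu, vertices=[pts[0]])
    total = 0.0
    for i in range(len(pts) - 1):
        p1, p2 = pts[i], pts[i + 1]
        wrap = wrap_by_pair.get(i)
        if wrap is None:
            total += float(np.linalg.norm(p2 - p1))
            routed.vertices.append(p2)
            routed.wrap_active.append(False)
        else:
            cyl_world = transforms[wrap.segment] @ wrap.pose_in_segment
            seg_len, verts, active = _wrap_segment(p1, p2, wrap, cyl_world, mtu)
            total += seg_len
            routed.vertices.extend(verts)
            routed.wrap_active.append(active)
    routed.length = total
    return routed


def path_length(
    model: SkeletalModel,
    pose: Pose,
    path: MusclePathDef,
    mtu: str = "?",
    transforms: WorldTransforms | None = None,
) -> float:
    """MTU length at a pose: forward kinematics followed by path routing."""
    if transforms is None:
        transforms = forward_kinematics(model, pose)
    return route_path(model, transforms, path, mtu=mtu).length
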