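"""Model file I/O: the package's YAML/JSON schema and a read-only importer
for a minimal subset of the OpenSim ``.osim`` XML dialect.

The native schema (``schema_version: 1``) stores the segment tree, joints
with their rotational coordinates, muscle roster and path geometry.
Angles are degrees in files and radians in memory; positions are metres.
Serialisation is canonical — fixed key order, floats rounded to 12
significant digits — so serialize → parse → serialize is byte-identical.

The ``.osim`` importer understands Bodies, CustomJoint rotational
transform axes, PathPoint and WrapCylinder elements; anything else is
recorded as a warning, never silently dropped.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Any, Dict, List, Tuple
from xml.etree import ElementTree

import numpy as np
import yaml
from scipy.spatial.transform import Rotation

from .model import (
    Coordinate,
    Joint,
    MusclePathDef,
    MuscleSpec,
    PathPoint,
    Segment,
    SkeletalModel,
    WrapCylinder,
)
from .transforms import RigidTransform

SCHEMA_VERSION = 1

_DEG = 180.0 / math.pi
_RAD = math.pi / 180.0


class ModelSchemaError(ValueError):
    """A model file violates the schema; the message names the offending key."""


def _r12(x: float) -> float:
    """Round to 12 significant digits so float text round-trips stably."""
    return float(f"{float(x):.12g}")


def _vec(v) -> List[float]:
    return [_r12(x) for x in np.asarray(v, dtype=float)]


def _transform_to_dict(tf: RigidTransform) -> Dict[str, Any]:
    euler = Rotation.from_matrix(tf.R).as_euler("xyz", degrees=True)
    return {"rotation_xyz_deg": _vec(euler), "translation": _vec(tf.t)}


def _transform_from_dict(d: Dict[str, Any], ctx: str) -> RigidTransform:
    try:
        R = Rotation.from_euler("xyz", d["rotation_xyz_deg"], degrees=True).as_matrix()
        return RigidTransform(R, np.asarray(d["translation"], dtype=float))
    except (KeyError, TypeError, ValueError) as e:
        raise ModelSchemaError(f"{ctx}: bad rigid transform ({e})") from e


def model_to_dict(model: SkeletalModel) -> Dict[str, Any]:
    """Canonical dictionary form of a model (the YAML document)."""
    return {
        "schema_version": SCHEMA_VERSION,
        "name": model.name,
        "segments": [
            {
                "name": s.name,
                "parent_joint": s.parent_joint,
                "fixed_offset": _transform_to_dict(s.fixed_offset),
            }
            for s in model.segments
        ],
        "joints": [
            {
                "name": j.name,
                "parent_segment": j.parent_segment,
                "child_segment": j.child_segment,
                "location_in_parent": _vec(j.location_in_parent),
                "location_in_child": _vec(j.location_in_child),
                "rotation_order": list(j.rotation_order),
                "coordinates": [
                    {
                        "name": c.name,
                        "axis_role": c.axis_role,
                        "axis": _vec(c.axis),
                        "range_deg": _vec([c.range[0] * _DEG, c.range[1] * _DEG]),
                        "sign_convention": c.sign_convention,
                    }
                    for c in j.coordinates
                ],
            }
            for j in model.joints
        ],
        "muscles": [
            {
                "code": m.code,
                "name": m.name,
                "group": m.group,
                "n_lines": m.n_lines,
                "take_off_relevant": m.take_off_relevant,
                "origin_inference": m.origin_inference,
                "insertion_inference": m.insertion_inference,
                "origin_description": m.origin_description,
                "insertion_description": m.insertion_description,
                "lines": [
                    {
                        "points": [
                            {
                                "segment": p.segment,
                                "position": _vec(p.local_position),
                                "kind": p.kind,
                            }
                            for p in line.points
                        ],
                        "wraps": [
                            {
                                "segment": w.segment,
                                "pose_in_segment": _transform_to_dict(w.pose_in_segment),
                                "radius": _r12(w.radius),
                                "length": _r12(w.length),
                                "wrap_side": w.wrap_side,
                                "applies_between": list(w.applies_between),
                            }
                            for w in line.wraps
                        ],
                    }
                    for line in m.lines
                ],
            }
            for m in model.muscles
        ],
        "analysis_coordinates": list(model.analysis_coordinates),
    }


def model_from_dict(doc: Dict[str, Any]) -> SkeletalModel:
    if not isinstance(doc, dict) or "schema_version" not in doc:
        raise ModelSchemaError("missing required key 'schema_version'")
    if doc["schema_version"] != SCHEMA_VERSION:
        raise ModelSchemaError(
            f"unsupported schema_version {doc['schema_version']} (expected {SCHEMA_VERSION})"
        )
    try:
        segments = [
            Segment(
                name=s["name"],
                parent_joint=s.get("parent_joint"),
                fixed_offset=_transform_from_dict(
                    s.get("fixed_offset", _transform_to_dict(RigidTransform.identity())),
                    f"segment '{s.get('name')}'",
                ),
            )
            for s in doc["segments"]
        ]
        joints = []
        for j in doc["joints"]:
            coords = [
                Coordinate(
                    name=c["name"],
                    joint=j["name"],
                    axis_role=c["axis_role"],
                    axis=np.asarray(c["axis"], dtype=float),
                    range=(c["range_deg"][0] * _RAD, c["range_deg"][1] * _RAD),
                    sign_convention=c.get("sign_convention", ""),
                )
                for c in j["coordinates"]
            ]
            joints.append(
                Joint(
                    name=j["name"],
                    parent_segment=j["parent_segment"],
                    child_segment=j["child_segment"],
                    location_in_parent=np.asarray(j["location_in_parent"], dtype=float),
                    location_in_child=np.asarray(j["location_in_child"], dtype=float),
                    rotation_order=list(j["rotation_order"]),
                    coordinates=coords,
                )
            )
        muscles = []
        for m in doc["muscles"]:
            lines = [
                MusclePathDef(
                    points=[
                        PathPoint(p["segment"], np.asarray(p["position"], dtype=float), p["kind"])
                        for p in line["points"]
                    ],
                    wraps=[
                        WrapCylinder(
                            segment=w["segment"],
                            pose_in_segment=_transform_from_dict(
                                w["pose_in_segment"], f"muscle '{m.get('code')}' wrap"
                            ),
                            radius=float(w["radius"]),
                            length=float(w["length"]),
                            wrap_side=w["wrap_side"],
                            applies_between=tuple(w["applies_between"]),
                        )
                        for w in line.get("wraps", [])
                    ],
                )
                for line in m.get("lines", [])
            ]
            muscles.append(
                MuscleSpec(
                    code=m["code"],
                    name=m["name"],
                    group=m["group"],
                    n_lines=int(m["n_lines"]),
                    take_off_relevant=bool(m["take_off_relevant"]),
                    origin_inference=m["origin_inference"],
                    insertion_inference=m["insertion_inference"],
                    lines=lines,
                    origin_description=m.get("origin_description", ""),
                    insertion_description=m.get("insertion_description", ""),
                )
            )
    except (KeyError, TypeError) as e:
        raise ModelSchemaError(f"malformed model document: missing key {e}") from e
    return SkeletalModel(
        segments=segments,
        joints=joints,
        muscles=muscles,
        analysis_coordinates=list(doc.get("analysis_coordinates", [])),
        name=doc.get("name", "model"),
    )


def serialize_model(model: SkeletalModel) -> str:
    return yaml.safe_dump(model_to_dict(model), sort_keys=False, default_flow_style=None)


def write_model(model: SkeletalModel, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(serialize_model(model))
    return path


def read_model(path: str | Path) -> SkeletalModel:
    path = Path(path)
    if path.suffix.lower() == ".osim":
        model, warnings = read_osim(path)
        return model
    doc = yaml.safe_load(path.read_text())
    return model_from_dict(doc)


# ---------------------------------------------------------------------------
# Minimal .osim subset importer (read-only)
# ---------------------------------------------------------------------------

_ROLE_FROM_AXIS = {
    (1.0, 0.0, 0.0): "long_axis_rotation",
    (0.0, 1.0, 0.0): "flexion_extension",
    (0.0, 0.0, 1.0): "abduction_adduction",
}


def _floats(text: str) -> List[float]:
    return [float(x) for x in text.split()]


def read_osim(path: str | Path) -> Tuple[SkeletalModel, List[str]]:
    """Import the supported subset of an OpenSim model file.

    Supported: Body, CustomJoint (rotational TransformAxis entries with a
    coordinate each), PathPoint, WrapCylinder.  Every unsupported element
    encountered is recorded in the returned warning list.
    """
    warnings: List[str] = []
    tree = ElementTree.parse(str(path))
    root = tree.getroot()
    mroot = root.find("Model")
    if mroot is None:
        raise ModelSchemaError(f"{path}: no <Model> element")

    segments = [Segment("ground")]
    for body in mroot.iter("Body"):
        segments.append(Segment(body.get("name", "body"), parent_joint=None))

    joints: List[Joint] = []
    seg_parent: Dict[str, str] = {}
    for cj in mroot.iter("CustomJoint"):
        jname = cj.get("name", "joint")
        parent = (cj.findtext("socket_parent_frame") or "ground").split("/")[-1]
        child = (cj.findtext("socket_child_frame") or "").split("/")[-1]
        loc_p = _floats(cj.findtext("location_in_parent") or "0 0 0")
        loc_c = _floats(cj.findtext("location_in_child") or "0 0 0")
        coords: List[Coordinate] = []
        order: List[str] = []
        for ta in cj.iter("TransformAxis"):
            axis = _floats(ta.findtext("axis") or "0 0 1")
            cname = (ta.findtext("coordinates") or "").strip()
            if not cname:
                # translational or locked axis: outside the rotational subset
                if ta.get("name", "").startswith("translation"):
                    continue
                warnings.append(f"{jname}: TransformAxis without coordinate skipped")
                continue
            if ta.get("name", "").startswith("translation"):
                warnings.append(f"{jname}: translational coordinate '{cname}' skipped")
                continue
            role = _ROLE_FROM_AXIS.get(tuple(axis), "flexion_extension")
            coords.append(
                Coordinate(name=cname, joint=jname, axis_role=role, axis=np.asarray(axis))
            )
            order.append(cname)
        if not coords:
            warnings.append(f"CustomJoint '{jname}' has no rotational coordinates; skipped")
            continue
        joints.append(
            Joint(
                name=jname,
                parent_segment=parent,
                child_segment=child,
                location_in_parent=np.asarray(loc_p),
                location_in_child=np.asarray(loc_c),
                rotation_order=order,
                coordinates=coords,
            )
        )
        seg_parent[child] = jname

    for tag in ("PinJoint", "BallJoint", "WeldJoint", "FreeJoint", "EllipsoidJoint"):
        for el in mroot.iter(tag):
            warnings.append(f"unsupported joint type {tag} '{el.get('name')}' skipped")

    for s in segments:
        s.parent_joint = seg_parent.get(s.name)

    wrap_objects: Dict[str, WrapCylinder] = {}
    for body in mroot.iter("Body"):
        bname = body.get("name", "body")
        for wc in body.iter("WrapCylinder"):
            xyz = _floats(wc.findtext("xyz_body_rotation") or "0 0 0")
            trans = _floats(wc.findtext("translation") or "0 0 0")
            quadrant = (wc.findtext("quadrant") or "+x").strip()
            side = "-" if quadrant.startswith("-") else "+"
            warnings.append(
                f"WrapCylinder '{wc.get('name')}': quadrant '{quadrant}' mapped to "
                f"travel side '{side}' (approximate semantics)"
            )
            R = Rotation.from_euler("xyz", xyz, degrees=False).as_matrix()
            wrap_objects[wc.get("name", "wrap")] = WrapCylinder(
                segment=bname,
                pose_in_segment=RigidTransform(R, np.asarray(trans)),
                radius=float(wc.findtext("radius") or 0.0),
                length=float(wc.findtext("length") or 0.0),
                wrap_side=side,
                applies_between=(0, 1),
            )
        for tag in ("WrapEllipsoid", "WrapSphere", "WrapTorus"):
            for el in body.iter(tag):
                warnings.append(f"unsupported wrap type {tag} '{el.get('name')}' skipped")

    muscles: List[MuscleSpec] = []
    for mu in mroot.iter("Thelen2003Muscle"):
        code = mu.get("name", "muscle")
        pts: List[PathPoint] = []
        for pp in mu.iter("PathPoint"):
            seg = (pp.findtext("socket_parent_frame") or pp.findtext("body") or "").split("/")[-1]
            loc = _floats(pp.findtext("location") or "0 0 0")
            pts.append(PathPoint(seg, np.asarray(loc)))
        for tag in ("ConditionalPathPoint", "MovingPathPoint"):
            for el in mu.iter(tag):
                warnings.append(f"muscle '{code}': unsupported {tag} skipped")
        if len(pts) < 2:
            warnings.append(f"muscle '{code}' has fewer than 2 supported path points; skipped")
            continue
        pts[0].kind = "origin"
        pts[-1].kind = "insertion"
        wraps: List[WrapCylinder] = []
        for pw in mu.iter("PathWrap"):
            wname = (pw.findtext("wrap_object") or "").strip()
            if wname in wrap_objects:
                w = wrap_objects[wname]
                wraps.append(
                    WrapCylinder(
                        segment=w.segment,
                        pose_in_segment=w.pose_in_segment,
                        radius=w.radius,
                        length=w.length,
                        wrap_side=w.wrap_side,
                        applies_between=(0, 1),
                    )
                )
            else:
                warnings.append(f"muscle '{code}': unknown wrap object '{wname}'")
        muscles.append(
            MuscleSpec(
                code=code,
                name=code,
                group="pectoral",
                n_lines=1,
                take_off_relevant=True,
                origin_inference="I",
                insertion_inference="I",
                lines=[MusclePathDef(points=pts, wraps=wraps)],
                origin_description="[imported from .osim]",
                insertion_description="[imported from .osim]",
            )
        )

    coord_names = [c.name for j in joints for c in j.coordinates]
    model = SkeletalModel(
        segments=segments,
        joints=joints,
        muscles=muscles,
        analysis_coordinates=coord_names,
        name=mroot.get("name", Path(path).stem),
    )
    return model, warnings
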