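"""Forward kinematics and path routing, checked against closed forms and a
brute-force shortest-path-around-a-circle oracle."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pterolaunch.geometry import (
    PathRoutingError,
    forward_kinematics,
    path_length,
    route_path,
)
from pterolaunch.model import (
    Coordinate,
    Joint,
    MusclePathDef,
    PathPoint,
    Segment,
    SkeletalModel,
    WrapCylinder,
    complete_pose,
)
from pterolaunch.synthetic import make_hinge_toy
from pterolaunch.transforms import RigidTransform


def brute_force_wrap_length(a, b, r, n=2000):
    """Shortest planar path from a to b around a circle of radius r at the
    origin: min over entry/exit circle samples of line + arc + line, with
    line segments constrained to stay outside the circle."""
    a = np.asarray(a[:2], dtype=float)
    b = np.asarray(b[:2], dtype=float)
    theta = np.linspace(0, 2 * math.pi, n, endpoint=False)
    pts = r * np.stack([np.cos(theta), np.sin(theta)], axis=1)

    def seg_ok(p, q):
        # distance from origin to segment p-q >= r (within tolerance)
        d = q - p
        t = np.clip(-(p @ d) / (d @ d), 0.0, 1.0)
        return np.linalg.norm(p + t * d) >= r * (1 - 1e-9)

    la = np.linalg.norm(pts - a, axis=1)
    lb = np.linalg.norm(pts - b, axis=1)
    ok_a = np.array([seg_ok(a, p) for p in pts])
    ok_b = np.array([seg_ok(b, p) for p in pts])
    dth = np.abs(theta[:, None] - theta[None, :])
    arc = r * np.minimum(dth, 2 * math.pi - dth)
    total = la[:, None] + arc + lb[None, :]
    total[~ok_a, :] = np.inf
    total[:, ~ok_b] = np.inf
    return float(total.min())


def single_wrap_model(radius, side="+", za=0.0, zb=0.0, ax=-1.0, bx=1.0, ay=0.0, by=0.0):
    model, _ = make_hinge_toy()
    wrap = WrapCylinder(
        "base", RigidTransform.identity(), radius, 10.0, side, (0, 1)
    )
    path = MusclePathDef(
        points=[
            PathPoint("base", (ax, ay, za), kind="origin"),
            PathPoint("base", (bx, by, zb), kind="insertion"),
        ],
        wraps=[wrap],
    )
    return model, path


class TestForwardKinematics:
    def test_zero_pose_composes_fixed_offsets_only(self, quadruped):
        model, _ = quadruped
        tf = forward_kinematics(model, complete_pose(model))
        trunk = tf["trunk"]
        assert np.allclose(trunk.R, np.eye(3)) and np.allclose(trunk.t, 0)
        # humerus frame sits at the shoulder location, unrotated
        assert np.allclose(tf["humerus"].t, [0.0, 0.0, 0.15])
        assert np.allclose(tf["humerus"].R, np.eye(3))

    def test_quarter_turn_maps_x_axis_to_y(self, hinge):
        model, _ = hinge
        tf = forward_kinematics(model, {"hinge_add": math.pi / 2})
        assert np.allclose(tf["arm"].R @ [1, 0, 0], [0, 1, 0], atol=1e-12)

    def test_stacked_hinges_compose_rotations(self):
        coords = [
            Coordinate(f"q{i}", f"j{i}", "abduction_adduction", np.array([0.0, 0.0, 1.0]))
            for i in (1, 2)
        ]
        model = SkeletalModel(
            segments=[Segment("s0"), Segment("s1", "j1"), Segment("s2", "j2")],
            joints=[
                Joint("j1", "s0", "s1", np.zeros(3), np.zeros(3), ["q1"], [coords[0]]),
                Joint("j2", "s1", "s2", np.zeros(3), np.zeros(3), ["q2"], [coords[1]]),
            ],
            muscles=[],
        )
        tf = forward_kinematics(model, {"q1": math.pi / 4, "q2": math.pi / 4})
        expected = RigidTransform.from_axis_angle([0, 0, 1], math.pi / 2).R
        assert np.allclose(tf["s2"].R, expected, atol=1e-12)

    def test_rotations_stay_orthonormal_at_random_poses(self, quadruped, rng):
        model, _ = quadruped
        names = list(model.coordinate_map())
        for _ in range(20):
            pose = {n: rng.uniform(-2.5, 2.5) for n in names}
            for X in forward_kinematics(model, pose).values():
                assert np.linalg.norm(X.R.T @ X.R - np.eye(3)) < 1e-9

    def test_missing_coordinate_raises(self, hinge):
        model, _ = hinge
        with pytest.raises(KeyError):
            forward_kinematics(model, {})


class TestRoutePath:
    def test_straight_chord_length(self, hinge):
        model, _ = hinge
        tf = forward_kinematics(model, {"hinge_add": 0.0})
        routed = route_path(model, tf, model.muscles[0].lines[0], mtu="HM")
        assert routed.length == pytest.approx(2.0)
        assert routed.wrap_active == [False]

    def test_grazing_tangency_keeps_chord(self, hinge):
        model, path = single_wrap_model(0.05, ay=0.05, by=0.05)
        tf = forward_kinematics(model, {"hinge_add": 0.0})
        routed = route_path(model, tf, path, mtu="X")
        assert routed.length == pytest.approx(2.0, abs=1e-12)
        assert routed.wrap_active == [False]

    @pytest.mark.parametrize("side", ["+", "-"])
    def test_planar_wrap_matches_closed_form_and_brute_force(self, side):
        # symmetric chord through the cylinder centre: both sides equal
        r = 0.5
        model, path = single_wrap_model(r, side=side)
        tf = forward_kinematics(model, {"hinge_add": 0.0})
        routed = route_path(model, tf, path, mtu="X")
        closed = 2 * math.sqrt(1 - r * r) + r * (math.pi - 2 * math.acos(r))
        assert routed.wrap_active == [True]
        assert routed.length == pytest.approx(closed, rel=1e-12)
        brute = brute_force_wrap_length((-1, 0), (1, 0), r)
        assert routed.length == pytest.approx(brute, rel=1e-4)

    def test_asymmetric_wrap_matches_brute_force(self):
        r = 0.3
        model, path = single_wrap_model(r, side="+", ay=-0.1, by=0.05, ax=-1.2, bx=0.9)
        tf = forward_kinematics(model, {"hinge_add": 0.0})
        routed = route_path(model, tf, path, mtu="X")
        brute = brute_force_wrap_length((-1.2, -0.1), (0.9, 0.05), r)
        assert routed.wrap_active == [True]
        assert routed.length == pytest.approx(brute, rel=1e-4)

    def test_out_of_plane_wrap_reduces_to_unrolled_hypotenuse(self):
        r = 0.5
        model, path_flat = single_wrap_model(r)
        model, path_skew = single_wrap_model(r, za=0.0, zb=0.4)
        tf = forward_kinematics(model, {"hinge_add": 0.0})
        flat = route_path(model, tf, path_flat, mtu="X").length
        skew = route_path(model, tf, path_skew, mtu="X").length
        assert skew == pytest.approx(math.hypot(flat, 0.4), rel=1e-12)

    def test_wrap_length_tends_to_chord_as_radius_shrinks(self):
        lengths = []
        for r in (0.4, 0.2, 0.1, 0.05, 0.01, 0.001):
            model, path = single_wrap_model(r, ay=-1e-6, by=1e-6)
            tf = forward_kinematics(model, {"hinge_add": 0.0})
            lengths.append(route_path(model, tf, path, mtu="X").length)
        assert all(a >= b - 1e-12 for a, b in zip(lengths, lengths[1:]))
        assert lengths[-1] == pytest.approx(2.0, abs=1e-3)

    def test_attachment_inside_cylinder_raises_with_mtu_name(self):
        model, path = single_wrap_model(0.5, ax=-0.2, ay=0.0)
        tf = forward_kinematics(model, {"hinge_add": 0.0})
        with pytest.raises(PathRoutingError, match="NAMED"):
            route_path(model, tf, path, mtu="NAMED")

    def test_length_bounded_below_by_endpoint_distance(self, quadruped, rng):
        model, _ = quadruped
        cmap = model.coordinate_map()
        for _ in range(5):
            pose = {n: rng.uniform(max(c.range[0], -1.5), min(c.range[1], 1.5))
                    for n, c in cmap.items()}
            tf = forward_kinematics(model, pose)
            for code, i, line in model.iter_mtus():
                routed = route_path(model, tf, line, mtu=code)
                chord = np.linalg.norm(routed.vertices[-1] - routed.vertices[0])
                assert routed.length >= chord - 1e-12


class TestPathLengthInvariance:
    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(
        angle=st.floats(-3.0, 3.0),
        tx=st.floats(-5.0, 5.0),
        q=st.floats(-2.5, 2.5),
    )
    def test_rigid_world_shift_leaves_length_unchanged(self, angle, tx, q):
        """Moving the whole model rigidly cannot change any muscle length."""
        model, _ = make_hinge_toy()
        pose = {"hinge_add": q}
        L0 = path_length(model, pose, model.muscles[0].lines[0])
        shift = RigidTransform.from_axis_angle([0.3, 0.5, 0.8], angle) @ (
            RigidTransform.from_translation([tx, 1.0, -2.0])
        )
        model.segments[0].fixed_offset = shift
        L1 = path_length(model, pose, model.muscles[0].lines[0])
        assert L1 == pytest.approx(L0, rel=1e-12, abs=1e-12)
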