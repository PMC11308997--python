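"""Virtual-work moment arms versus closed forms and the perpendicular-
distance oracle; finite-difference robustness properties."""

import math

import numpy as np
import pytest

from pterolaunch.model import complete_pose
from pterolaunch.momentarm import (
    hinge_moment_arm_oracle,
    moment_arm,
    mtu_spans_coordinate,
    trace_sequence,
)
from pterolaunch.geometry import path_length
from pterolaunch.kinematics import KeyPose, KinematicSequence
from pterolaunch.synthetic import make_hinge_toy, make_pulley_toy


def _hinge_path(model):
    return model.muscles[0].lines[0]


class TestMomentArmClosedForms:
    def test_line_through_joint_centre_has_zero_leverage(self, hinge):
        model, _ = hinge
        ma = moment_arm(model, {"hinge_add": 0.0}, _hinge_path(model), "hinge_add")
        assert ma == pytest.approx(0.0, abs=1e-9)

    def test_quarter_turn_matches_sin_half_q(self, hinge):
        model, analytic = hinge
        q = math.pi / 2
        ma = moment_arm(model, {"hinge_add": q}, _hinge_path(model), "hinge_add")
        assert ma == pytest.approx(math.sin(q / 2), abs=1e-8)
        assert analytic(q) == pytest.approx(math.sin(q / 2), abs=1e-15)

    def test_fd_tracks_analytic_form_across_poses(self, hinge, rng):
        model, analytic = hinge
        for q in rng.uniform(-2.8, 2.8, size=50):
            ma = moment_arm(model, {"hinge_add": float(q)}, _hinge_path(model), "hinge_add")
            assert ma == pytest.approx(analytic(q), abs=1e-7)

    def test_step_must_be_positive(self, hinge):
        model, _ = hinge
        with pytest.raises(ValueError):
            moment_arm(model, {"hinge_add": 0.3}, _hinge_path(model), "hinge_add", step=0.0)


class TestHingeOracle:
    def test_oracle_agrees_with_fd_on_random_poses(self, hinge, rng):
        model, _ = hinge
        path = _hinge_path(model)
        for q in rng.uniform(-2.9, 2.9, size=100):
            pose = {"hinge_add": float(q)}
            fd = moment_arm(model, pose, path, "hinge_add")
            oracle = hinge_moment_arm_oracle(model, pose, path, "hinge_add")
            assert abs(fd - oracle) < 1e-6

    def test_offset_parallel_muscle_gives_perpendicular_distance(self):
        # muscle running parallel to x at y = 0.1: lever about z is 0.1
        model, _ = make_hinge_toy(a=(-1.0, 0.1, 0.0), b=(1.0, 0.1, 0.0))
        path = model.muscles[0].lines[0]
        pose = {"hinge_add": 0.0}
        oracle = hinge_moment_arm_oracle(model, pose, path, "hinge_add")
        assert abs(oracle) == pytest.approx(0.1, abs=1e-12)
        fd = moment_arm(model, pose, path, "hinge_add")
        assert fd == pytest.approx(oracle, abs=1e-7)

    def test_line_intersecting_axis_scores_zero(self, hinge):
        model, _ = hinge
        v = hinge_moment_arm_oracle(
            model, {"hinge_add": 0.0}, _hinge_path(model), "hinge_add"
        )
        assert v == pytest.approx(0.0, abs=1e-12)

    def test_oracle_rejects_wrapped_paths(self, pulley):
        model, _ = pulley
        with pytest.raises(ValueError):
            hinge_moment_arm_oracle(
                model, {"hinge_add": 0.0}, model.muscles[0].lines[0], "hinge_add"
            )


class TestPulleyTheorem:
    @pytest.mark.parametrize("radius", [0.05, 0.5])
    def test_wrapped_arm_equals_cylinder_radius(self, radius):
        model, (q_lo, q_hi) = make_pulley_toy(radius=radius)
        path = model.muscles[0].lines[0]
        margin = 0.05 * (q_hi - q_lo)
        for q in np.linspace(q_lo + margin, q_hi - margin, 9):
            ma = moment_arm(model, {"hinge_add": float(q)}, path, "hinge_add")
            assert abs(ma) == pytest.approx(radius, rel=1e-4)

    def test_out_of_contact_reverts_to_straight_line_value(self, pulley):
        model, (q_lo, q_hi) = pulley
        path = model.muscles[0].lines[0]
        q = q_hi + 0.5  # far outside the contact interval
        fd = moment_arm(model, {"hinge_add": q}, path, "hinge_add")
        # same attachments without the (inactive) wrap: the analytic
        # straight-line hinge form must take over
        a = path.points[0].local_position
        b = path.points[1].local_position
        _, analytic = make_hinge_toy(a=tuple(a), b=tuple(b))
        assert fd == pytest.approx(analytic(q), abs=1e-6)


class TestFiniteDifferenceProperties:
    def test_work_consistency(self, hinge):
        """dL/dq == -MA to second order in the step."""
        model, _ = hinge
        path = _hinge_path(model)
        q, delta = 0.9, 1e-5
        ma = moment_arm(model, {"hinge_add": q}, path, "hinge_add")
        dL = path_length(model, {"hinge_add": q + delta}, path) - path_length(
            model, {"hinge_add": q}, path
        )
        assert dL == pytest.approx(-ma * delta, abs=1e-10)

    def test_step_robustness(self, hinge):
        model, _ = hinge
        path = _hinge_path(model)
        vals = [
            moment_arm(model, {"hinge_add": 0.7}, path, "hinge_add", step=s)
            for s in (1e-3, 1e-4, 1e-5)
        ]
        assert max(vals) - min(vals) < 1e-6

    def test_unspanned_coordinate_has_zero_arm(self, quadruped):
        model, _ = quadruped
        pose = complete_pose(model)
        # a pelvic muscle cannot act about the elbow
        add = model.muscle_map()["ADD"].lines[0]
        assert not mtu_spans_coordinate(model, add, "elbow_ext")
        ma = moment_arm(model, pose, add, "elbow_ext")
        assert abs(ma) < 1e-9


class TestTraceSequence:
    def _constant_sequence(self, model, q=0.4):
        pose = complete_pose(model, {"hinge_add": q})
        return KinematicSequence(
            style="bipedal_burst",
            key_poses=[KeyPose(pose, 0.0), KeyPose(pose, 1.0)],
            phases=[("crouch", 0.0, 0.4), ("ankle_lifted", 0.4, 0.7), ("launch", 0.7, 1.0)],
        )

    def test_constant_pose_yields_constant_trace(self, hinge):
        model, _ = hinge
        seq = self._constant_sequence(model)
        traces = trace_sequence(model, seq, coordinates=["hinge_add"], n_frames=7)
        assert len(traces) == 1
        assert np.ptp(traces[0].values) < 1e-12

    def test_linear_ramp_matches_closed_form(self, hinge):
        model, _ = hinge
        p0 = complete_pose(model, {"hinge_add": 0.0})
        p1 = complete_pose(model, {"hinge_add": math.pi / 2})
        seq = KinematicSequence(
            style="bipedal_burst",
            key_poses=[KeyPose(p0, 0.0), KeyPose(p1, 1.0)],
            phases=[("crouch", 0.0, 0.4), ("ankle_lifted", 0.4, 0.7), ("launch", 0.7, 1.0)],
            interpolation="linear",
        )
        traces = trace_sequence(model, seq, coordinates=["hinge_add"], n_frames=3)
        expected = [0.0, math.sin(math.pi / 8), math.sin(math.pi / 4)]
        assert traces[0].values == pytest.approx(expected, abs=1e-7)

    def test_two_frames_hit_sequence_endpoints(self, hinge):
        model, _ = hinge
        seq = self._constant_sequence(model)
        traces = trace_sequence(model, seq, coordinates=["hinge_add"], n_frames=2)
        assert list(traces[0].times) == [0.0, 1.0]

    def test_every_pair_produced(self, quadruped):
        model, seqs = quadruped
        traces = trace_sequence(model, seqs["quadrupedal"], n_frames=3)
        n_mtus = sum(m.n_lines for m in model.muscles)
        assert len(traces) == n_mtus * len(model.analysis_coordinates)

    def test_n_frames_below_two_rejected(self, hinge):
        model, _ = hinge
        with pytest.raises(ValueError):
            trace_sequence(model, self._constant_sequence(model), n_frames=1)
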