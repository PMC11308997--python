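"""Key-pose interpolation, timing normalisation, phase structure and
launch-applicability rules."""

import numpy as np
import pytest

from pterolaunch.kinematics import (
    KeyPose,
    KinematicSequence,
    build_takeoff_sequence,
    interpolate_pose,
    limb_of_coordinate,
    normalise_timing,
)
from pterolaunch.model import complete_pose
from pterolaunch.motion import read_motion, write_motion
from pterolaunch.synthetic import default_key_poses


def _ramp_sequence(model, q0=0.0, q1=1.0, mode="linear"):
    p0 = complete_pose(model, {"hinge_add": q0})
    p1 = complete_pose(model, {"hinge_add": q1})
    return KinematicSequence(
        style="bipedal_countermotion",
        key_poses=[KeyPose(p0, 0.0), KeyPose(p1, 1.0)],
        phases=[("countermotion", 0.0, 0.55), ("launch", 0.55, 1.0)],
        interpolation=mode,
    )


class TestInterpolation:
    def test_linear_midpoint(self, hinge):
        model, _ = hinge
        seq = _ramp_sequence(model)
        assert interpolate_pose(seq, 0.5)["hinge_add"] == pytest.approx(0.5)

    def test_key_pose_fractions_reproduce_key_poses_exactly(self, quadruped):
        model, seqs = quadruped
        for seq in seqs.values():
            for kp in seq.key_poses:
                assert interpolate_pose(seq, kp.time_fraction) == kp.pose

    def test_pchip_never_overshoots_flanking_key_values(self, quadruped):
        model, seqs = quadruped
        seq = seqs["quadrupedal"]
        fracs = np.array([kp.time_fraction for kp in seq.key_poses])
        for cname in seq.coordinates():
            vals = np.array([kp.pose[cname] for kp in seq.key_poses])
            for t in np.linspace(0, 1, 1000):
                k = np.searchsorted(fracs, t, side="right")
                lo, hi = sorted((vals[max(k - 1, 0)], vals[min(k, len(vals) - 1)]))
                q = seq.pose_at(float(t))[cname]
                assert lo - 1e-12 <= q <= hi + 1e-12

    def test_out_of_range_time_rejected(self, hinge):
        model, _ = hinge
        with pytest.raises(ValueError):
            _ramp_sequence(model).pose_at(1.2)

    def test_interpolated_angles_clamped_to_range_with_warning(self, hinge, caplog):
        model, _ = hinge
        seq = _ramp_sequence(model)
        seq.coordinate_ranges = {"hinge_add": (0.0, 0.25)}
        with caplog.at_level("WARNING"):
            q = seq.pose_at(0.5)["hinge_add"]
        assert q == 0.25
        assert any("clamped" in r.message for r in caplog.records)


class TestNormaliseTiming:
    def test_affine_rescale(self):
        assert normalise_timing([0.0, 0.2, 0.5]) == pytest.approx([0.0, 0.4, 1.0])

    def test_two_point_case(self):
        assert normalise_timing([3.0, 4.0]) == pytest.approx([0.0, 1.0])

    def test_unit_span_for_any_valid_input(self, rng):
        raw = np.cumsum(rng.uniform(0.05, 1.0, size=6)) + 2.0
        out = normalise_timing(raw)
        assert out[0] == 0.0 and out[-1] == 1.0
        # relative spacing preserved
        ratios = np.diff(raw) / (raw[-1] - raw[0])
        assert np.allclose(np.diff(out), ratios)

    def test_non_increasing_times_rejected(self):
        with pytest.raises(ValueError):
            normalise_timing([0.0, 0.5, 0.5])


class TestPhaseStructure:
    def test_style_phase_names(self, quadruped):
        _, seqs = quadruped
        assert [p[0] for p in seqs["quadrupedal"].phases] == ["crouch", "vault", "launch"]
        assert [p[0] for p in seqs["bipedal_countermotion"].phases] == [
            "countermotion", "launch",
        ]
        assert [p[0] for p in seqs["bipedal_burst"].phases] == [
            "crouch", "ankle_lifted", "launch",
        ]

    def test_every_sequence_lasts_one_second_with_gapless_phases(self, quadruped):
        _, seqs = quadruped
        for seq in seqs.values():
            assert seq.duration == 1.0
            spans = sum(b - a for _, a, b in seq.phases)
            assert spans == pytest.approx(1.0, abs=1e-15)
            edges = [seq.phases[0][1]] + [b for _, _, b in seq.phases]
            assert edges[0] == 0.0 and edges[-1] == 1.0

    def test_wrong_phase_set_rejected(self, hinge):
        model, _ = hinge
        p = complete_pose(model)
        with pytest.raises(ValueError, match="phases"):
            KinematicSequence(
                style="quadrupedal",
                key_poses=[KeyPose(p, 0.0), KeyPose(p, 1.0)],
                phases=[("crouch", 0.0, 0.5), ("launch", 0.5, 1.0)],
            )

    def test_gapped_phases_rejected(self, hinge):
        model, _ = hinge
        p = complete_pose(model)
        with pytest.raises(ValueError, match="partition"):
            KinematicSequence(
                style="bipedal_countermotion",
                key_poses=[KeyPose(p, 0.0), KeyPose(p, 1.0)],
                phases=[("countermotion", 0.0, 0.4), ("launch", 0.5, 1.0)],
            )


class TestLaunchApplicability:
    def test_bipedal_hindlimb_applicable_throughout(self, quadruped):
        _, seqs = quadruped
        assert seqs["bipedal_burst"].launch_applicable["knee_ext"] == [(0.0, 1.0)]

    def test_quadrupedal_forelimb_applicable_from_vault_onset(self, quadruped):
        _, seqs = quadruped
        assert seqs["quadrupedal"].launch_applicable["elbow_ext"] == [(0.35, 1.0)]

    def test_bipedal_forelimb_never_applicable(self, quadruped):
        _, seqs = quadruped
        assert seqs["bipedal_burst"].launch_applicable["elbow_ext"] == []

    def test_quadrupedal_hindlimb_applicable_until_liftoff(self, quadruped):
        _, seqs = quadruped
        assert seqs["quadrupedal"].launch_applicable["knee_ext"] == [(0.0, 0.55)]

    def test_limb_mapping_rejects_unknown_joints(self, hinge):
        model, _ = hinge
        with pytest.raises(KeyError):
            limb_of_coordinate(model, "hinge_add")


class TestMotionFiles:
    def test_round_trip_preserves_angles_within_tolerance(self, quadruped, tmp_path):
        model, seqs = quadruped
        seq = seqs["bipedal_burst"]
        path = write_motion(seq, tmp_path / "burst.sto", n_frames=11)
        coords, times, angles = read_motion(path)
        assert coords == seq.coordinates()
        for i, t in enumerate(times):
            pose = seq.pose_at(float(t))
            for j, c in enumerate(coords):
                assert abs(angles[i, j] - pose[c]) < 1e-9

    def test_header_declares_degrees(self, quadruped, tmp_path):
        _, seqs = quadruped
        path = write_motion(seqs["quadrupedal"], tmp_path / "q.sto", n_frames=3)
        head = path.read_text().splitlines()[:6]
        assert any(line.startswith("inDegrees=yes") for line in head)
        assert "endheader" in head


class TestBuildTakeoffSequence:
    def test_wrong_boundary_count_rejected(self, quadruped):
        model, _ = quadruped
        kps = default_key_poses(model, "quadrupedal")
        with pytest.raises(ValueError):
            build_takeoff_sequence(model, "quadrupedal", kps, phase_boundaries=[0.5])

    def test_unknown_style_rejected(self, quadruped):
        model, _ = quadruped
        with pytest.raises(ValueError):
            build_takeoff_sequence(model, "hovering", [], phase_boundaries=[])
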