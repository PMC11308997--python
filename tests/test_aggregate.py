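"""Multi-line averaging, directional summation, mean-across-muscles and
launch-applicability masking."""

import numpy as np
import pytest

from pterolaunch.aggregate import (
    average_muscle_lines,
    add_monte_carlo_bands,
    directional_sum,
    mask_launch_applicable,
    mean_across_muscles,
)
from pterolaunch.momentarm import MomentArmTrace
from pterolaunch.montecarlo import MonteCarloConfig


def _trace(mtu, values, coordinate="knee_ext", times=None):
    values = np.asarray(values, dtype=float)
    if times is None:
        times = np.linspace(0, 1, values.size)
    return MomentArmTrace(mtu=mtu, coordinate=coordinate, times=times, values=values)


class TestAverageMuscleLines:
    def test_mean_of_identical_lines_is_identity(self):
        lines = [_trace(f"PECT.{i}", [0.02, 0.02]) for i in range(4)]
        avg = average_muscle_lines(lines, "PECT")
        assert np.allclose(avg.values, 0.02)

    def test_arithmetic_mean_of_two_lines(self):
        avg = average_muscle_lines([_trace("BI.1", [0.02]), _trace("BI.2", [0.04])], "BI")
        assert avg.values[0] == pytest.approx(0.03)

    def test_single_line_is_identity(self):
        tr = _trace("DS", [0.01, 0.03])
        avg = average_muscle_lines([tr], "DS")
        assert np.array_equal(avg.values, tr.values)

    def test_mismatched_grids_rejected(self):
        a = _trace("X.1", [0.1, 0.2])
        b = _trace("X.2", [0.1, 0.2], times=np.array([0.0, 0.5]))
        with pytest.raises(ValueError):
            average_muscle_lines([a, b], "X")

    def test_mixed_coordinates_rejected(self):
        a = _trace("X.1", [0.1], coordinate="knee_ext")
        b = _trace("X.2", [0.1], coordinate="hip_ext")
        with pytest.raises(ValueError):
            average_muscle_lines([a, b], "X")


class TestDirectionalSum:
    def test_signed_partition(self):
        traces = [_trace("A", [0.02]), _trace("B", [0.03]), _trace("C", [-0.04])]
        s = directional_sum(traces, "knee_ext")
        assert s.positive_sum[0] == pytest.approx(0.05)
        assert s.negative_sum[0] == pytest.approx(0.04)
        assert s.members_positive[0] == ["A", "B"]
        assert s.members_negative[0] == ["C"]

    def test_all_zero_arms_yield_empty_membership(self):
        s = directional_sum([_trace("A", [0.0, 0.0])], "knee_ext")
        assert np.all(s.positive_sum == 0) and np.all(s.negative_sum == 0)
        assert s.members_positive == [[], []] and s.members_negative == [[], []]

    def test_sign_crossing_moves_membership_between_sides(self):
        crossing = _trace("X", np.linspace(0.02, -0.02, 5))
        steady = _trace("Y", np.full(5, 0.01))
        s = directional_sum([crossing, steady], "knee_ext")
        assert s.members_positive[0] == ["X", "Y"]
        assert s.members_negative[0] == []
        assert s.members_positive[-1] == ["Y"]
        assert s.members_negative[-1] == ["X"]
        # brute-force re-summation at every frame
        for i in range(5):
            arms = [crossing.values[i], steady.values[i]]
            assert s.positive_sum[i] == pytest.approx(sum(a for a in arms if a > 0))
            assert s.negative_sum[i] == pytest.approx(-sum(a for a in arms if a < 0))

    def test_conservation_against_brute_force_on_random_frames(self, rng):
        traces = [_trace(f"M{k}", rng.normal(0, 0.05, size=100)) for k in range(7)]
        s = directional_sum(traces, "knee_ext")
        total = s.positive_sum + s.negative_sum
        expected = np.sum([np.abs(tr.values) for tr in traces], axis=0)
        assert np.allclose(total, expected, atol=1e-15)


class TestMeanAcrossMuscles:
    def test_positive_side_mean(self):
        m = mean_across_muscles([_trace("A", [0.02]), _trace("B", [0.04])], "knee_ext")
        assert m.positive_mean[0] == pytest.approx(0.03)
        assert m.positive_count[0] == 2

    def test_single_muscle_is_identity(self):
        m = mean_across_muscles([_trace("A", [0.05, -0.01])], "knee_ext")
        assert m.positive_mean[0] == pytest.approx(0.05)
        assert m.negative_mean[1] == pytest.approx(0.01)

    def test_mean_times_count_equals_directional_sum(self, rng):
        traces = [_trace(f"M{k}", rng.normal(0, 0.05, size=20)) for k in range(5)]
        s = directional_sum(traces, "knee_ext")
        m = mean_across_muscles(traces, "knee_ext")
        assert np.allclose(m.positive_mean * m.positive_count, s.positive_sum)
        assert np.allclose(m.negative_mean * m.negative_count, s.negative_sum)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            mean_across_muscles([], "knee_ext")


class TestMonteCarloBands:
    def test_band_mean_tracks_sum_and_sd_positive(self):
        traces = [_trace("A", [0.1, 0.1]), _trace("B", [-0.05, 0.2])]
        s = directional_sum(traces, "knee_ext")
        cfg = MonteCarloConfig(n_trials=2000, seed=21)
        add_monte_carlo_bands(s, traces, cfg)
        assert np.allclose(s.positive_mean, s.positive_sum, rtol=0.02)
        assert np.all(s.positive_sd >= 0)

    def test_pooled_method_matches_per_trial_for_single_member(self):
        traces = [_trace("A", [0.1])]
        cfg = MonteCarloConfig(n_trials=5000, seed=22)
        s1 = add_monte_carlo_bands(directional_sum(traces, "knee_ext"), traces, cfg)
        s2 = add_monte_carlo_bands(
            directional_sum(traces, "knee_ext"), traces, cfg, method="pooled"
        )
        assert s1.positive_mean[0] == pytest.approx(s2.positive_mean[0], abs=1e-12)
        assert s1.positive_sd[0] == pytest.approx(s2.positive_sd[0], abs=1e-12)

    def test_unknown_method_rejected(self):
        traces = [_trace("A", [0.1])]
        with pytest.raises(ValueError):
            add_monte_carlo_bands(
                directional_sum(traces, "knee_ext"), traces, MonteCarloConfig(), method="x"
            )


class TestMaskLaunchApplicable:
    def test_masking_annotates_without_changing_values(self, quadruped):
        _, seqs = quadruped
        seq = seqs["quadrupedal"]
        traces = [_trace("A", np.linspace(0.01, 0.05, 11), coordinate="elbow_ext")]
        s = directional_sum(traces, "elbow_ext")
        before = s.positive_sum.copy()
        mask_launch_applicable(s, seq)
        assert np.array_equal(s.positive_sum, before)
        # elbow applicable from vault onset (0.35) onward
        assert list(s.applicable) == [t >= 0.35 for t in s.times]

    def test_unknown_coordinate_rejected(self, quadruped):
        _, seqs = quadruped
        s = directional_sum([_trace("A", [0.1], coordinate="tail_ext")], "tail_ext")
        with pytest.raises(KeyError):
            mask_launch_applicable(s, seqs["quadrupedal"])
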