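"""Aggregation of moment-arm traces into the study's summary statistics.

Multi-line muscles are first collapsed to one trace by frame-wise
averaging of their MTU lines.  Per coordinate, muscles are then split by
sign into a positive and a negative functional group (about an
extension-positive Y axis the positive group are the extensors, about an
adduction-positive Z axis the adductors, about a pronation-positive X
axis the internal rotators) and summed per side: the directional sum, the
study's headline leverage statistic.  Membership is re-evaluated every
frame, so a muscle whose arm crosses zero switches sides mid-sequence.

Monte Carlo bands for summed traces are obtained by summing the per-trial
perturbed member arms and summarising the sums, which propagates the
members' independent errors through the sum; a pooled-variance shortcut
(sum of means, root-sum-square of SDs) is available as an alternative.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .kinematics import KinematicSequence, limb_of_coordinate
from .model import SkeletalModel
from .momentarm import MomentArmTrace
from .montecarlo import MonteCarloConfig, perturb_trials, summarise

#: functional-group label per (axis_role, side)
GROUP_LABELS = {
    ("flexion_extension", "positive"): "extensors",
    ("flexion_extension", "negative"): "flexors",
    ("abduction_adduction", "positive"): "adductors",
    ("abduction_adduction", "negative"): "abductors",
    ("long_axis_rotation", "positive"): "internal_rotators",
    ("long_axis_rotation", "negative"): "external_rotators",
}


@dataclass
class DirectionalSummary:
    """Signed-group summed moment arms about one coordinate."""

    coordinate: str
    times: np.ndarray
    positive_sum: np.ndarray  # sum of positive arms (m), >= 0
    negative_sum: np.ndarray  # sum of |negative arms| (m), >= 0
    members_positive: List[List[str]] = field(default_factory=list)
    members_negative: List[List[str]] = field(default_factory=list)
    applicable: Optional[np.ndarray] = None  # bool mask, None until annotated
    positive_mean: Optional[np.ndarray] = None
    positive_sd: Optional[np.ndarray] = None
    negative_mean: Optional[np.ndarray] = None
    negative_sd: Optional[np.ndarray] = None


@dataclass
class MeanAcrossMuscles:
    """Per-side frame-wise mean arm, normalising away muscle count."""

    coordinate: str
    times: np.ndarray
    positive_mean: np.ndarray
    negative_mean: np.ndarray
    positive_count: np.ndarray
    negative_count: np.ndarray


def _check_common_grid(traces: Sequence[MomentArmTrace]) -> np.ndarray:
    if not traces:
        raise ValueError("no traces supplied")
    t0 = traces[0].times
    for tr in traces[1:]:
        if tr.times.shape != t0.shape or not np.array_equal(tr.times, t0):
            raise ValueError("traces do not share a common time grid")
    return t0


def average_muscle_lines(traces: Sequence[MomentArmTrace], muscle_code: str) -> MomentArmTrace:
    """Collapse one muscle's MTU lines to a single frame-wise mean trace."""
    coords = {tr.coordinate for tr in traces}
    if len(coords) != 1:
        raise ValueError(f"cannot average across coordinates {sorted(coords)}")
    times = _check_common_grid(traces)
    values = np.mean([tr.values for tr in traces], axis=0)
    flagged = sorted({f for tr in traces for f in tr.wrap_transition_frames})
    return MomentArmTrace(
        mtu=muscle_code,
        coordinate=coords.pop(),
        times=times.copy(),
        values=values,
        wrap_transition_frames=flagged,
    )


def average_all_muscles(
    traces: Sequence[MomentArmTrace], model: SkeletalModel
) -> Dict[Tuple[str, str], MomentArmTrace]:
    """Per-(muscle, coordinate) averaged traces from raw per-MTU traces."""
    by_key: Dict[Tuple[str, str], List[MomentArmTrace]] = {}
    for tr in traces:
        code = tr.mtu.split(".")[0]
        by_key.setdefault((code, tr.coordinate), []).append(tr)
    out = {}
    for (code, coord), group in by_key.items():
        n_lines = model.muscle_map()[code].n_lines
        if len(group) != n_lines:
            raise ValueError(
                f"muscle '{code}' about '{coord}': expected {n_lines} line traces, "
                f"got {len(group)}"
            )
        out[(code, coord)] = average_muscle_lines(group, code)
    return out


def directional_sum(
    averaged: Sequence[MomentArmTrace], coordinate: str
) -> DirectionalSummary:
    """Frame-wise signed-group sums over muscles for one coordinate.

    Exact zeros contribute to neither side (a measure-zero event under
    finite-difference noise).
    """
    traces = [tr for tr in averaged if tr.coordinate == coordinate]
    if not traces:
        times = np.array([0.0, 1.0])
        n = 2
        return DirectionalSummary(
            coordinate=coordinate,
            times=times,
            positive_sum=np.zeros(n),
            negative_sum=np.zeros(n),
            members_positive=[[] for _ in range(n)],
            members_negative=[[] for _ in range(n)],
        )
    times = _check_common_grid(traces)
    n = times.size
    pos = np.zeros(n)
    neg = np.zeros(n)
    mpos: List[List[str]] = [[] for _ in range(n)]
    mneg: List[List[str]] = [[] for _ in range(n)]
    for tr in traces:
        for i, v in enumerate(tr.values):
            if v > 0:
                pos[i] += v
                mpos[i].append(tr.mtu)
            elif v < 0:
                neg[i] += -v
                mneg[i].append(tr.mtu)
    return DirectionalSummary(
        coordinate=coordinate,
        times=times.copy(),
        positive_sum=pos,
        negative_sum=neg,
        members_positive=mpos,
        members_negative=mneg,
    )


def mean_across_muscles(
    averaged: Sequence[MomentArmTrace], coordinate: str
) -> MeanAcrossMuscles:
    """Per-side frame-wise mean of signed arms (directional sum / count)."""
    traces = [tr for tr in averaged if tr.coordinate == coordinate]
    if not traces:
        raise ValueError(f"no traces for coordinate '{coordinate}'")
    summary = directional_sum(traces, coordinate)
    pcount = np.array([len(m) for m in summary.members_positive], dtype=float)
    ncount = np.array([len(m) for m in summary.members_negative], dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        pmean = np.where(pcount > 0, summary.positive_sum / np.maximum(pcount, 1), 0.0)
        nmean = np.where(ncount > 0, summary.negative_sum / np.maximum(ncount, 1), 0.0)
    return MeanAcrossMuscles(
        coordinate=coordinate,
        times=summary.times,
        positive_mean=pmean,
        negative_mean=nmean,
        positive_count=pcount,
        negative_count=ncount,
    )


def add_monte_carlo_bands(
    summary: DirectionalSummary,
    averaged: Sequence[MomentArmTrace],
    config: MonteCarloConfig,
    method: str = "per_trial_sum",
    rng: Optional[np.random.Generator] = None,
) -> DirectionalSummary:
    """Attach Monte Carlo mean/SD bands per side to a directional summary.

    ``per_trial_sum`` perturbs every member muscle independently, sums the
    signed-group contributions within each trial, and summarises the trial
    sums.  ``pooled`` sums the per-muscle trial means and combines SDs in
    quadrature (valid for independent members).
    """
    traces = [tr for tr in averaged if tr.coordinate == summary.coordinate]
    if rng is None:
        rng = config.rng()
    n = summary.times.size
    if method == "per_trial_sum":
        pos_trials = np.zeros((config.n_trials, n))
        neg_trials = np.zeros((config.n_trials, n))
        for tr in traces:
            trials = perturb_trials(tr.values, config, rng=rng)
            pos_trials += np.where(tr.values[None, :] > 0, trials, 0.0)
            neg_trials += np.where(tr.values[None, :] < 0, -trials, 0.0)
        psum = summarise(pos_trials, config)
        nsum = summarise(neg_trials, config)
        summary.positive_mean, summary.positive_sd = psum.mean, psum.sd
        summary.negative_mean, summary.negative_sd = nsum.mean, nsum.sd
    elif method == "pooled":
        pmean = np.zeros(n)
        nmean = np.zeros(n)
        pvar = np.zeros(n)
        nvar = np.zeros(n)
        for tr in traces:
            s = summarise(perturb_trials(tr.values, config, rng=rng), config)
            pos_mask = tr.values > 0
            neg_mask = tr.values < 0
            pmean += np.where(pos_mask, s.mean, 0.0)
            nmean += np.where(neg_mask, -s.mean, 0.0)
            pvar += np.where(pos_mask, s.sd**2, 0.0)
            nvar += np.where(neg_mask, s.sd**2, 0.0)
        summary.positive_mean, summary.positive_sd = pmean, np.sqrt(pvar)
        summary.negative_mean, summary.negative_sd = nmean, np.sqrt(nvar)
    else:
        raise ValueError(f"unknown band method '{method}'")
    return summary


def mask_launch_applicable(
    summary: DirectionalSummary,
    sequence: KinematicSequence,
) -> DirectionalSummary:
    """Annotate frames with launch applicability; numeric values untouched."""
    if summary.coordinate not in sequence.launch_applicable:
        raise KeyError(
            f"sequence carries no launch-applicability intervals for "
            f"'{summary.coordinate}'"
        )
    intervals = sequence.launch_applicable[summary.coordinate]
    mask = np.zeros(summary.times.size, dtype=bool)
    for a, b in intervals:
        mask |= (summary.times >= a) & (summary.times <= b)
    summary.applicable = mask
    return summary


def extensors_only_total(
    summaries: Dict[str, DirectionalSummary],
    model: SkeletalModel,
    sequence: KinematicSequence,
) -> np.ndarray:
    """Launch-limb extensor leverage: summed positive (extensor) arms over the
    flexion–extension coordinates that are launch-applicable at each frame."""
    cmap = model.coordinate_map()
    total: Optional[np.ndarray] = None
    for cname, summary in summaries.items():
        if cmap[cname].axis_role != "flexion_extension":
            continue
        masked = mask_launch_applicable(summary, sequence)
        contrib = np.where(masked.applicable, masked.positive_sum, 0.0)
        total = contrib if total is None else total + contrib
    if total is None:
        raise ValueError("no flexion-extension coordinates among summaries")
    return total
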