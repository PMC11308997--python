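"""End-to-end orchestration: traces -> averaging -> Monte Carlo -> sums.

One call runs the whole moment-arm study for a model over one or more
take-off sequences and returns an in-memory result object that the
results writer (and the analysis drivers) consume.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np

from .aggregate import (
    DirectionalSummary,
    MeanAcrossMuscles,
    add_monte_carlo_bands,
    average_all_muscles,
    directional_sum,
    extensors_only_total,
    mask_launch_applicable,
    mean_across_muscles,
)
from .kinematics import KinematicSequence
from .model import SkeletalModel
from .momentarm import MomentArmTrace, trace_sequence
from .montecarlo import MonteCarloConfig


@dataclass
class StyleResult:
    """All computed quantities for one take-off style."""

    style: str
    sequence: KinematicSequence
    mtu_traces: List[MomentArmTrace]
    averaged: Dict[tuple, MomentArmTrace]
    summaries: Dict[str, DirectionalSummary]
    means: Dict[str, MeanAcrossMuscles]
    extensors_only: np.ndarray


@dataclass
class AnalysisResult:
    model: SkeletalModel
    styles: Dict[str, StyleResult] = field(default_factory=dict)
    n_frames: int = 101
    mc: Optional[MonteCarloConfig] = None


def run_takeoff_analysis(
    model: SkeletalModel,
    sequences: Dict[str, KinematicSequence],
    n_frames: int = 101,
    mc: Optional[MonteCarloConfig] = None,
    band_method: str = "per_trial_sum",
    coordinates: Optional[Sequence[str]] = None,
) -> AnalysisResult:
    """Run the full moment-arm analysis for each take-off style.

    Monte Carlo bands (when ``mc`` is given) use one random stream per
    style, seeded deterministically from ``mc.seed`` and the style's
    position in sorted order, so muscles and coordinates all draw
    independent perturbations yet the whole run is reproducible.
    """
    if mc is None:
        mc = MonteCarloConfig()
    if coordinates is None:
        coordinates = list(model.analysis_coordinates)
    result = AnalysisResult(model=model, n_frames=n_frames, mc=mc)
    for si, style in enumerate(sorted(sequences)):
        seq = sequences[style]
        traces = trace_sequence(model, seq, coordinates=coordinates, n_frames=n_frames)
        averaged = average_all_muscles(traces, model)
        avg_list = list(averaged.values())
        rng = np.random.default_rng([mc.seed, si])
        summaries: Dict[str, DirectionalSummary] = {}
        means: Dict[str, MeanAcrossMuscles] = {}
        for coord in coordinates:
            summary = directional_sum(avg_list, coord)
            add_monte_carlo_bands(summary, avg_list, mc, method=band_method, rng=rng)
            mask_launch_applicable(summary, seq)
            summaries[coord] = summary
            means[coord] = mean_across_muscles(avg_list, coord)
        ext = extensors_only_total(summaries, model, seq)
        result.styles[style] = StyleResult(
            style=style,
            sequence=seq,
            mtu_traces=traces,
            averaged=averaged,
            summaries=summaries,
            means=means,
            extensors_only=ext,
        )
    return result
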