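"""Results export: long-format CSV tables, a JSON run manifest, and
figure-style trace plots.

CSV output is deterministic for a given seed and configuration: fixed
column order, fixed float formatting, no timestamps.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd

from . import __version__
from .aggregate import GROUP_LABELS
from .model import SkeletalModel
from .pipeline import AnalysisResult

_FLOAT_FMT = "%.10g"


@dataclass
class RunConfig:
    """Configuration for a full analysis run."""

    model_path: Optional[str] = None
    styles: List[str] = field(
        default_factory=lambda: ["bipedal_burst", "bipedal_countermotion", "quadrupedal"]
    )
    n_frames: int = 101
    mc_fraction: float = 0.20
    mc_trials: int = 1000
    seed: int = 0
    output_dir: str = "results"
    band_method: str = "per_trial_sum"
    presets: List[str] = field(
        default_factory=lambda: ["summed", "mean_across_muscles", "extensors_only"]
    )
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")


def _axis_role(model: SkeletalModel, coordinate: str) -> str:
    return model.coordinate_map()[coordinate].axis_role


def summed_table(result: AnalysisResult) -> pd.DataFrame:
    """Long-format directional-sum table: one row per (style, coordinate, side, time)."""
    rows = []
    model = result.model
    for style in sorted(result.styles):
        sr = result.styles[style]
        for coord in sorted(sr.summaries):
            s = sr.summaries[coord]
            role = _axis_role(model, coord)
            for side, total, mean, sd, members in (
                ("positive", s.positive_sum, s.positive_mean, s.positive_sd, s.members_positive),
                ("negative", s.negative_sum, s.negative_mean, s.negative_sd, s.members_negative),
            ):
                label = GROUP_LABELS[(role, side)]
                for i, t in enumerate(s.times):
                    rows.append(
                        {
                            "style": style,
                            "coordinate": coord,
                            "side": side,
                            "functional_group": label,
                            "time_s": t,
                            "summed_ma_m": total[i],
                            "mc_mean_m": mean[i] if mean is not None else np.nan,
                            "mc_sd_m": sd[i] if sd is not None else np.nan,
                            "launch_applicable": bool(s.applicable[i])
                            if s.applicable is not None
                            else False,
                            "n_members": len(members[i]),
                            "members": "|".join(members[i]),
                        }
                    )
    return pd.DataFrame(rows)


def mtu_table(result: AnalysisResult) -> pd.DataFrame:
    """Per-MTU moment-arm table across styles and coordinates."""
    rows = []
    for style in sorted(result.styles):
        sr = result.styles[style]
        for tr in sr.mtu_traces:
            flagged = set(tr.wrap_transition_frames)
            for i, t in enumerate(tr.times):
                rows.append(
                    {
                        "style": style,
                        "mtu": tr.mtu,
                        "coordinate": tr.coordinate,
                        "time_s": t,
                        "moment_arm_m": tr.values[i],
                        "wrap_transition": i in flagged,
                    }
                )
    return pd.DataFrame(rows)


def mean_table(result: AnalysisResult) -> pd.DataFrame:
    rows = []
    for style in sorted(result.styles):
        sr = result.styles[style]
        for coord in sorted(sr.means):
            m = sr.means[coord]
            for side, vals, counts in (
                ("positive", m.positive_mean, m.positive_count),
                ("negative", m.negative_mean, m.negative_count),
            ):
                for i, t in enumerate(m.times):
                    rows.append(
                        {
                            "style": style,
                            "coordinate": coord,
                            "side": side,
                            "time_s": t,
                            "mean_ma_m": vals[i],
                            "n_muscles": int(counts[i]),
                        }
                    )
    return pd.DataFrame(rows)


def extensors_table(result: AnalysisResult) -> pd.DataFrame:
    rows = []
    for style in sorted(result.styles):
        sr = result.styles[style]
        times = next(iter(sr.summaries.values())).times
        for i, t in enumerate(times):
            rows.append(
                {"style": style, "time_s": t, "launch_extensor_total_m": sr.extensors_only[i]}
            )
    return pd.DataFrame(rows)


def write_results(
    result: AnalysisResult,
    directory: str | Path,
    config: Optional[RunConfig] = None,
    plots: bool = False,
) -> Dict[str, Path]:
    """Write all result tables plus a JSON manifest; optionally plots."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    out: Dict[str, Path] = {}

    tables = {
        "summed_moment_arms.csv": summed_table(result),
        "mtu_moment_arms.csv": mtu_table(result),
        "mean_across_muscles.csv": mean_table(result),
        "extensors_only.csv": extensors_table(result),
    }
    for fname, df in tables.items():
        p = directory / fname
        df.to_csv(p, index=False, float_format=_FLOAT_FMT)
        out[fname] = p

    manifest = {
        "package_version": __version__,
        "model": result.model.name,
        "n_frames": result.n_frames,
        "monte_carlo": {
            "fraction": result.mc.fraction if result.mc else None,
            "n_trials": result.mc.n_trials if result.mc else None,
            "seed": result.mc.seed if result.mc else None,
            "perturbation_scope": result.mc.perturbation_scope if result.mc else None,
        },
        "styles": sorted(result.styles),
        "coordinates": sorted(next(iter(result.styles.values())).summaries)
        if result.styles
        else [],
        "run_config": vars(config) if config else None,
    }
    p = directory / "manifest.json"
    p.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    out["manifest.json"] = p

    if plots:
        out.update(write_plots(result, directory / "figures"))
    return out


def write_plots(result: AnalysisResult, directory: str | Path) -> Dict[str, Path]:
    """Per-style trace figures: solid Monte Carlo means, dashed error
    bounds, shading where frames are not launch-applicable."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    out: Dict[str, Path] = {}
    model = result.model
    for style in sorted(result.styles):
        sr = result.styles[style]
        coords = sorted(sr.summaries)
        ncols = 3
        nrows = int(np.ceil(len(coords) / ncols))
        fig, axes = plt.subplots(nrows, ncols, figsize=(4 * ncols, 2.6 * nrows), squeeze=False)
        for k, coord in enumerate(coords):
            ax = axes[k // ncols][k % ncols]
            s = sr.summaries[coord]
            role = _axis_role(model, coord)
            for side, mean, sd, color in (
                ("positive", s.positive_mean, s.positive_sd, "tab:red"),
                ("negative", s.negative_mean, s.negative_sd, "tab:blue"),
            ):
                if mean is None:
                    continue
                ax.plot(s.times, mean, color=color, label=GROUP_LABELS[(role, side)])
                ax.plot(s.times, mean + sd, color=color, ls="--", lw=0.8)
                ax.plot(s.times, mean - sd, color=color, ls="--", lw=0.8)
            if s.applicable is not None and not s.applicable.all():
                ax.fill_between(
                    s.times, 0, 1, where=~s.applicable, transform=ax.get_xaxis_transform(),
                    color="0.85", zorder=0,
                )
            for _, a, b in sr.sequence.phases[:-1]:
                ax.axvline(b, color="0.5", lw=0.6)
            ax.set_title(coord, fontsize=9)
            ax.legend(fontsize=6)
        for k in range(len(coords), nrows * ncols):
            axes[k // ncols][k % ncols].axis("off")
        fig.suptitle(f"Summed moment arms — {style}")
        fig.supxlabel("time (s)")
        fig.supylabel("moment arm (m)")
        fig.tight_layout()
        p = directory / f"summed_{style}.png"
        fig.savefig(p, dpi=110)
        plt.close(fig)
        out[p.name] = p
    return out
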