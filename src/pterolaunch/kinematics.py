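"""Take-off kinematic sequences built from key poses.

Each hypothesised take-off style is a one-second sequence assembled from a
small set of key poses at fractional times, interpolated coordinate-wise.
The default interpolant is shape-preserving piecewise-cubic (PCHIP), which
reproduces key poses exactly and cannot overshoot the range spanned by
neighbouring key values; linear interpolation is available as an option.

Phase structure per style:

* bipedal burst       — crouch, ankle_lifted, launch
* bipedal countermotion — countermotion, launch
* quadrupedal         — crouch, vault, launch (hindlimb leaves the ground
  partway through the vault)

Launch applicability follows the styles' mechanics: the hindlimb powers
both bipedal styles throughout, while the quadrupedal style uses the
hindlimb only until liftoff during the vault and the forelimb from vault
onset to the end of launch.  The default phase-boundary fractions are
package defaults chosen to reflect the published extant profiles (quail,
starling, vampire bat); they are configuration, not measured values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.interpolate import PchipInterpolator

from .model import Pose, SkeletalModel

logger = logging.getLogger(__name__)

STYLES = ("bipedal_burst", "bipedal_countermotion", "quadrupedal")

STYLE_PHASES: Dict[str, Tuple[str, ...]] = {
    "bipedal_burst": ("crouch", "ankle_lifted", "launch"),
    "bipedal_countermotion": ("countermotion", "launch"),
    "quadrupedal": ("crouch", "vault", "launch"),
}

# Default interior phase-boundary fractions per style.  NON-MEASURED
# package defaults: the source profiles print no boundary numbers.
DEFAULT_PHASE_BOUNDARIES: Dict[str, Tuple[float, ...]] = {
    "bipedal_burst": (0.40, 0.70),
    "bipedal_countermotion": (0.55,),
    "quadrupedal": (0.35, 0.65),
}

#: fraction at which the hindlimb leaves the ground during the quadrupedal vault
DEFAULT_HINDLIMB_LIFTOFF = 0.55

_FORELIMB_KEYS = ("shoulder", "elbow", "wrist", "wing")
_HINDLIMB_KEYS = ("hip", "knee", "ankle")


def limb_of_coordinate(model: SkeletalModel, coordinate: str) -> str:
    """'forelimb' or 'hindlimb', inferred from the owning joint's name."""
    coord = model.coordinate_map().get(coordinate)
    if coord is None:
        raise KeyError(f"unknown coordinate '{coordinate}'")
    jname = coord.joint.lower()
    if any(k in jname for k in _FORELIMB_KEYS):
        return "forelimb"
    if any(k in jname for k in _HINDLIMB_KEYS):
        return "hindlimb"
    raise KeyError(f"cannot map joint '{coord.joint}' to a limb")


@dataclass
class KeyPose:
    pose: Pose
    time_fraction: float
    label: str = ""


@dataclass
class KinematicSequence:
    """A one-second take-off trajectory with phase structure."""

    style: str
    key_poses: List[KeyPose]
    phases: List[Tuple[str, float, float]]
    launch_applicable: Dict[str, List[Tuple[float, float]]] = field(default_factory=dict)
    duration: float = 1.0
    interpolation: str = "pchip"  # pchip | linear
    coordinate_ranges: Dict[str, Tuple[float, float]] = field(default_factory=dict)
    _interp: Optional[Dict[str, object]] = field(default=None, repr=False)

    def __post_init__(self) -> None:
        fracs = [kp.time_fraction for kp in self.key_poses]
        if len(fracs) < 2 or any(b <= a for a, b in zip(fracs, fracs[1:])):
            raise ValueError("key-pose time fractions must be strictly increasing")
        if fracs[0] != 0.0 or fracs[-1] != 1.0:
            raise ValueError("key poses must start at fraction 0 and end at 1")
        if self.duration != 1.0:
            raise ValueError("take-off sequences are normalised to 1 s")
        expected = STYLE_PHASES.get(self.style)
        if expected is None:
            raise ValueError(f"unknown take-off style '{self.style}'")
        if tuple(name for name, _, _ in self.phases) != expected:
            raise ValueError(
                f"phases {[p[0] for p in self.phases]} do not match "
                f"style '{self.style}' phases {list(expected)}"
            )
        edges = [self.phases[0][1]] + [p[2] for p in self.phases]
        starts = [p[1] for p in self.phases]
        if edges[0] != 0.0 or edges[-1] != 1.0 or any(
            s != e for s, e in zip(starts[1:], edges[1:-1])
        ) or any(b <= a for a, b in zip(edges, edges[1:])):
            raise ValueError("phases must partition [0, 1] without gaps or overlaps")

    def coordinates(self) -> List[str]:
        return list(self.key_poses[0].pose.keys())

    def _interpolators(self) -> Dict[str, object]:
        if self._interp is None:
            fracs = np.array([kp.time_fraction for kp in self.key_poses])
            interp: Dict[str, object] = {}
            for cname in self.coordinates():
                vals = np.array([kp.pose[cname] for kp in self.key_poses])
                if self.interpolation == "linear":
                    interp[cname] = (fracs, vals)
                else:
                    interp[cname] = PchipInterpolator(fracs, vals)
            self._interp = interp
        return self._interp

    def pose_at(self, t: float) -> Pose:
        """Interpolated pose at time fraction t in [0, 1]."""
        if not 0.0 <= t <= 1.0:
            raise ValueError(f"time fraction {t} outside [0, 1]")
        for kp in self.key_poses:
            if t == kp.time_fraction:
                return dict(kp.pose)
        interp = self._interpolators()
        pose: Pose = {}
        for cname, f in interp.items():
            if self.interpolation == "linear":
                fracs, vals = f
                q = float(np.interp(t, fracs, vals))
            else:
                q = float(f(t))
            rng = self.coordinate_ranges.get(cname)
            if rng is not None:
                qc = min(max(q, rng[0]), rng[1])
                if qc != q:
                    logger.warning(
                        "interpolated %s=%.6f clamped to %.6f at t=%.4f", cname, q, qc, t
                    )
                q = qc
            pose[cname] = q
        return pose

    def phase_at(self, t: float) -> str:
        for name, a, b in self.phases:
            if a <= t < b:
                return name
        return self.phases[-1][0]


def interpolate_pose(sequence: KinematicSequence, t: float) -> Pose:
    return sequence.pose_at(t)


def normalise_timing(raw_times: Sequence[float]) -> List[float]:
    """Affine map of raw key-pose times (s) onto [0, 1], spacing preserved."""
    times = list(map(float, raw_times))
    if len(times) < 2 or any(b <= a for a, b in zip(times, times[1:])):
        raise ValueError("raw times must be strictly increasing with >= 2 entries")
    t0, t1 = times[0], times[-1]
    return [(t - t0) / (t1 - t0) for t in times]


def launch_applicability(
    model: SkeletalModel,
    style: str,
    phase_boundaries: Sequence[float],
    hindlimb_liftoff: float = DEFAULT_HINDLIMB_LIFTOFF,
    coordinates: Optional[Sequence[str]] = None,
) -> Dict[str, List[Tuple[float, float]]]:
    """Per-coordinate time intervals over which moment arms count toward launch."""
    if coordinates is None:
        coordinates = model.analysis_coordinates
    out: Dict[str, List[Tuple[float, float]]] = {}
    for cname in coordinates:
        limb = limb_of_coordinate(model, cname)
        if style in ("bipedal_burst", "bipedal_countermotion"):
            out[cname] = [(0.0, 1.0)] if limb == "hindlimb" else []
        elif style == "quadrupedal":
            vault_onset = phase_boundaries[0]
            if limb == "forelimb":
                out[cname] = [(vault_onset, 1.0)]
            else:
                out[cname] = [(0.0, hindlimb_liftoff)]
        else:
            raise ValueError(f"unknown style '{style}'")
    return out


def build_takeoff_sequence(
    model: SkeletalModel,
    style: str,
    key_poses: Sequence[KeyPose],
    phase_boundaries: Optional[Sequence[float]] = None,
    hindlimb_liftoff: float = DEFAULT_HINDLIMB_LIFTOFF,
    interpolation: str = "pchip",
) -> KinematicSequence:
    """Assemble a validated one-second sequence for one take-off style."""
    if style not in STYLES:
        raise ValueError(f"unknown take-off style '{style}'")
    if phase_boundaries is None:
        phase_boundaries = DEFAULT_PHASE_BOUNDARIES[style]
    names = STYLE_PHASES[style]
    if len(phase_boundaries) != len(names) - 1:
        raise ValueError(
            f"style '{style}' needs {len(names) - 1} interior phase boundaries"
        )
    edges = [0.0, *phase_boundaries, 1.0]
    phases = [(n, edges[i], edges[i + 1]) for i, n in enumerate(names)]
    ranges = {c.name: c.range for j in model.joints for c in j.coordinates}
    applicable = launch_applicability(
        model, style, phase_boundaries, hindlimb_liftoff=hindlimb_liftoff
    )
    return KinematicSequence(
        style=style,
        key_poses=list(key_poses),
        phases=phases,
        launch_applicable=applicable,
        interpolation=interpolation,
        coordinate_ranges=ranges,
    )
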