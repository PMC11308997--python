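"""Monte Carlo uncertainty model for moment-arm estimates.

Each moment-arm value v is independently perturbed multiplicatively,
v -> v * (1 + u) with u ~ Uniform(-fraction, +fraction), for ``n_trials``
simulated trials (defaults: fraction 0.20, 1000 trials), and the trial
distribution is summarised by its mean and standard deviation.  The
perturbation acts on computed moment-arm values, not on model geometry.

Whether each time sample gets its own multiplier or one multiplier covers
a whole trial is genuinely ambiguous in this kind of error model; both
scopes are implemented (``per_frame_independent`` is the default).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

logger = logging.getLogger(__name__)

SCOPES = ("per_frame_independent", "per_trial_constant")


@dataclass
class MonteCarloConfig:
    fraction: float = 0.20
    n_trials: int = 1000
    seed: int = 0
    perturbation_scope: str = "per_frame_independent"

    def __post_init__(self) -> None:
        if not 0.0 <= self.fraction < 1.0:
            raise ValueError("fraction must be in [0, 1)")
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")
        if self.perturbation_scope not in SCOPES:
            raise ValueError(f"perturbation_scope must be one of {SCOPES}")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass
class MonteCarloSummary:
    """Per-sample mean and SD of the simulated trial distribution."""

    mean: np.ndarray
    sd: np.ndarray
    fraction: float
    n_trials: int
    seed: int


def perturb_trials(
    values: np.ndarray,
    config: MonteCarloConfig,
    rng: Optional[np.random.Generator] = None,
) -> np.ndarray:
    """Simulated trials for one trace: an (n_trials, n_samples) matrix.

    Pass a shared ``rng`` when perturbing several traces so each draws an
    independent stream from one seeded generator; by default a fresh
    generator is seeded from the config.
    """
    v = np.atleast_1d(np.asarray(values, dtype=float))
    if not np.all(np.isfinite(v)):
        raise ValueError("trace values must be finite")
    if rng is None:
        rng = config.rng()
    f = config.fraction
    if config.perturbation_scope == "per_frame_independent":
        u = rng.uniform(-f, f, size=(config.n_trials, v.size))
    else:
        u = rng.uniform(-f, f, size=(config.n_trials, 1))
    return v[None, :] * (1.0 + u)


def summarise(trials: np.ndarray, config: Optional[MonteCarloConfig] = None) -> MonteCarloSummary:
    """Mean and (n-1)-denominator SD of a trial matrix, per time sample."""
    trials = np.asarray(trials, dtype=float)
    if trials.ndim != 2 or trials.shape[0] < 1:
        raise ValueError("trial matrix must be 2-D with at least one trial")
    mean = trials.mean(axis=0)
    if trials.shape[0] == 1:
        logger.warning("single-trial summary: SD reported as 0")
        sd = np.zeros_like(mean)
    else:
        sd = trials.std(axis=0, ddof=1)
    return MonteCarloSummary(
        mean=mean,
        sd=sd,
        fraction=config.fraction if config else float("nan"),
        n_trials=trials.shape[0],
        seed=config.seed if config else -1,
    )
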