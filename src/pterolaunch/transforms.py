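"""Minimal rigid-transform algebra used by the kinematic chain.

All rotations are proper orthonormal 3x3 matrices; translations are in
metres.  Scipy's Rotation class backs the axis-angle construction so the
package never hand-rolls Rodrigues' formula.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation


@dataclass(frozen=True)
class RigidTransform:
    """A rotation followed by a translation: x_world = R @ x_local + t."""

    R: np.ndarray = field(default_factory=lambda: np.eye(3))
    t: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        object.__setattr__(self, "R", np.asarray(self.R, dtype=float).reshape(3, 3))
        object.__setattr__(self, "t", np.asarray(self.t, dtype=float).reshape(3))

    @staticmethod
    def identity() -> "RigidTransform":
        return RigidTransform()

    @staticmethod
    def from_translation(t) -> "RigidTransform":
        return RigidTransform(np.eye(3), t)

    @staticmethod
    def from_axis_angle(axis, angle: float) -> "RigidTransform":
        axis = np.asarray(axis, dtype=float)
        n = np.linalg.norm(axis)
        if n == 0.0:
            raise ValueError("rotation axis must be non-zero")
        return RigidTransform(Rotation.from_rotvec(axis / n * angle).as_matrix(), np.zeros(3))

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self ∘ other: apply `other` first, then `self`."""
        return RigidTransform(self.R @ other.R, self.R @ other.t + self.t)

    def __matmul__(self, other: "RigidTransform") -> "RigidTransform":
        return self.compose(other)

    def apply(self, points) -> np.ndarray:
        p = np.asarray(points, dtype=float)
        return p @ self.R.T + self.t

    def inverse(self) -> "RigidTransform":
        Rt = self.R.T
        return RigidTransform(Rt, -Rt @ self.t)

    def is_orthonormal(self, tol: float = 1e-9) -> bool:
        return bool(
            np.linalg.norm(self.R.T @ self.R - np.eye(3)) < tol
            and np.linalg.det(self.R) > 0.0
        )
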