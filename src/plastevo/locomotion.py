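"""Deterministic 2-D locomotion surrogate and behaviour metrics.

Each motor command contributes thrust along its joint's orientation: the
unit vector of the slot direction through which the joint attaches to
its parent, rotated 90 degrees (counter-clockwise) when the joint's
rotation label is 90.  Per-tick velocity is the gain-scaled mean of the
signed joint thrusts, so top speed is the gain ``c`` regardless of body
size, and zero-mean oscillation produces negligible net displacement.
This keeps the joint body/brain determination of locomotion direction
while replacing contact physics with a closed-form model, so absolute
speeds are not comparable to a physics engine — only relational results
are.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .morphogenesis import DIRECTIONS, BodyPhenotype
from .neurogenesis import DEFAULT_DT, BrainPhenotype, run_controller

DEFAULT_GAIN = 1.0  # cm/s at full saturated thrust


@dataclass(frozen=True)
class Direction:
    tag: str
    unit_vector: tuple[float, float]


RIGHT = Direction("right", (1.0, 0.0))
LEFT = Direction("left", (-1.0, 0.0))
DOWN = Direction("down", (0.0, -1.0))

DIRECTIONS_BY_TAG = {d.tag: d for d in (RIGHT, LEFT, DOWN)}

#: the studied behaviour pairs: mutually exclusive vs. partially compatible
DIRECTION_PAIRS = {
    "right_left": (RIGHT, LEFT),
    "right_down": (RIGHT, DOWN),
}


@dataclass
class BehaviorRecord:
    """Planar trajectory of one 30 s condition, starting at the origin."""

    trajectory: np.ndarray  # (steps + 1, 2) positions in cm, row 0 = (0, 0)
    condition: str  # "A" | "B"
    dt: float = DEFAULT_DT

    @property
    def endpoint(self) -> np.ndarray:
        return self.trajectory[-1]

    @property
    def duration_s(self) -> float:
        return (len(self.trajectory) - 1) * self.dt

    def path_length(self) -> float:
        deltas = np.diff(self.trajectory, axis=0)
        return float(np.hypot(deltas[:, 0], deltas[:, 1]).sum())


def joint_orientations(body: BodyPhenotype) -> np.ndarray:
    """Thrust unit vectors, one per joint, in oscillator order."""
    rows = []
    for m in body.joint_modules():
        ux, uy = DIRECTIONS[m.parent_slot]
        if m.rotation == 90:
            ux, uy = -uy, ux  # counter-clockwise quarter turn
        rows.append((float(ux), float(uy)))
    return np.array(rows, dtype=float).reshape(len(rows), 2)


def simulate(body: BodyPhenotype, brain: BrainPhenotype, steps: int,
             gain: float = DEFAULT_GAIN, dt: float = DEFAULT_DT,
             condition: str = "A") -> BehaviorRecord:
    """Integrate the surrogate: v(t) = (c / max(1, J)) * sum_j u_j m_j(t)."""
    orientations = joint_orientations(body)
    positions = tuple(m.grid_pos for m in body.joint_modules())
    if positions != brain.positions:
        raise ValueError("brain was not built for this body (joint mismatch)")
    n_joints = orientations.shape[0]
    trace = run_controller(brain, steps, dt=dt)
    if n_joints == 0:
        trajectory = np.zeros((steps + 1, 2))
    else:
        velocity = (gain / max(1, n_joints)) * trace.outputs @ orientations
        trajectory = np.vstack([np.zeros(2), np.cumsum(velocity * dt, axis=0)])
    if not np.all(np.isfinite(trajectory)):
        raise ValueError("non-finite trajectory")
    return BehaviorRecord(trajectory=trajectory, condition=condition, dt=dt)


def speed_in_direction(record: BehaviorRecord, direction: Direction,
                       duration_s: float | None = None) -> float:
    """Signed speed (cm/s) toward the due direction; wrong-way is negative."""
    if len(record.trajectory) < 2:
        raise ValueError("empty trajectory")
    if duration_s is None:
        duration_s = record.duration_s
    if duration_s <= 0:
        raise ValueError("duration_s must be > 0")
    displacement = record.trajectory[-1] - record.trajectory[0]
    u = np.asarray(direction.unit_vector)
    return float(displacement @ u / duration_s)


def total_displacement(record_a: BehaviorRecord, record_b: BehaviorRecord) -> float:
    """Sum over both conditions of |dx| + |dy| between start and end (cm)."""
    total = 0.0
    for rec in (record_a, record_b):
        delta = rec.trajectory[-1] - rec.trajectory[0]
        total += float(abs(delta[0]) + abs(delta[1]))
    return total


def trajectory_table(record: BehaviorRecord) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "tick": np.arange(len(record.trajectory)),
            "x": record.trajectory[:, 0],
            "y": record.trajectory[:, 1],
            "condition": record.condition,
        }
    )
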