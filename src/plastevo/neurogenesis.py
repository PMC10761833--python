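"""Differential-CPG controllers generated by the brain CPPN.

Each servo joint carries one differential oscillator: a pair of neurons
(x, y) whose activations change per control tick as

    dx_i = w_yx_i * y_i(t-1) + sum_j w_ij * x_j(t-1)      (j grid-adjacent)
    dy_i = w_xy_i * x_i(t-1)

followed by the explicit-Euler update x += dx, y += dy with an implicit
unit step (one control tick = 0.1 s of simulated lifetime).  The motor
command is the y neuron clipped to [-1, 1]; clipping never feeds back
into the internal state.  All weights come from querying the brain CPPN
at the joint coordinates (pairs of coordinates for neighbour weights)
and are squashed into (-1, 1) with tanh.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace

import numpy as np

from .cppn import EnvironmentSignal, OrganismGenotype, PlasticityMode
from .morphogenesis import DIRECTIONS, BodyPhenotype

logger = logging.getLogger(__name__)

_clamp_warned = False


def _warn_clamped() -> None:
    # saturated oscillators clamp routinely; report loudly once, then quietly
    global _clamp_warned
    level = logging.DEBUG if _clamp_warned else logging.WARNING
    logger.log(level, "oscillator state clamped at magnitude %.0e", STATE_BOUND)
    _clamp_warned = True

#: default initial oscillator state (non-zero: the origin is a fixed point)
INITIAL_STATE = math.sqrt(0.5)

#: internal-state magnitude guard against float overflow
STATE_BOUND = 1e6

DEFAULT_DT = 0.1


@dataclass
class BrainPhenotype:
    """One oscillator per joint plus recurrent neighbour couplings.

    ``neighbors`` holds ordered pairs ``(i, j, w)``: ``w * x_j`` is added
    to ``dx_i``.  Oscillator order matches
    :meth:`BodyPhenotype.joint_modules`.
    """

    positions: tuple[tuple[int, int], ...]
    w_xy: tuple[float, ...]
    w_yx: tuple[float, ...]
    neighbors: tuple[tuple[int, int, float], ...]
    x: tuple[float, ...]
    y: tuple[float, ...]

    @property
    def n_oscillators(self) -> int:
        return len(self.positions)


@dataclass
class MotorTrace:
    """Clipped per-oscillator motor commands, one row per control tick."""

    outputs: np.ndarray  # shape (steps, n_oscillators), values in [-1, 1]
    dt: float = DEFAULT_DT

    @property
    def steps(self) -> int:
        return self.outputs.shape[0]


def develop_brain(genotype: OrganismGenotype, body: BodyPhenotype,
                  signal: int, initial_state: float = INITIAL_STATE) -> BrainPhenotype:
    """Build the controller for a developed body under one condition.

    The signal is clamped to 0 in the non-plastic mode, making the
    brains for S=+1 and S=-1 identical by construction.
    """
    signal = EnvironmentSignal(int(signal))
    if genotype.plasticity_mode is PlasticityMode.NON_PLASTIC:
        s = 0.0
    else:
        s = float(signal)
    brain_cppn = genotype.brain_cppn

    joints = body.joint_modules()
    positions = tuple(m.grid_pos for m in joints)
    w_xy: list[float] = []
    w_yx: list[float] = []
    for (jx, jy) in positions:
        out = brain_cppn.query([float(jx), float(jy), float(jx), float(jy), s, 1.0])
        w_xy.append(math.tanh(out[0]))
        w_yx.append(math.tanh(out[1]))

    index = {pos: i for i, pos in enumerate(positions)}
    neighbors: list[tuple[int, int, float]] = []
    for i, (jx, jy) in enumerate(positions):
        for dx, dy in DIRECTIONS:
            j = index.get((jx + dx, jy + dy))
            if j is None:
                continue
            out = brain_cppn.query(
                [float(jx), float(jy), float(jx + dx), float(jy + dy), s, 1.0]
            )
            neighbors.append((i, j, math.tanh(out[1])))

    n = len(positions)
    state = (float(initial_state),) * n
    return BrainPhenotype(
        positions=positions,
        w_xy=tuple(w_xy),
        w_yx=tuple(w_yx),
        neighbors=tuple(neighbors),
        x=state,
        y=state,
    )


def _advance(x: list[float], y: list[float], w_xy, w_yx, neighbors, steps: int,
             record: list | None = None) -> bool:
    """In-place explicit-Euler iteration; returns True if the bound clamped."""
    n = len(x)
    clamped = False
    bound = STATE_BOUND
    for _ in range(steps):
        dx = [w_yx[i] * y[i] for i in range(n)]
        for i, j, w in neighbors:
            dx[i] += w * x[j]
        for i in range(n):
            xi = x[i] + dx[i]
            yi = y[i] + w_xy[i] * x[i]
            if xi > bound:
                xi, clamped = bound, True
            elif xi < -bound:
                xi, clamped = -bound, True
            if yi > bound:
                yi, clamped = bound, True
            elif yi < -bound:
                yi, clamped = -bound, True
            x[i] = xi
            y[i] = yi
        if record is not None:
            record.append([max(-1.0, min(1.0, yi)) for yi in y])
    return clamped


def step_cpg(brain: BrainPhenotype) -> BrainPhenotype:
    """Advance all oscillators one control tick; returns a new brain state."""
    x, y = list(brain.x), list(brain.y)
    clamped = _advance(x, y, brain.w_xy, brain.w_yx, brain.neighbors, 1)
    if clamped:
        _warn_clamped()
    return replace(brain, x=tuple(x), y=tuple(y))


def motor_outputs(brain: BrainPhenotype) -> np.ndarray:
    """Motor commands for the current state: y clipped to [-1, 1]."""
    return np.clip(np.asarray(brain.y, dtype=float), -1.0, 1.0)


def run_controller(brain: BrainPhenotype, steps: int,
                   dt: float = DEFAULT_DT) -> MotorTrace:
    """Run the CPG from its configured initial state, recording motor outputs."""
    if steps < 0:
        raise ValueError("steps must be >= 0")
    n = brain.n_oscillators
    record: list[list[float]] = []
    x, y = list(brain.x), list(brain.y)
    clamped = _advance(x, y, brain.w_xy, brain.w_yx, brain.neighbors, steps, record)
    if clamped:
        _warn_clamped()
    outputs = np.array(record, dtype=float).reshape(steps, n)
    return MotorTrace(outputs=outputs, dt=dt)


def brain_to_dict(brain: BrainPhenotype) -> dict:
    return {
        "positions": [list(p) for p in brain.positions],
        "w_xy": list(brain.w_xy),
        "w_yx": list(brain.w_yx),
        "neighbors": [list(t) for t in brain.neighbors],
        "x": list(brain.x),
        "y": list(brain.y),
    }


def brain_from_dict(d: dict) -> BrainPhenotype:
    return BrainPhenotype(
        positions=tuple(tuple(p) for p in d["positions"]),
        w_xy=tuple(d["w_xy"]),
        w_yx=tuple(d["w_yx"]),
        neighbors=tuple((int(i), int(j), float(w)) for i, j, w in d["neighbors"]),
        x=tuple(d["x"]),
        y=tuple(d["y"]),
    )
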