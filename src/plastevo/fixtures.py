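"""Hand-built reference organisms with known, analytically tractable behaviour.

These are constructed directly at the phenotype (or genotype) level and
serve as ground-truth probes of the surrogate: a saturating thruster
moves straight at top speed, an antisymmetric oscillator produces
zero-mean wobble, and an S-switched genotype demonstrates that
environmental regulation of the body is functional.
"""

from __future__ import annotations

import math

from .cppn import (
    BODY_INPUT_ARITY,
    BODY_OUTPUT_ARITY,
    BRAIN_INPUT_ARITY,
    BRAIN_OUTPUT_ARITY,
    ConnGene,
    CPPNGenome,
    NodeGene,
    OrganismGenotype,
    PlasticityMode,
)
from .morphogenesis import DIRECTIONS, BodyPhenotype, Module
from .neurogenesis import INITIAL_STATE, BrainPhenotype

#: saturating intra-oscillator weight: same sign on both connections makes
#: the state grow along (+1, +1) from the symmetric initial state, so the
#: motor command reaches and holds +1 within a few ticks.
SATURATING_WEIGHT = 0.6

#: antisymmetric weight: w_xy = -w_yx gives a pure (growing) rotation whose
#: motor output is zero-mean.
OSCILLATING_WEIGHT = 0.3


def _body_with_joints(slots: list[int], rotations: list[int] | None = None) -> BodyPhenotype:
    """Core plus one joint per requested slot direction."""
    rotations = rotations or [0] * len(slots)
    core = Module("core", 0, (0, 0), None)
    occupancy = {(0, 0): core}
    for slot, rot in zip(slots, rotations):
        dx, dy = DIRECTIONS[slot]
        joint = Module("joint", rot, (dx, dy), slot)
        core.children[slot] = joint
        occupancy[joint.grid_pos] = joint
    return BodyPhenotype(core, occupancy, max_modules=10)


def _manual_brain(body: BodyPhenotype, w_xy: float, w_yx: float) -> BrainPhenotype:
    joints = body.joint_modules()
    n = len(joints)
    state = (INITIAL_STATE,) * n
    return BrainPhenotype(
        positions=tuple(m.grid_pos for m in joints),
        w_xy=(w_xy,) * n,
        w_yx=(w_yx,) * n,
        neighbors=(),
        x=state,
        y=state,
    )


def right_thruster() -> tuple[BodyPhenotype, BrainPhenotype]:
    """One +x joint whose oscillator saturates at +1: straight-right motion."""
    body = _body_with_joints([0])
    return body, _manual_brain(body, SATURATING_WEIGHT, SATURATING_WEIGHT)


def down_thruster() -> tuple[BodyPhenotype, BrainPhenotype]:
    """One -y joint whose oscillator saturates at +1: straight-down motion."""
    body = _body_with_joints([3])
    return body, _manual_brain(body, SATURATING_WEIGHT, SATURATING_WEIGHT)


def diagonal_thruster() -> tuple[BodyPhenotype, BrainPhenotype]:
    """A +x joint and a -y joint, both saturated: the 45-degree compromise.

    This organism attains positive speed toward right and down
    simultaneously — the structural premise of the right-down pair.
    """
    body = _body_with_joints([0, 3])
    return body, _manual_brain(body, SATURATING_WEIGHT, SATURATING_WEIGHT)


def oscillating_organism() -> tuple[BodyPhenotype, BrainPhenotype]:
    """One joint driven by an antisymmetric oscillator: zero-mean wobble."""
    body = _body_with_joints([0])
    return body, _manual_brain(body, -OSCILLATING_WEIGHT, OSCILLATING_WEIGHT)


def _empty_brain_cppn(weight: float = 0.0) -> CPPNGenome:
    nodes = [NodeGene(i, "input", "identity") for i in range(BRAIN_INPUT_ARITY)]
    nodes += [
        NodeGene(BRAIN_INPUT_ARITY + j, "output", "identity")
        for j in range(BRAIN_OUTPUT_ARITY)
    ]
    bias = BRAIN_INPUT_ARITY - 1
    conns = [
        ConnGene(bias, BRAIN_INPUT_ARITY + j, weight, True)
        for j in range(BRAIN_OUTPUT_ARITY)
    ]
    return CPPNGenome(tuple(nodes), tuple(conns), BRAIN_INPUT_ARITY, BRAIN_OUTPUT_ARITY)


def s_switched_genotype(dev_seed: int = 7) -> OrganismGenotype:
    """Fully plastic genotype whose body flips between conditions.

    The brick-score output reads ``1 - 10 * S``: with S=+1 every slot
    scores negative and the body stays a bare core; with S=-1 brick wins
    everywhere and the body fills its module budget.  Demonstrates that
    the regulation input is functional end to end.
    """
    nodes = [NodeGene(i, "input", "identity") for i in range(BODY_INPUT_ARITY)]
    nodes += [
        NodeGene(BODY_INPUT_ARITY + j, "output", "identity")
        for j in range(BODY_OUTPUT_ARITY)
    ]
    s_input, bias = 3, 4
    brick_out = BODY_INPUT_ARITY + 1
    conns = (
        ConnGene(bias, brick_out, 1.0, True),
        ConnGene(s_input, brick_out, -10.0, True),
    )
    body = CPPNGenome(tuple(nodes), conns, BODY_INPUT_ARITY, BODY_OUTPUT_ARITY)
    return OrganismGenotype(
        body_cppn=body,
        brain_cppn=_empty_brain_cppn(),
        dev_seed=dev_seed,
        plasticity_mode=PlasticityMode.FULLY_PLASTIC,
    )


def right_thruster_genotype(dev_seed: int = 11,
                            plasticity_mode: PlasticityMode = PlasticityMode.NON_PLASTIC
                            ) -> OrganismGenotype:
    """Genotype developing into a chain of +x joints with saturating motors.

    The joint-0 score reads ``-10 * slot - 9``, positive only for the +x
    slot direction (scaled to -1), so development grows a straight line
    of right-pointing joints; the brain CPPN gives every oscillator the
    same-sign weight pair, so all motors saturate at +1.
    """
    nodes = [NodeGene(i, "input", "identity") for i in range(BODY_INPUT_ARITY)]
    nodes += [
        NodeGene(BODY_INPUT_ARITY + j, "output", "identity")
        for j in range(BODY_OUTPUT_ARITY)
    ]
    slot_input, bias = 2, 4
    joint0_out = BODY_INPUT_ARITY + 2
    conns = (
        ConnGene(slot_input, joint0_out, -10.0, True),
        ConnGene(bias, joint0_out, -9.0, True),
    )
    body = CPPNGenome(tuple(nodes), conns, BODY_INPUT_ARITY, BODY_OUTPUT_ARITY)
    raw = math.atanh(SATURATING_WEIGHT)
    return OrganismGenotype(
        body_cppn=body,
        brain_cppn=_empty_brain_cppn(weight=raw),
        dev_seed=dev_seed,
        plasticity_mode=plasticity_mode,
    )
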