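"""Seeded development of a modular body from the body CPPN.

Bodies are rooted ordered trees of modules embedded in a 2-D integer
grid: one core at the origin, structural bricks, and servo-motor joints
(rotation 0 or 90 degrees).  Core and bricks expose four lateral child
slots; a joint exposes only the slot opposite its attachment, so joints
continue in a straight line.  Development expands a breadth-first
frontier from the core, querying the body CPPN once per free slot; the
inherited development seed shuffles the frontier each round so that
which slot hits the module budget is a heritable, genotype-level
property rather than an artefact of iteration order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cppn import EnvironmentSignal, OrganismGenotype, PlasticityMode

#: slot/direction index 0..3 -> grid step (+x right, +y up; "down" is -y)
DIRECTIONS = ((1, 0), (0, 1), (-1, 0), (0, -1))
#: slot direction index scaled into [-1, 1] for CPPN queries
SLOT_SCALE = (-1.0, -1.0 / 3.0, 1.0 / 3.0, 1.0)

#: body CPPN output channels
MODULE_CHOICES = ("empty", "brick", "joint0", "joint90")

DEFAULT_MAX_MODULES = 10


@dataclass
class Module:
    kind: str  # "core" | "brick" | "joint"
    rotation: int  # 0 | 90 (joints only; 0 otherwise)
    grid_pos: tuple[int, int]
    parent_slot: int | None  # absolute direction index from the parent, None at root
    children: dict[int, "Module"] = field(default_factory=dict)


@dataclass
class BodyPhenotype:
    root: Module
    occupancy: dict[tuple[int, int], Module]
    max_modules: int

    @property
    def modules(self) -> list[Module]:
        out: list[Module] = []
        stack = [self.root]
        while stack:
            m = stack.pop()
            out.append(m)
            for slot in sorted(m.children, reverse=True):
                stack.append(m.children[slot])
        return out

    def joint_modules(self) -> list[Module]:
        """Joints in a canonical order (sorted by grid position)."""
        return sorted(
            (m for m in self.modules if m.kind == "joint"),
            key=lambda m: m.grid_pos,
        )


def _child_slots(kind: str, attach_dir: int) -> tuple[int, ...]:
    if kind == "joint":
        # two lateral, opposite slots; one is taken by the parent
        return (attach_dir,)
    return tuple(d for d in range(4) if d != (attach_dir + 2) % 4)


def develop_body(genotype: OrganismGenotype, signal: int,
                 max_modules: int = DEFAULT_MAX_MODULES) -> BodyPhenotype:
    """Deterministically grow a body for one environment condition.

    The signal reaches the body CPPN only in the fully plastic mode; in
    the other modes it is clamped to 0 so that both conditions develop
    bit-identical bodies.
    """
    signal = EnvironmentSignal(int(signal))
    if genotype.plasticity_mode is PlasticityMode.FULLY_PLASTIC:
        s = float(signal)
    else:
        s = 0.0
    rng = np.random.default_rng(genotype.dev_seed)
    body_cppn = genotype.body_cppn

    core = Module("core", 0, (0, 0), None)
    occupancy: dict[tuple[int, int], Module] = {(0, 0): core}
    frontier: list[tuple[Module, int]] = [(core, d) for d in range(4)]

    while frontier and len(occupancy) < max_modules:
        order = rng.permutation(len(frontier))
        next_frontier: list[tuple[Module, int]] = []
        for idx in order:
            if len(occupancy) >= max_modules:
                break
            parent, d = frontier[idx]
            px, py = parent.grid_pos
            dx, dy = DIRECTIONS[d]
            target = (px + dx, py + dy)
            if target in occupancy:
                continue
            scores = body_cppn.query(
                [float(target[0]), float(target[1]), SLOT_SCALE[d], s, 1.0]
            )
            choice = max(range(len(scores)), key=scores.__getitem__)
            if MODULE_CHOICES[choice] == "empty":
                continue
            if MODULE_CHOICES[choice] == "brick":
                kind, rotation = "brick", 0
            else:
                kind, rotation = "joint", 0 if MODULE_CHOICES[choice] == "joint0" else 90
            child = Module(kind, rotation, target, d)
            parent.children[d] = child
            occupancy[target] = child
            next_frontier.extend((child, cd) for cd in _child_slots(kind, d))
        frontier = next_frontier

    return BodyPhenotype(core, occupancy, max_modules)


@dataclass(frozen=True)
class TreeNode:
    """Ordered labelled tree node (adapter for edit-distance and traits)."""

    label: str
    children: tuple["TreeNode", ...] = ()


def _module_label(m: Module) -> str:
    if m.kind == "joint":
        return f"joint{m.rotation}"
    return m.kind


def module_tree(body: BodyPhenotype) -> TreeNode:
    """Lossless ordered labelled tree of the body (children by slot index)."""

    def rec(m: Module) -> TreeNode:
        kids = tuple(rec(m.children[slot]) for slot in sorted(m.children))
        return TreeNode(_module_label(m), kids)

    return rec(body.root)


def tree_size(node: TreeNode) -> int:
    return 1 + sum(tree_size(c) for c in node.children)


# -- serialization --------------------------------------------------------


def body_to_dict(body: BodyPhenotype) -> dict:
    def rec(m: Module) -> dict:
        return {
            "kind": m.kind,
            "rotation": m.rotation,
            "grid_pos": list(m.grid_pos),
            "parent_slot": m.parent_slot,
            "children": [rec(m.children[slot]) for slot in sorted(m.children)],
        }

    return {"max_modules": body.max_modules, "root": rec(body.root)}


def body_from_dict(d: dict) -> BodyPhenotype:
    occupancy: dict[tuple[int, int], Module] = {}

    def rec(nd: dict) -> Module:
        m = Module(
            nd["kind"], nd["rotation"], tuple(nd["grid_pos"]), nd["parent_slot"]
        )
        occupancy[m.grid_pos] = m
        for child in nd["children"]:
            cm = rec(child)
            m.children[cm.parent_slot] = cm
        return m

    root = rec(d["root"])
    return BodyPhenotype(root, occupancy, d["max_modules"])


def occupancy_table(body: BodyPhenotype) -> pd.DataFrame:
    """Grid occupancy as a table (for CSV dumps and plotting)."""
    rows = [
        {"x": pos[0], "y": pos[1], "kind": m.kind, "rotation": m.rotation}
        for pos, m in sorted(body.occupancy.items())
    ]
    return pd.DataFrame(rows, columns=["x", "y", "kind", "rotation"])
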