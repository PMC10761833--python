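"""Compositional pattern-producing network (CPPN) genomes.

A CPPN is a small feed-forward graph of heterogeneous activation
functions.  Queried over a spatial context (grid coordinates, the
environment signal ``S`` and a bias), it generates the body plan and the
controller weights of a modular organism.  Because one network answers
every query, genes are shared across phenotypic traits — which is what
lets pleiotropy and epistasis (and hence genetic costs of plasticity)
arise in this system.

An organism genotype bundles two CPPNs (body and brain), an inherited
development seed, and the plasticity mode of its experiment.  The seed
is drawn once in the initial population and never mutated: mutating it
would destroy genotype–phenotype locality.
"""

from __future__ import annotations

import enum
import json
import math
from dataclasses import dataclass, field, replace

import numpy as np

FORMAT_VERSION = 1

#: body queries: (x, y, slot direction, S, bias)
BODY_INPUT_ARITY = 5
#: body outputs: scores for (empty, brick, joint-0, joint-90)
BODY_OUTPUT_ARITY = 4
#: brain queries: (x_joint, y_joint, x_other, y_other, S, bias)
BRAIN_INPUT_ARITY = 6
#: brain outputs: raw values for w_xy and for w_yx / neighbour weight
BRAIN_OUTPUT_ARITY = 2

#: index of the environment-signal input in both query schemes
BODY_SIGNAL_INDEX = 3
BRAIN_SIGNAL_INDEX = 4


class PlasticityMode(str, enum.Enum):
    """Which phenotypic components may respond to the environment signal."""

    FULLY_PLASTIC = "fully_plastic"
    BRAIN_PLASTIC = "brain_plastic"
    NON_PLASTIC = "non_plastic"


class EnvironmentSignal(enum.IntEnum):
    """State broadcast by the central system: +1 asks for behaviour A, -1 for B."""

    BEHAVIOR_A = 1
    BEHAVIOR_B = -1


def _sigmoid(v: float) -> float:
    return 1.0 / (1.0 + math.exp(-max(-60.0, min(60.0, v))))


def _gauss(v: float) -> float:
    return math.exp(-min(60.0, v * v))


ACTIVATIONS = {
    "identity": lambda v: v,
    "sigmoid": _sigmoid,
    "sine": math.sin,
    "gauss": _gauss,
    "abs": abs,
}

ACTIVATION_NAMES = tuple(sorted(ACTIVATIONS))


@dataclass(frozen=True)
class NodeGene:
    id: int
    role: str  # "input" | "hidden" | "output"
    activation: str


@dataclass(frozen=True)
class ConnGene:
    source: int
    target: int
    weight: float
    enabled: bool = True


@dataclass
class CPPNGenome:
    """Feed-forward graph of activation nodes with weighted connections."""

    nodes: tuple[NodeGene, ...]
    connections: tuple[ConnGene, ...]
    input_arity: int
    output_arity: int
    _plan: tuple | None = field(default=None, compare=False, repr=False)

    def __post_init__(self) -> None:
        self.nodes = tuple(self.nodes)
        self.connections = tuple(self.connections)

    # -- evaluation -------------------------------------------------------

    def _build_plan(self):
        index = {n.id: i for i, n in enumerate(self.nodes)}
        if len(index) != len(self.nodes):
            raise ValueError("duplicate node ids")
        n = len(self.nodes)
        incoming: list[list[tuple[int, float]]] = [[] for _ in range(n)]
        indeg = [0] * n
        out_edges: list[list[int]] = [[] for _ in range(n)]
        for c in self.connections:
            if c.source not in index or c.target not in index:
                raise ValueError(f"connection references unknown node: {c}")
            if not math.isfinite(c.weight):
                raise ValueError(f"non-finite connection weight: {c}")
            if not c.enabled:
                continue
            s, t = index[c.source], index[c.target]
            if self.nodes[t].role == "input":
                raise ValueError("input node has incoming enabled connection")
            incoming[t].append((s, c.weight))
            indeg[t] += 1
            out_edges[s].append(t)
        # Kahn topological order over enabled connections
        queue = [i for i in range(n) if indeg[i] == 0]
        order: list[int] = []
        while queue:
            i = queue.pop()
            order.append(i)
            for t in out_edges[i]:
                indeg[t] -= 1
                if indeg[t] == 0:
                    queue.append(t)
        if len(order) != n:
            raise ValueError("cycle among enabled connections")
        inputs = [i for i, nd in enumerate(self.nodes) if nd.role == "input"]
        outputs = [i for i, nd in enumerate(self.nodes) if nd.role == "output"]
        if len(inputs) != self.input_arity:
            raise ValueError("input node count does not match input_arity")
        if len(outputs) != self.output_arity:
            raise ValueError("output node count does not match output_arity")
        steps = [
            (i, ACTIVATIONS[self.nodes[i].activation], tuple(incoming[i]))
            for i in order
            if self.nodes[i].role != "input"
        ]
        return tuple(inputs), tuple(outputs), tuple(steps), n

    @property
    def plan(self):
        if self._plan is None:
            self._plan = self._build_plan()
        return self._plan

    def query(self, inputs) -> list[float]:
        """Evaluate the network on one context vector, in topological order."""
        in_idx, out_idx, steps, n = self.plan
        if len(inputs) != self.input_arity:
            raise ValueError(
                f"expected {self.input_arity} inputs, got {len(inputs)}"
            )
        values = [0.0] * n
        for pos, v in zip(in_idx, inputs):
            v = float(v)
            if not math.isfinite(v):
                raise ValueError("non-finite CPPN input")
            values[pos] = v
        for pos, act, inc in steps:
            total = 0.0
            for src, w in inc:
                total += w * values[src]
            values[pos] = act(total)
        return [values[i] for i in out_idx]


def query(cppn: CPPNGenome, inputs) -> list[float]:
    """Module-level alias for :meth:`CPPNGenome.query`."""
    return cppn.query(inputs)


@dataclass(frozen=True)
class OrganismGenotype:
    """Body CPPN + brain CPPN + inherited development seed + plasticity mode."""

    body_cppn: CPPNGenome
    brain_cppn: CPPNGenome
    dev_seed: int
    plasticity_mode: PlasticityMode


@dataclass(frozen=True)
class MutationRates:
    """Per-offspring mutation configuration (probabilities and scales)."""

    weight_prob: float = 0.8
    weight_sigma: float = 0.5
    add_connection_prob: float = 0.2
    add_node_prob: float = 0.1
    activation_prob: float = 0.1


def _reaches(connections, start: int, goal: int) -> bool:
    """Directed reachability over *all* connections (enabled or not)."""
    if start == goal:
        return True
    adj: dict[int, list[int]] = {}
    for c in connections:
        adj.setdefault(c.source, []).append(c.target)
    stack, seen = [start], {start}
    while stack:
        node = stack.pop()
        for nxt in adj.get(node, ()):
            if nxt == goal:
                return True
            if nxt not in seen:
                seen.add(nxt)
                stack.append(nxt)
    return False


def mutate_cppn(cppn: CPPNGenome, rng: np.random.Generator,
                rates: MutationRates) -> CPPNGenome:
    nodes = list(cppn.nodes)
    conns = list(cppn.connections)

    for i, c in enumerate(conns):
        if c.enabled and rng.random() < rates.weight_prob:
            conns[i] = replace(
                c, weight=c.weight + rates.weight_sigma * float(rng.standard_normal())
            )

    if rng.random() < rates.add_connection_prob:
        existing = {(c.source, c.target) for c in conns}
        candidates = []
        for s in nodes:
            if s.role == "output":
                continue
            for t in nodes:
                if t.role == "input" or s.id == t.id:
                    continue
                if (s.id, t.id) in existing:
                    continue
                # reject edges that would close a cycle (checked over all
                # connections so re-enabling can never break feed-forwardness)
                if _reaches(conns, t.id, s.id):
                    continue
                candidates.append((s.id, t.id))
        if candidates:
            s_id, t_id = candidates[int(rng.integers(len(candidates)))]
            conns.append(ConnGene(s_id, t_id, float(rng.uniform(-1.0, 1.0)), True))

    if rng.random() < rates.add_node_prob:
        enabled = [i for i, c in enumerate(conns) if c.enabled]
        if enabled:
            i = enabled[int(rng.integers(len(enabled)))]
            old = conns[i]
            new_id = max(n.id for n in nodes) + 1
            act = ACTIVATION_NAMES[int(rng.integers(len(ACTIVATION_NAMES)))]
            conns[i] = replace(old, enabled=False)
            nodes.append(NodeGene(new_id, "hidden", act))
            conns.append(ConnGene(old.source, new_id, 1.0, True))
            conns.append(ConnGene(new_id, old.target, old.weight, True))

    if rng.random() < rates.activation_prob:
        hidden = [i for i, n in enumerate(nodes) if n.role == "hidden"]
        if hidden:
            j = hidden[int(rng.integers(len(hidden)))]
            act = ACTIVATION_NAMES[int(rng.integers(len(ACTIVATION_NAMES)))]
            nodes[j] = replace(nodes[j], activation=act)

    return CPPNGenome(tuple(nodes), tuple(conns), cppn.input_arity, cppn.output_arity)


def mutate(genotype: OrganismGenotype, rng: np.random.Generator,
           rates: MutationRates | None = None) -> OrganismGenotype:
    """Asexual replication with mutation; the development seed is copied verbatim."""
    rates = rates or MutationRates()
    return OrganismGenotype(
        body_cppn=mutate_cppn(genotype.body_cppn, rng, rates),
        brain_cppn=mutate_cppn(genotype.brain_cppn, rng, rates),
        dev_seed=genotype.dev_seed,
        plasticity_mode=genotype.plasticity_mode,
    )


def make_initial_cppn(rng: np.random.Generator, input_arity: int,
                      output_arity: int) -> CPPNGenome:
    """Minimal-structure start: inputs fully connected to outputs, no hidden nodes."""
    nodes = [NodeGene(i, "input", "identity") for i in range(input_arity)]
    nodes += [
        NodeGene(input_arity + j, "output", "identity") for j in range(output_arity)
    ]
    conns = [
        ConnGene(i, input_arity + j, float(rng.uniform(-1.0, 1.0)), True)
        for i in range(input_arity)
        for j in range(output_arity)
    ]
    return CPPNGenome(tuple(nodes), tuple(conns), input_arity, output_arity)


def make_initial_genotype(rng: np.random.Generator,
                          plasticity_mode: PlasticityMode | str) -> OrganismGenotype:
    mode = PlasticityMode(plasticity_mode)
    body = make_initial_cppn(rng, BODY_INPUT_ARITY, BODY_OUTPUT_ARITY)
    brain = make_initial_cppn(rng, BRAIN_INPUT_ARITY, BRAIN_OUTPUT_ARITY)
    dev_seed = int(rng.integers(0, 2**31))
    return OrganismGenotype(body, brain, dev_seed, mode)


def signal_connected(cppn: CPPNGenome, signal_index: int) -> bool:
    """True if an enabled path links the S input node to any output node."""
    in_idx, out_idx, _, _ = cppn.plan
    start_id = cppn.nodes[in_idx[signal_index]].id
    output_ids = {cppn.nodes[i].id for i in out_idx}
    adj: dict[int, list[int]] = {}
    for c in cppn.connections:
        if c.enabled:
            adj.setdefault(c.source, []).append(c.target)
    stack, seen = [start_id], {start_id}
    while stack:
        node = stack.pop()
        for nxt in adj.get(node, ()):
            if nxt in output_ids:
                return True
            if nxt not in seen:
                seen.add(nxt)
                stack.append(nxt)
    return False


# -- serialization --------------------------------------------------------


def cppn_to_dict(cppn: CPPNGenome) -> dict:
    return {
        "nodes": [
            {"id": n.id, "role": n.role, "activation": n.activation}
            for n in cppn.nodes
        ],
        "connections": [
            {
                "source": c.source,
                "target": c.target,
                "weight": c.weight,
                "enabled": c.enabled,
            }
            for c in cppn.connections
        ],
        "input_arity": cppn.input_arity,
        "output_arity": cppn.output_arity,
    }


def cppn_from_dict(d: dict) -> CPPNGenome:
    nodes = tuple(NodeGene(n["id"], n["role"], n["activation"]) for n in d["nodes"])
    conns = tuple(
        ConnGene(c["source"], c["target"], c["weight"], c["enabled"])
        for c in d["connections"]
    )
    return CPPNGenome(nodes, conns, d["input_arity"], d["output_arity"])


def genotype_to_dict(genotype: OrganismGenotype) -> dict:
    return {
        "format_version": FORMAT_VERSION,
        "body_cppn": cppn_to_dict(genotype.body_cppn),
        "brain_cppn": cppn_to_dict(genotype.brain_cppn),
        "dev_seed": genotype.dev_seed,
        "plasticity_mode": genotype.plasticity_mode.value,
    }


def genotype_from_dict(d: dict) -> OrganismGenotype:
    if d.get("format_version") != FORMAT_VERSION:
        raise ValueError(f"unsupported genome format version: {d.get('format_version')}")
    return OrganismGenotype(
        body_cppn=cppn_from_dict(d["body_cppn"]),
        brain_cppn=cppn_from_dict(d["brain_cppn"]),
        dev_seed=d["dev_seed"],
        plasticity_mode=PlasticityMode(d["plasticity_mode"]),
    )


def genotype_to_json(genotype: OrganismGenotype) -> str:
    return json.dumps(genotype_to_dict(genotype), indent=1)


def genotype_from_json(text: str) -> OrganismGenotype:
    return genotype_from_dict(json.loads(text))
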