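"""Overlapping-generations evolutionary search over organism genotypes.

Each generation, lambda offspring are produced from binary-tournament
parents by replication and mutation; fitness is recomputed over the
pooled mu parents plus lambda offspring (dominance counts are
population-relative) and mu survivors are drawn by repeated binary
tournaments without re-selection.  In the two-condition setups an
individual's fitness is the number of pool members it Pareto-dominates
on (speed A, speed B); in the focal environment it is the raw speed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field, fields, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import analysis
from .cppn import (
    MutationRates,
    OrganismGenotype,
    PlasticityMode,
    genotype_to_dict,
    make_initial_genotype,
    mutate,
)
from .locomotion import (
    DIRECTION_PAIRS,
    RIGHT,
    simulate,
    speed_in_direction,
    total_displacement,
)
from .morphogenesis import develop_body, module_tree
from .neurogenesis import develop_brain

logger = logging.getLogger(__name__)

PAIRS = tuple(DIRECTION_PAIRS) + ("focal",)


@dataclass(frozen=True)
class ExperimentConfig:
    """One experiment: a directions pair, a plasticity mode, EA parameters."""

    mu: int = 100
    lam: int = 100
    generations: int = 150
    pair: str = "right_left"  # "right_left" | "right_down" | "focal"
    plasticity_mode: str = "fully_plastic"
    repetitions: int = 20
    steps_per_condition: int = 300  # 30 s at one 0.1 s control tick
    dt: float = 0.1
    gain: float = 1.0  # top speed c, cm/s
    max_modules: int = 10
    mutation: MutationRates = field(default_factory=MutationRates)
    novelty_k: int = analysis.DEFAULT_NOVELTY_K
    archive_prob: float = analysis.DEFAULT_ARCHIVE_PROB
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mu < 2 or self.lam < 2:
            raise ValueError("mu and lam must be >= 2")
        if self.pair not in PAIRS:
            raise ValueError(f"unknown pair {self.pair!r}; choose from {PAIRS}")
        PlasticityMode(self.plasticity_mode)

    @property
    def condition_duration_s(self) -> float:
        return self.steps_per_condition * self.dt

    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        d = dict(d)
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "mutation" in d and isinstance(d["mutation"], dict):
            d["mutation"] = MutationRates(**d["mutation"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValueError("config YAML must be a mapping")
        return cls.from_dict(data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


def desk_preset(**overrides) -> ExperimentConfig:
    """Scaled-down preset: the full suite completes on one desktop CPU core."""
    base = dict(mu=32, lam=32, generations=40, repetitions=10)
    base.update(overrides)
    return ExperimentConfig(**base)


def paper_preset(**overrides) -> ExperimentConfig:
    """Full-scale study conditions (mu = lambda = 100, 150 generations, 20 reps)."""
    base = dict(mu=100, lam=100, generations=150, repetitions=20)
    base.update(overrides)
    return ExperimentConfig(**base)


PRESETS = {"desk": desk_preset, "paper": paper_preset}


@dataclass
class Individual:
    id: int
    parent_id: int | None
    genotype: OrganismGenotype
    speeds: tuple[float, ...] = ()
    fitness: float = 0.0
    traits: np.ndarray | None = None
    body_change: float = 0.0
    brain_change: float = float("nan")
    displacement: float = 0.0
    behavior: tuple[float, ...] = ()
    generation_born: int = 0


def evaluate(genotype: OrganismGenotype, config: ExperimentConfig) -> dict:
    """Develop, simulate and measure one organism under the experiment protocol.

    Two-condition setups develop and simulate the organism once per
    condition (signal +1 then -1, position reset in between); the focal
    setup runs a single 30 s condition of locomoting right.  Development
    is deterministic, so phenotypes known to coincide across conditions
    (gated components) are built once and reused.
    """
    steps = config.steps_per_condition
    mode = PlasticityMode(genotype.plasticity_mode)

    if config.pair == "focal":
        body = develop_body(genotype, +1, config.max_modules)
        brain = develop_brain(genotype, body, +1)
        record = simulate(body, brain, steps, gain=config.gain, dt=config.dt)
        speed = speed_in_direction(record, RIGHT)
        end = record.endpoint
        traits = analysis.body_traits(body).as_array()
        return {
            "speeds": (speed,),
            "traits": traits,
            "body_change": 0.0,
            "brain_change": 0.0,
            "displacement": float(abs(end[0]) + abs(end[1])),
            "behavior": (float(end[0]), float(end[1]), float(end[0]), float(end[1])),
        }

    dir_a, dir_b = DIRECTION_PAIRS[config.pair]
    body_a = develop_body(genotype, +1, config.max_modules)
    if mode is PlasticityMode.FULLY_PLASTIC:
        body_b = develop_body(genotype, -1, config.max_modules)
    else:
        body_b = body_a
    brain_a = develop_brain(genotype, body_a, +1)
    if mode is PlasticityMode.NON_PLASTIC:
        brain_b = brain_a
    else:
        brain_b = develop_brain(genotype, body_b, -1)

    record_a = simulate(body_a, brain_a, steps, gain=config.gain, dt=config.dt,
                        condition="A")
    if body_b is body_a and brain_b is brain_a:
        record_b = replace(record_a, condition="B")
    else:
        record_b = simulate(body_b, brain_b, steps, gain=config.gain, dt=config.dt,
                            condition="B")

    speed_a = speed_in_direction(record_a, dir_a)
    speed_b = speed_in_direction(record_b, dir_b)

    if body_b is body_a:
        body_change = 0.0
        traits = analysis.body_traits(body_a).as_array()
    else:
        body_change = float(
            analysis.tree_edit_distance(module_tree(body_a), module_tree(body_b))
        )
        traits = 0.5 * (
            analysis.body_traits(body_a).as_array()
            + analysis.body_traits(body_b).as_array()
        )
    try:
        b_change = analysis.brain_change(brain_a, brain_b)
    except ValueError:
        b_change = float("nan")  # undefined when the bodies differ

    end_a, end_b = record_a.endpoint, record_b.endpoint
    return {
        "speeds": (speed_a, speed_b),
        "traits": traits,
        "body_change": body_change,
        "brain_change": b_change,
        "displacement": total_displacement(record_a, record_b),
        "behavior": (float(end_a[0]), float(end_a[1]), float(end_b[0]), float(end_b[1])),
    }


def pareto_fitness(speeds) -> list[int]:
    """Dominance counts: i dominates j iff >= on both speeds, > on at least one."""
    arr = np.asarray([tuple(s) for s in speeds], dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("pareto_fitness requires (speed_A, speed_B) pairs")
    if np.isnan(arr).any():
        raise ValueError("missing speeds")
    ge = (arr[:, None, :] >= arr[None, :, :]).all(axis=-1)
    gt = (arr[:, None, :] > arr[None, :, :]).any(axis=-1)
    dominates = ge & gt
    return [int(c) for c in dominates.sum(axis=1)]


def binary_tournament(population: list[Individual],
                      rng: np.random.Generator) -> Individual:
    """Uniformly draw two distinct individuals; the fitter wins, ties at random."""
    if len(population) < 2:
        raise ValueError("population must have at least 2 individuals")
    i, j = rng.choice(len(population), size=2, replace=False)
    a, b = population[int(i)], population[int(j)]
    if a.fitness > b.fitness:
        return a
    if b.fitness > a.fitness:
        return b
    return a if rng.random() < 0.5 else b


def _survivor_selection(pool: list[Individual], mu: int,
                        rng: np.random.Generator) -> list[Individual]:
    """Repeated binary tournaments without re-selection of the same individual."""
    candidates = list(pool)
    survivors: list[Individual] = []
    while len(survivors) < mu:
        winner = binary_tournament(candidates, rng)
        candidates.remove(winner)
        survivors.append(winner)
    return survivors


def _assign_objective_fitness(pool: list[Individual],
                              rng: np.random.Generator) -> None:
    if len(pool[0].speeds) == 1:
        for ind in pool:
            ind.fitness = float(ind.speeds[0])
    else:
        counts = pareto_fitness([ind.speeds for ind in pool])
        for ind, c in zip(pool, counts):
            ind.fitness = float(c)


@dataclass
class EvolutionHistory:
    """Per-generation population snapshots plus every evaluated organism."""

    config: ExperimentConfig
    snapshots: list[list[Individual]] = field(default_factory=list)
    all_individuals: list[Individual] = field(default_factory=list)

    def _rows(self, generation: int, individuals) -> list[dict]:
        rows = []
        focal = self.config.pair == "focal"
        for ind in individuals:
            row = {
                "generation": generation,
                "id": ind.id,
                "parent_id": -1 if ind.parent_id is None else ind.parent_id,
                "speed_a": ind.speeds[0],
                "speed_b": ind.speeds[0] if focal else ind.speeds[1],
                "fitness": ind.fitness,
                "body_change": ind.body_change,
                "brain_change": ind.brain_change,
                "displacement": ind.displacement,
            }
            for name, value in zip(analysis.TRAIT_NAMES, ind.traits):
                row[name] = float(value)
            for name, value in zip(("end_ax", "end_ay", "end_bx", "end_by"),
                                   ind.behavior):
                row[name] = value
            rows.append(row)
        return rows

    def to_dataframe(self) -> pd.DataFrame:
        rows: list[dict] = []
        for generation, snapshot in enumerate(self.snapshots):
            rows.extend(self._rows(generation, snapshot))
        return pd.DataFrame(rows)

    def evaluated_organisms(self) -> pd.DataFrame:
        """One row per evaluated organism (offspring included even if not selected)."""
        rows = []
        for ind in self.all_individuals:
            row = {"generation": ind.generation_born, "id": ind.id,
                   "speed_a": ind.speeds[0],
                   "speed_b": ind.speeds[0] if self.config.pair == "focal"
                   else ind.speeds[1]}
            for name, value in zip(analysis.TRAIT_NAMES, ind.traits):
                row[name] = float(value)
            for name, value in zip(("end_ax", "end_ay", "end_bx", "end_by"),
                                   ind.behavior):
                row[name] = value
            rows.append(row)
        return pd.DataFrame(rows)

    def final_population(self) -> list[Individual]:
        return self.snapshots[-1]

    def save(self, out_dir) -> None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        self.to_dataframe().to_csv(out_dir / "history.csv", index=False)
        final = [
            {"id": ind.id, "fitness": ind.fitness,
             "genotype": genotype_to_dict(ind.genotype)}
            for ind in self.final_population()
        ]
        with open(out_dir / "population_final.json", "w") as fh:
            json.dump(final, fh, indent=1)
        self.config.to_yaml(out_dir / "config.yaml")


def run_ea(config: ExperimentConfig, rng: np.random.Generator | int,
           assign_fitness=None, on_offspring=None,
           keep_all: bool = False) -> EvolutionHistory:
    """Generic overlapping-generations loop shared by objective and novelty search."""
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    if assign_fitness is None:
        assign_fitness = _assign_objective_fitness

    mode = (PlasticityMode.NON_PLASTIC if config.pair == "focal"
            else PlasticityMode(config.plasticity_mode))
    history = EvolutionHistory(config=config)
    next_id = 0

    def new_individual(genotype, parent_id, generation):
        nonlocal next_id
        ind = Individual(id=next_id, parent_id=parent_id, genotype=genotype,
                         generation_born=generation)
        next_id += 1
        measures = evaluate(genotype, config)
        ind.speeds = measures["speeds"]
        ind.traits = measures["traits"]
        ind.body_change = measures["body_change"]
        ind.brain_change = measures["brain_change"]
        ind.displacement = measures["displacement"]
        ind.behavior = measures["behavior"]
        if keep_all:
            history.all_individuals.append(ind)
        return ind

    population = [
        new_individual(make_initial_genotype(rng, mode), None, 0)
        for _ in range(config.mu)
    ]
    assign_fitness(population, rng)
    history.snapshots.append(list(population))

    for generation in range(1, config.generations + 1):
        offspring = []
        for _ in range(config.lam):
            parent = binary_tournament(population, rng)
            child_genotype = mutate(parent.genotype, rng, config.mutation)
            child = new_individual(child_genotype, parent.id, generation)
            if on_offspring is not None:
                on_offspring(child, rng)
            offspring.append(child)
        pool = population + offspring
        assign_fitness(pool, rng)
        population = _survivor_selection(pool, config.mu, rng)
        history.snapshots.append(list(population))
        if generation % 10 == 0 or generation == config.generations:
            mean_fit = float(np.mean([ind.fitness for ind in population]))
            logger.info("%s/%s gen %d mean fitness %.3f", config.pair,
                        config.plasticity_mode, generation, mean_fit)
    return history


def evolve(config: ExperimentConfig,
           rng: np.random.Generator | int | None = None) -> EvolutionHistory:
    """Run one experiment with the objective (speed / dominance-count) fitness."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    return run_ea(config, rng)
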