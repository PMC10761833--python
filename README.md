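# plastevo

Digital experimental evolution of **environmentally regulated phenotypic
plasticity** in modular organisms, built to study the *genetic costs* of
plasticity: the fitness deficits that arise when the genes regulating
plastic responses are pleiotropically and epistatically entangled with
the genes encoding traits.

It is aimed at artificial-life / evolutionary-robotics researchers who
want a self-contained, deterministic, desk-scale system in which those
costs can be measured — no physics engine required.

## The system

Organisms are modular robots on a 2-D grid: a core, structural bricks,
and servo joints (rotation 0° or 90°), each joint driven by a
differential oscillator

    dx_i/dt = w_yx · y_i(t−1),   dy_i/dt = w_xy · x_i(t−1),
    m_i(t) = clip(y_i(t), −1, 1)

with recurrent coupling between grid-adjacent oscillators.  Both the
body plan and all controller weights are generated by CPPNs
(compositional pattern-producing networks) queried over grid
coordinates, a bias, and an environment signal **S ∈ {+1, −1}** that
announces which of two behaviours is currently wanted.  Organisms live
60 s: locomote in direction A for 30 s, reset, locomote in direction B
for 30 s.  Plasticity regimes — *fully plastic* (body + brain respond
to S), *brain plastic*, and *non-plastic* (S clamped to 0) — are
compared on a mutually exclusive pair (**right–left**) and a partially
compatible pair (**right–down**), plus a *focal environment* baseline
that only ever locomotes right.

Search is a (μ + λ) overlapping-generations EA (μ = λ = 100, 150
generations, binary tournaments) whose consolidated fitness is the
number of Pareto-dominated individuals on the pair (speed A, speed B).
A deterministic 2-D locomotion surrogate replaces 3-D physics, so
absolute speeds are package units — only relational and qualitative
results carry over (see `docs/methods.md`).

The analysis layer provides the study's machinery: tree edit distance
between the two condition bodies ("body changes"), mean absolute weight
difference between the two condition brains ("brain changes"), bounded
morphological trait descriptors (size, joint proportion, limbs,
symmetry), novelty search over a behavioural descriptor, and PCA
fitness landscapes with a ruggedness (local-peak) score.

## Worked example

```python
from plastevo import desk_preset, evolve

cfg = desk_preset(pair="right_left", plasticity_mode="brain_plastic",
                  generations=20, mu=16, lam=16, seed=0)
df = evolve(cfg).to_dataframe()
final = df[df.generation == df.generation.max()]
print(f"speed toward right (condition A): {final.speed_a.mean():+.3f} cm/s")
print(f"speed toward left  (condition B): {final.speed_b.mean():+.3f} cm/s")
best = final.sort_values("fitness").iloc[-1]
print(f"best organism: speeds ({best.speed_a:+.2f}, {best.speed_b:+.2f}), "
      f"brain change {best.brain_change:.3f}")
```

prints

```
speed toward right (condition A): +0.410 cm/s
speed toward left  (condition B): +0.200 cm/s
best organism: speeds (+1.00, +0.50), brain change 1.323
```

Right and left are mutually exclusive — a fixed phenotype moving right
at +v moves left at −v — yet this brain-plastic population is positive
in *both* directions: the signal S has rewired the evolved controllers
between conditions (the best organism's brains differ by a mean
absolute weight change of 1.32).  A non-plastic run of the same
configuration stays pinned near 0.0 in both directions, since no
individual can ever Pareto-dominate another.

The same workflow is available from the shell:

```bash
plastevo suite --preset desk --seed 7 --out runs/desk
plastevo stats --suite-dir runs/desk --preset desk --seed 7 --out runs/desk
plastevo novelty --preset desk --seed 7 --pair right_down --out runs/nov
plastevo fixtures --out runs/fixtures
```

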