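# Methods

## The system in one paragraph

`plastevo` evolves digital modular organisms that must perform a pair of
locomotion behaviours during their lifetime: move in direction A for the
first 30 s, then (after a position reset) in direction B for the last
30 s.  Which behaviour is wanted is broadcast as an environment signal
S ∈ {+1, −1} that feeds into the organisms' genotypes, so a genotype can
express different phenotypes per condition — environmentally regulated
phenotypic plasticity of the reversible (acclimatisation) kind.  Three
regimes are compared: plasticity in body and brain, in the brain only,
or in neither, plus a baseline in which organisms evolve in a *focal
environment* with a single behaviour (locomote right).  Because the
environment signal is provided unconditionally and organisms pay no
energetic price for development, the only plasticity costs that can
arise are *genetic* costs: pleiotropic/epistatic entanglement between
the genes that regulate plasticity and the genes that encode traits.

## Genotype and development

A genotype is two compositional pattern-producing networks (CPPNs) —
one for the body, one for the brain — plus an inherited development
seed and the experiment's plasticity mode.  Both CPPNs are feed-forward
graphs over the activation repertoire {identity, sigmoid, sine,
gaussian, absolute value}; initial networks fully connect inputs to
outputs with weights ~ U(−1, 1) and no hidden nodes, and structure
grows by NEAT-style mutation (per-connection Gaussian weight
perturbation σ = 0.5 with probability 0.8; add-connection 0.2; add-node
0.1, splitting a connection into weight-1.0 and old-weight halves with
the original disabled; activation swap 0.1).  Reproduction is asexual;
the development seed is copied verbatim because mutating it would
destroy genotype–phenotype locality.

**Body.**  Development expands a breadth-first frontier from a core
module on a 2-D integer grid (+x right, +y up).  Each free slot queries
the body CPPN with (x, y, slot-direction index scaled to [−1, 1], S,
bias = 1); the argmax of four output scores selects empty / brick /
joint-0 / joint-90 (ties break to the lowest index; occupied target
cells are skipped).  Core and bricks expose four lateral slots, joints
only the slot opposite their attachment.  Growth stops at
`max_modules` (default 10) or an empty frontier.  The development seed
shuffles the frontier each round, so which slot hits the budget is a
heritable property.  The S input exists in every mode but is clamped to
0 for body queries except in the fully plastic mode, which guarantees
bit-identical bodies across conditions whenever body plasticity is off.

**Brain.**  One differential oscillator per joint.  The brain CPPN is
queried at (x_joint, y_joint, x_other, y_other, S, bias); for the
intra-oscillator weights the "other" coordinates repeat the joint's
own, and each ordered pair of grid-adjacent joints gets one neighbour
weight.  Raw outputs are squashed with tanh so every weight lies in
(−1, 1); tanh was chosen because the activation repertoire has no
primitive bounded to (−1, 1) and a smooth sign-preserving squash keeps
the weight's sign under the CPPN's control (which is what lets the
signal flip oscillator behaviour).  S is clamped to 0 for brain queries
in the non-plastic mode only.

## Controller dynamics

Each oscillator is a neuron pair (x, y) advanced per control tick by

    dx_i = w_yx_i · y_i(t−1) + Σ_j w_ij · x_j(t−1)   (j grid-adjacent)
    dy_i = w_xy_i · x_i(t−1)
    x_i(t) = x_i(t−1) + dx_i,   y_i(t) = y_i(t−1) + dy_i

i.e. the printed update equations taken literally with an implicit unit
step; one control tick represents 0.1 s, so a 30 s condition is 300
ticks (the tick length only rescales weight magnitudes).  The motor
command is y clipped to [−1, 1]; clipping never feeds back into the
state.  The neighbour term is a reconstruction — the source equations
are intra-oscillator only and state merely that neighbouring
oscillators connect recurrently; the minimal x→x coupling keeps one
CPPN output channel serving all inter-oscillator weights.  Internal
state magnitude is clamped at 10^6 with a logged warning (saturated
same-sign oscillators grow exponentially; the clamp only prevents
float overflow and cannot affect motor output, which saturates at 1).
All oscillators start at x = y = √2/2: the origin is a fixed point, so
a non-zero, symmetric, unit-energy start is used.

Two closed-form properties anchor the implementation and are asserted
in tests: with antisymmetric weights (w_xy = −w_yx = w) the pre-clip
energy x² + y² is multiplied by exactly (1 + w²) per step, and with
same-sign weights the motor output saturates to ±1 within a few steps
from the standard initial state.

## Locomotion surrogate

The 3-D physics simulation of the original system is out of scope; a
deterministic 2-D surrogate preserves the relational structure of the
problem instead.  Each joint thrusts along the unit vector of the slot
direction through which it attaches to its parent, rotated 90°
counter-clockwise when its rotation label is 90; per-tick velocity is

    v(t) = (c / max(1, J)) · Σ_j u_j · m_j(t)

with gain c = 1 cm/s by default.  Consequences, by construction: a
saturated joint chain moves at top speed c; zero-mean oscillation
yields negligible net displacement; right and left speeds of a single
trajectory are exact negations (the mutually exclusive pair is an
identity here); and an organism with a +x joint and a −y joint is
simultaneously positive toward right and down (the compatible pair's
premise).  Normalising by the joint count bounds top speed regardless
of body size so trait comparisons stay meaningful.  Absolute speeds are
*not* comparable to a physics engine; only relational and qualitative
results are interpreted.

## Evolutionary search

Overlapping generations: μ parents produce λ offspring (binary
tournaments, replication, mutation), fitness is recomputed over the
pooled μ + λ individuals, and μ survivors are drawn by repeated binary
tournaments *without re-selection* (winners leave the candidate pool,
guaranteeing μ distinct survivors; the original description does not
state the replacement scheme).  Fitness per direction is the speed
toward the due direction over one 30 s condition; the consolidated
fitness is the number of pooled individuals an organism
Pareto-dominates on (speed A, speed B).  The focal baseline uses raw
speed directly.  Evaluation is deterministic, so parents' speeds are
cached and each organism is evaluated once.

Full-scale study conditions (`paper` preset): μ = λ = 100, 150
generations, 20 repetitions per setup.  The scaled-down `desk` preset
(μ = λ = 32, 40 generations, 10 repetitions) keeps the full
seven-setup suite around four minutes on one CPU core and is the
problem size used by the packaged qualitative tests and the acceptance
script; it was chosen as the smallest scale at which the behavioural
contrasts between setups are statistically resolvable with rank-sum
tests.

## Analysis machinery

* **Body changes** — exact ordered-tree edit distance (Zhang–Shasha
  dynamic programming, unit insert/delete/relabel costs) between the
  module trees developed under the two conditions, children ordered by
  slot index.  Cross-checked in tests against an exhaustive forest-edit
  recursion and for metric axioms on random tree pairs.
* **Brain changes** — mean absolute difference of corresponding
  controller weights; defined only when the two brains share a
  topology (guaranteed when the bodies coincide, i.e. the brain-plastic
  regime), otherwise an error.
* **Trait descriptors**, all in [0, 1]: size = modules/max_modules;
  joints_prop = joints/modules; limbs = leaf modules/(modules − 1)
  (0 for a bare core) — a monotone bounded proxy for limb count;
  symmetry = the larger of the vertical- and horizontal-mirror overlap
  fractions of the occupied cells through the core.  The exact
  formulas of the descriptor family this emulates are not published in
  the available text; these reconstructions keep the intended
  qualitative meaning and bounds.
* **Novelty search** — the same overlapping-generations loop with
  selection on the mean Euclidean distance to the k = 15 nearest
  neighbours (pool plus archive) of a 4-D behaviour descriptor, the
  concatenated endpoints of both conditions; offspring enter the
  archive with probability 0.1.  Used to sample organism space
  agnostically for landscape construction.
* **Fitness landscape** — trait vectors standardised and projected onto
  the first two principal components (fitted on the pooled organisms of
  all compared methods so grids share a coordinate system;
  zero-variance trait dimensions are dropped with a warning), binned
  20×20, each cell holding the mean of (speed A + speed B)/2; empty
  cells are flagged, never imputed.  **Ruggedness** is the count of
  occupied cells that are ≥ all occupied 8-neighbours, with plateaus
  counted once (lowest flat index wins) for determinism.

## Statistics

Final generations are compared with two-sided rank-sum tests
(`scipy.stats.mannwhitneyu`, exact for small tie-free samples) on one
exchangeable value per run — the final-generation population mean —
to avoid pseudo-replicating individuals within a run.  Significance
uses a Bonferroni correction for three comparisons (threshold
p < 0.05/3 ≈ 0.016).  Aggregated curves are population means per
generation, then median/Q25/Q75 across repetitions.

## What the surrogate does and does not show

The package reproduces the structural and statistical machinery of the
study plus its qualitative contrasts at desk scale: plasticity is
decisively beneficial for mutually exclusive behaviours while
non-plastic populations stay pinned to the zero-average region (their
two speeds are exact negations, so no individual ever dominates
another); brain plasticity is neutral for the compatible right-down
pair, whose non-plastic diagonals displace more in |x| + |y|; and every
multi-condition regime shows a fitness deficit against the focal
baseline.  One contrast comes out stronger than in the original
system: with the surrogate's frictionless kinematics, *body* plasticity
can fully exploit the right-down pair (re-developing a right-thrusting
body in condition A and a down-thrusting one in condition B), so the
fully plastic regime significantly outruns the non-plastic one there,
whereas the original physics-based system showed no significant
difference.  Re-orienting a body between conditions costs nothing
here — no gait re-coordination, no contact dynamics — so the genetic
costs that suppressed this exploit in the original system are
outweighed at desk scale.  This is a limitation of the surrogate's
fidelity, not of the analysis pipeline, and it is surfaced (not
hidden) by the corresponding packaged test.

Other known limitations: the CPPN query contexts and the development
procedure are reconstructions (the originals live in unavailable
supplementary material); the neighbour-coupling form and the
novelty-search budget are package choices; 2-D grids cannot represent
the 3-D module geometries, so morphology comparisons are relative.
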