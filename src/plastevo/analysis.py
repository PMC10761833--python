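"""Phenotypic-change metrics, trait descriptors, novelty search, landscapes.

The "body changes" metric is the exact ordered-tree edit distance
(Zhang–Shasha dynamic programming, unit insert/delete/relabel costs)
between the module trees developed under the two conditions; "brain
changes" is the mean absolute difference of corresponding controller
weights, defined only when the two brains share a topology.  Morphology
is summarised by four bounded descriptors (size, joint proportion,
limbs, symmetry).  Novelty search explores organism space agnostically;
its organisms, projected onto two principal components of their traits,
give a fitness-landscape grid whose local maxima count is the
ruggedness score.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.preprocessing import StandardScaler

from .morphogenesis import BodyPhenotype, TreeNode
from .neurogenesis import BrainPhenotype

logger = logging.getLogger(__name__)

DEFAULT_NOVELTY_K = 15
DEFAULT_ARCHIVE_PROB = 0.1
DEFAULT_BINS = 20


# -- ordered-tree edit distance (Zhang–Shasha) ----------------------------


def _annotate(root: TreeNode):
    """Postorder labels and leftmost-leaf indices."""
    labels: list[str] = []
    leftmost: list[int] = []

    def rec(node: TreeNode) -> int:
        if not node.children:
            labels.append(node.label)
            leftmost.append(len(labels) - 1)
            return len(labels) - 1
        lm = rec(node.children[0])
        for child in node.children[1:]:
            rec(child)
        labels.append(node.label)
        leftmost.append(lm)
        return lm

    rec(root)
    return labels, leftmost


def _keyroots(leftmost: list[int]) -> list[int]:
    last: dict[int, int] = {}
    for i, lm in enumerate(leftmost):
        last[lm] = i
    return sorted(last.values())


def tree_edit_distance(tree_a: TreeNode, tree_b: TreeNode) -> int:
    """Minimum unit-cost edit script (insert/delete/relabel) between ordered trees."""
    la, lma = _annotate(tree_a)
    lb, lmb = _annotate(tree_b)
    na, nb = len(la), len(lb)
    dist = np.zeros((na, nb), dtype=int)
    for i in _keyroots(lma):
        for j in _keyroots(lmb):
            # forest distance over subforests rooted at keyroots i, j
            ioff, joff = lma[i], lmb[j]
            m, n = i - ioff + 2, j - joff + 2
            fd = np.zeros((m, n), dtype=int)
            fd[1:, 0] = np.arange(1, m)
            fd[0, 1:] = np.arange(1, n)
            for di in range(1, m):
                ai = ioff + di - 1
                for dj in range(1, n):
                    bj = joff + dj - 1
                    if lma[ai] == ioff and lmb[bj] == joff:
                        cost = 0 if la[ai] == lb[bj] else 1
                        fd[di, dj] = min(
                            fd[di - 1, dj] + 1,
                            fd[di, dj - 1] + 1,
                            fd[di - 1, dj - 1] + cost,
                        )
                        dist[ai, bj] = fd[di, dj]
                    else:
                        fd[di, dj] = min(
                            fd[di - 1, dj] + 1,
                            fd[di, dj - 1] + 1,
                            fd[lma[ai] - ioff, lmb[bj] - joff] + dist[ai, bj],
                        )
    return int(dist[na - 1, nb - 1])


# -- brain change ---------------------------------------------------------


def brain_change(brain_a: BrainPhenotype, brain_b: BrainPhenotype) -> float:
    """Mean absolute difference of corresponding controller weights.

    Defined only when both brains share oscillator positions and
    neighbour topology (guaranteed when the bodies coincide, as in the
    brain-plastic mode); otherwise the metric is undefined and a
    ``ValueError`` is raised.
    """
    if brain_a.positions != brain_b.positions:
        raise ValueError("brain topologies differ (oscillator mismatch)")
    pairs_a = [(i, j) for i, j, _ in brain_a.neighbors]
    pairs_b = [(i, j) for i, j, _ in brain_b.neighbors]
    if pairs_a != pairs_b:
        raise ValueError("brain topologies differ (neighbour mismatch)")
    diffs = [abs(a - b) for a, b in zip(brain_a.w_xy, brain_b.w_xy)]
    diffs += [abs(a - b) for a, b in zip(brain_a.w_yx, brain_b.w_yx)]
    diffs += [
        abs(wa - wb)
        for (_, _, wa), (_, _, wb) in zip(brain_a.neighbors, brain_b.neighbors)
    ]
    if not diffs:
        return 0.0
    return float(np.mean(diffs))


# -- morphological trait descriptors --------------------------------------


@dataclass(frozen=True)
class TraitVector:
    """Bounded morphology descriptors, each in [0, 1]."""

    size: float
    joints_prop: float
    limbs: float
    symmetry: float

    def as_array(self) -> np.ndarray:
        return np.array([self.size, self.joints_prop, self.limbs, self.symmetry])


TRAIT_NAMES = ("size", "joints_prop", "limbs", "symmetry")


def body_traits(body: BodyPhenotype, max_modules: int | None = None) -> TraitVector:
    if max_modules is None:
        max_modules = body.max_modules
    modules = body.modules
    n = len(modules)
    joints = sum(1 for m in modules if m.kind == "joint")
    leaves = sum(1 for m in modules if m.kind != "core" and not m.children)
    cells = set(body.occupancy)
    mirror_v = {(-x, y) for x, y in cells}
    mirror_h = {(x, -y) for x, y in cells}
    symmetry = max(len(cells & mirror_v), len(cells & mirror_h)) / len(cells)
    return TraitVector(
        size=n / max_modules,
        joints_prop=joints / n,
        limbs=leaves / (n - 1) if n > 1 else 0.0,
        symmetry=symmetry,
    )


# -- novelty --------------------------------------------------------------


def novelty_score(behavior, population_behaviors, archive, k: int = DEFAULT_NOVELTY_K) -> float:
    """Mean Euclidean distance to the k nearest neighbours in population ∪ archive.

    ``population_behaviors`` is expected to contain the queried
    behaviour itself; one exact self-match is excluded.  With fewer than
    k neighbours available all of them are used; with none the score is
    defined as 0.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    b = np.asarray(behavior, dtype=float)
    dists: list[float] = []
    self_removed = False
    for other in population_behaviors:
        o = np.asarray(other, dtype=float)
        if not self_removed and np.array_equal(o, b):
            self_removed = True
            continue
        dists.append(float(np.linalg.norm(o - b)))
    for other in archive:
        o = np.asarray(other, dtype=float)
        dists.append(float(np.linalg.norm(o - b)))
    if not dists:
        return 0.0
    dists.sort()
    return float(np.mean(dists[:k]))


def _novelty_scores(pool_behaviors: np.ndarray, archive: np.ndarray | None,
                    k: int) -> np.ndarray:
    """Vectorised novelty over a pool (self excluded per row)."""
    pool = np.asarray(pool_behaviors, dtype=float)
    n = pool.shape[0]
    diffs = pool[:, None, :] - pool[None, :, :]
    d_pool = np.sqrt((diffs**2).sum(-1))
    np.fill_diagonal(d_pool, np.inf)
    if archive is not None and len(archive):
        arch = np.asarray(archive, dtype=float)
        d_arch = np.sqrt(((pool[:, None, :] - arch[None, :, :]) ** 2).sum(-1))
        d_all = np.concatenate([d_pool, d_arch], axis=1)
    else:
        d_all = d_pool
    scores = np.empty(n)
    for i in range(n):
        finite = np.sort(d_all[i][np.isfinite(d_all[i])])
        scores[i] = finite[:k].mean() if finite.size else 0.0
    return scores


def novelty_search(config, rng: np.random.Generator | int) -> pd.DataFrame:
    """Explore organism space selecting on behavioural novelty.

    Runs the same overlapping-generations loop as the objective-driven
    search, but with fitness replaced by the novelty score against the
    current pool and an insertion-only archive.  Returns one row per
    evaluated organism with speeds, traits, and the 4-D behaviour
    descriptor (condition endpoints).
    """
    from .evolution import run_ea  # deferred: evolution imports this module

    archive: list[np.ndarray] = []

    def assign_novelty(pool, gen_rng):
        behaviors = np.array([ind.behavior for ind in pool])
        scores = _novelty_scores(behaviors, np.array(archive) if archive else None,
                                 config.novelty_k)
        for ind, s in zip(pool, scores):
            ind.fitness = float(s)

    def on_offspring(individual, gen_rng):
        if gen_rng.random() < config.archive_prob:
            archive.append(np.asarray(individual.behavior, dtype=float))

    history = run_ea(config, rng, assign_fitness=assign_novelty,
                     on_offspring=on_offspring, keep_all=True)
    return history.evaluated_organisms()


# -- fitness landscape ----------------------------------------------------


class TraitProjection:
    """Standardise trait vectors and project them onto two principal components.

    Zero-variance trait dimensions are dropped with a warning; when
    fewer than two informative dimensions remain the projection is
    padded with zeros.
    """

    def __init__(self) -> None:
        self.keep: np.ndarray | None = None
        self.scaler: StandardScaler | None = None
        self.pca: PCA | None = None

    def fit(self, traits: np.ndarray) -> "TraitProjection":
        traits = np.asarray(traits, dtype=float)
        variances = traits.var(axis=0)
        # relative tolerance: constant columns carry rounding-level variance
        self.keep = variances > 1e-12 * max(1.0, float(variances.max()))
        dropped = int((~self.keep).sum())
        if dropped:
            warnings.warn(
                f"dropping {dropped} zero-variance trait dimension(s)",
                stacklevel=2,
            )
        kept = traits[:, self.keep]
        if kept.shape[1] == 0:
            return self
        self.scaler = StandardScaler().fit(kept)
        n_comp = min(2, kept.shape[1], kept.shape[0])
        self.pca = PCA(n_components=n_comp).fit(self.scaler.transform(kept))
        return self

    def transform(self, traits: np.ndarray) -> np.ndarray:
        traits = np.asarray(traits, dtype=float)
        out = np.zeros((traits.shape[0], 2))
        if self.pca is None:
            return out
        proj = self.pca.transform(self.scaler.transform(traits[:, self.keep]))
        out[:, : proj.shape[1]] = proj
        return out


@dataclass
class LandscapeGrid:
    """Binned PC1 x PC2 grid of mean average-speed; NaN marks empty bins."""

    mean_speed: np.ndarray  # (bins, bins)
    counts: np.ndarray  # (bins, bins) integer occupancy
    x_edges: np.ndarray
    y_edges: np.ndarray

    @property
    def occupied(self) -> np.ndarray:
        return self.counts > 0

    def to_table(self) -> pd.DataFrame:
        xi, yi = np.nonzero(self.counts)
        return pd.DataFrame(
            {
                "pc1_bin": xi,
                "pc2_bin": yi,
                "mean_speed": self.mean_speed[xi, yi],
                "count": self.counts[xi, yi],
            }
        )


def fitness_landscape(traits, speeds, bins: int = DEFAULT_BINS,
                      projection: TraitProjection | None = None,
                      extent=None) -> LandscapeGrid:
    """Project trait vectors and bin the average speed onto a 2-D grid.

    When comparing methods, fit ``projection`` (and choose ``extent``)
    on the pooled set of all methods so the grids share a coordinate
    system.
    """
    traits = np.asarray(traits, dtype=float)
    speeds = np.asarray(speeds, dtype=float)
    if traits.shape[0] < 3:
        raise ValueError("need at least 3 organisms")
    if projection is None:
        projection = TraitProjection().fit(traits)
    points = projection.transform(traits)
    if extent is None:
        extent = (
            (points[:, 0].min(), points[:, 0].max()),
            (points[:, 1].min(), points[:, 1].max()),
        )
    (x_lo, x_hi), (y_lo, y_hi) = extent
    x_edges = np.linspace(x_lo, x_hi, bins + 1)
    y_edges = np.linspace(y_lo, y_hi, bins + 1)
    xi = np.clip(np.searchsorted(x_edges, points[:, 0], side="right") - 1, 0, bins - 1)
    yi = np.clip(np.searchsorted(y_edges, points[:, 1], side="right") - 1, 0, bins - 1)
    sums = np.zeros((bins, bins))
    counts = np.zeros((bins, bins), dtype=int)
    np.add.at(sums, (xi, yi), speeds)
    np.add.at(counts, (xi, yi), 1)
    with np.errstate(invalid="ignore"):
        mean = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return LandscapeGrid(mean, counts, x_edges, y_edges)


def ruggedness(grid: LandscapeGrid) -> int:
    """Count of occupied bins that are local maxima over their 8-neighbours.

    A bin tied with a neighbour counts only once per plateau: it must
    have no strictly greater occupied neighbour and carry the lowest
    flat index of its (8-connected, equal-valued) plateau.
    """
    occ = grid.occupied
    vals = grid.mean_speed
    bins_x, bins_y = occ.shape
    if not occ.any():
        raise ValueError("grid has no occupied bins")

    def neighbors(i, j):
        for di in (-1, 0, 1):
            for dj in (-1, 0, 1):
                if di == 0 and dj == 0:
                    continue
                ni, nj = i + di, j + dj
                if 0 <= ni < bins_x and 0 <= nj < bins_y and occ[ni, nj]:
                    yield ni, nj

    def plateau_min_index(i, j):
        v = vals[i, j]
        seen = {(i, j)}
        stack = [(i, j)]
        best = i * bins_y + j
        while stack:
            ci, cj = stack.pop()
            for ni, nj in neighbors(ci, cj):
                if (ni, nj) not in seen and vals[ni, nj] == v:
                    seen.add((ni, nj))
                    stack.append((ni, nj))
                    best = min(best, ni * bins_y + nj)
        return best

    peaks = 0
    for i in range(bins_x):
        for j in range(bins_y):
            if not occ[i, j]:
                continue
            if any(vals[ni, nj] > vals[i, j] for ni, nj in neighbors(i, j)):
                continue
            if plateau_min_index(i, j) == i * bins_y + j:
                peaks += 1
    return peaks


def landscapes_by_method(data: dict[str, tuple[np.ndarray, np.ndarray]],
                         bins: int = DEFAULT_BINS) -> dict[str, LandscapeGrid]:
    """Comparable landscapes: one PCA basis and extent fitted on the pooled set."""
    pooled = np.vstack([np.asarray(t, dtype=float) for t, _ in data.values()])
    projection = TraitProjection().fit(pooled)
    points = projection.transform(pooled)
    extent = (
        (points[:, 0].min(), points[:, 0].max()),
        (points[:, 1].min(), points[:, 1].max()),
    )
    return {
        name: fitness_landscape(t, s, bins=bins, projection=projection, extent=extent)
        for name, (t, s) in data.items()
    }
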