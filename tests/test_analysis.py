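"""Phenotypic metrics, novelty, landscapes — checked against brute-force oracles."""

import numpy as np
import pytest

from plastevo.analysis import (
    LandscapeGrid,
    TraitProjection,
    body_traits,
    brain_change,
    fitness_landscape,
    landscapes_by_method,
    novelty_score,
    novelty_search,
    ruggedness,
    tree_edit_distance,
)
from plastevo.cppn import make_initial_genotype
from plastevo.evolution import ExperimentConfig
from plastevo.fixtures import _body_with_joints
from plastevo.morphogenesis import Module, TreeNode, develop_body
from plastevo.neurogenesis import BrainPhenotype


# -- independent oracle: exhaustive ordered-forest edit recursion ---------


def ted_oracle(tree_a, tree_b):
    cache = {}

    def forest_size(forest):
        return sum(1 + forest_size(t.children) for t in forest)

    def fed(f1, f2):
        key = (f1, f2)
        if key in cache:
            return cache[key]
        if not f1 and not f2:
            result = 0
        elif not f1:
            result = forest_size(f2)
        elif not f2:
            result = forest_size(f1)
        else:
            v, w = f1[-1], f2[-1]
            result = min(
                fed(f1[:-1] + v.children, f2) + 1,
                fed(f1, f2[:-1] + w.children) + 1,
                fed(v.children, w.children)
                + fed(f1[:-1], f2[:-1])
                + (v.label != w.label),
            )
        cache[key] = result
        return result

    return fed((tree_a,), (tree_b,))


def _random_tree_proper(rng, n, labels):
    children: dict[int, list[int]] = {i: [] for i in range(n)}
    for i in range(1, n):
        children[int(rng.integers(i))].append(i)
    label_of = [labels[int(rng.integers(len(labels)))] for _ in range(n)]

    def build(i):
        return TreeNode(label_of[i], tuple(build(c) for c in children[i]))

    return build(0)


def leaf(label):
    return TreeNode(label, ())


def node(label, *children):
    return TreeNode(label, tuple(children))


class TestTreeEditDistance:
    @pytest.mark.parametrize(
        "a, b, expected",
        [
            (node("core", leaf("brick")), node("core", leaf("brick")), 0),
            (node("core", leaf("brick")), leaf("core"), 1),
            (node("core", node("brick", leaf("joint0"))), node("core", leaf("joint0")), 1),
            (leaf("core"), leaf("brick"), 1),
            (node("core", leaf("joint0"), leaf("joint90")), node("core", leaf("joint90")), 1),
            (node("core", leaf("joint0"), leaf("joint90")),
             node("brick", leaf("joint90"), leaf("joint0")), 3),
        ],
    )
    def test_small_hand_cases_match_exhaustive_search(self, a, b, expected):
        assert ted_oracle(a, b) == expected  # oracle agrees with hand count
        assert tree_edit_distance(a, b) == expected

    def test_matches_exhaustive_search_on_small_trees(self, rng):
        for _ in range(200):
            a = _random_tree_proper(rng, int(rng.integers(1, 6)),
                                    ("core", "brick", "joint0"))
            b = _random_tree_proper(rng, int(rng.integers(1, 6)),
                                    ("core", "brick", "joint0"))
            assert tree_edit_distance(a, b) == ted_oracle(a, b)

    def test_metric_axioms_on_random_pairs(self, rng):
        trees = [
            _random_tree_proper(rng, int(rng.integers(1, 9)),
                                ("core", "brick", "joint0", "joint90"))
            for _ in range(60)
        ]
        pairs = [
            (trees[int(rng.integers(60))], trees[int(rng.integers(60))])
            for _ in range(500)
        ]
        for a, b in pairs:
            d_ab = tree_edit_distance(a, b)
            assert d_ab == tree_edit_distance(b, a)
            assert d_ab >= 0
            assert (d_ab == 0) == (a == b)
        for _ in range(150):
            a, b, c = (trees[int(rng.integers(60))] for _ in range(3))
            assert tree_edit_distance(a, c) <= (
                tree_edit_distance(a, b) + tree_edit_distance(b, c)
            )


class TestBrainChange:
    def make_brain(self, w_xy, w_yx, neighbors=(), positions=None):
        n = len(w_xy)
        positions = positions or tuple((i, 0) for i in range(n))
        return BrainPhenotype(positions=positions, w_xy=tuple(w_xy),
                              w_yx=tuple(w_yx), neighbors=tuple(neighbors),
                              x=(0.0,) * n, y=(0.0,) * n)

    def test_identical_brains_have_zero_change(self):
        brain = self.make_brain((0.1, 0.2), (0.3, 0.4))
        assert brain_change(brain, brain) == 0.0

    def test_uniform_half_differences_average_to_half(self):
        a = self.make_brain((0.1, 0.2), (0.3, 0.4))
        b = self.make_brain((0.6, 0.7), (0.8, 0.9))
        assert brain_change(a, b) == pytest.approx(0.5)

    def test_topology_mismatch_raises(self):
        a = self.make_brain((0.1,), (0.2,))
        b = self.make_brain((0.1, 0.2), (0.3, 0.4))
        with pytest.raises(ValueError):
            brain_change(a, b)

    def test_neighbor_weights_included(self):
        a = self.make_brain((0.0,) * 2, (0.0,) * 2, neighbors=((0, 1, 0.0), (1, 0, 0.0)))
        b = self.make_brain((0.0,) * 2, (0.0,) * 2, neighbors=((0, 1, 0.6), (1, 0, 0.6)))
        assert brain_change(a, b) == pytest.approx(1.2 / 6.0)


class TestBodyTraits:
    def test_core_only(self):
        body = _body_with_joints([])
        traits = body_traits(body, max_modules=10)
        assert traits.size == pytest.approx(0.1)
        assert traits.joints_prop == 0.0
        assert traits.limbs == 0.0
        assert traits.symmetry == 1.0

    def test_two_joint_line(self):
        chain = _body_with_joints([0])
        second = Module("joint", 0, (2, 0), 0)
        chain.root.children[0].children[0] = second
        chain.occupancy[(2, 0)] = second
        traits = body_traits(chain, max_modules=10)
        assert traits.joints_prop == pytest.approx(2.0 / 3.0)
        assert traits.limbs == pytest.approx(0.5)  # one leaf, two non-root modules
        assert traits.symmetry == 1.0  # the x-axis line mirrors onto itself

    def test_l_shape_symmetry(self):
        body = _body_with_joints([0, 3])  # occupancy {(0,0),(1,0),(0,-1)}
        traits = body_traits(body, max_modules=10)
        assert traits.symmetry == pytest.approx(2.0 / 3.0)

    def test_traits_bounded_for_random_bodies(self, random_genotypes):
        for genotype in random_genotypes("fully_plastic", n=12):
            body = develop_body(genotype, +1)
            arr = body_traits(body).as_array()
            assert (arr >= 0.0).all() and (arr <= 1.0).all()

    def test_mirror_symmetric_body_scores_one(self):
        body = _body_with_joints([0, 2])  # joints at +x and -x
        assert body_traits(body).symmetry == 1.0


def novelty_oracle(behavior, others, k):
    dists = sorted(float(np.linalg.norm(np.array(behavior) - np.array(o)))
                   for o in others)
    dists = dists[:k]
    return float(np.mean(dists)) if dists else 0.0


class TestNoveltyScore:
    def test_spec_example(self):
        pop = [(0.0, 0.0), (1.0, 0.0), (0.0, 1.0), (5.0, 5.0)]
        assert novelty_score((0.0, 0.0), pop, [], k=2) == pytest.approx(1.0)

    def test_all_identical_behaviors_score_zero(self):
        pop = [(2.0, 2.0)] * 5
        assert novelty_score((2.0, 2.0), pop, [], k=3) == 0.0

    def test_singleton_with_empty_archive_is_zero(self):
        assert novelty_score((1.0, 1.0), [(1.0, 1.0)], [], k=5) == 0.0

    def test_matches_bruteforce_knn_on_random_sets(self, rng):
        for _ in range(50):
            n = int(rng.integers(2, 30))
            pop = [tuple(rng.normal(size=4)) for _ in range(n)]
            archive = [tuple(rng.normal(size=4)) for _ in range(int(rng.integers(0, 10)))]
            k = int(rng.integers(1, 20))
            idx = int(rng.integers(n))
            others = pop[:idx] + pop[idx + 1:] + archive
            expected = novelty_oracle(pop[idx], others, k)
            assert novelty_score(pop[idx], pop, archive, k=k) == pytest.approx(expected)


@pytest.fixture(scope="module")
def tiny_config():
    return ExperimentConfig(mu=12, lam=12, generations=8, pair="right_down",
                            plasticity_mode="non_plastic", novelty_k=5)


class TestNoveltySearch:

    def test_reproducible(self, tiny_config):
        df1 = novelty_search(tiny_config, np.random.default_rng(4))
        df2 = novelty_search(tiny_config, np.random.default_rng(4))
        assert df1.equals(df2)

    def test_spread_beats_random_baseline(self, tiny_config):
        """Novelty-driven exploration spreads behaviours at least as widely
        as a random-search baseline of equal evaluation budget."""

        def spread(df):
            pts = df[["end_ax", "end_ay", "end_bx", "end_by"]].to_numpy()
            diffs = pts[:, None, :] - pts[None, :, :]
            d = np.sqrt((diffs**2).sum(-1))
            n = len(pts)
            return d[np.triu_indices(n, 1)].mean()

        novelty_spreads, random_spreads = [], []
        for seed in range(5):
            df_nov = novelty_search(tiny_config, np.random.default_rng(seed))
            rng = np.random.default_rng(seed)
            from plastevo.evolution import evaluate

            rows = []
            for _ in range(len(df_nov)):
                g = make_initial_genotype(rng, tiny_config.plasticity_mode)
                rows.append(evaluate(g, tiny_config)["behavior"])
            df_rand = np.array(rows)
            novelty_spreads.append(spread(df_nov))
            diffs = df_rand[:, None, :] - df_rand[None, :, :]
            d = np.sqrt((diffs**2).sum(-1))
            random_spreads.append(d[np.triu_indices(len(df_rand), 1)].mean())
        assert np.mean(novelty_spreads) >= np.mean(random_spreads)


class TestLandscape:
    def test_identical_organisms_fall_in_one_bin(self):
        traits = np.tile([0.5, 0.2, 0.1, 1.0], (6, 1))
        speeds = np.full(6, 0.3)
        with pytest.warns(UserWarning, match="zero-variance"):
            grid = fitness_landscape(traits, speeds, bins=10)
        assert grid.occupied.sum() == 1
        assert ruggedness(grid) == 1

    def test_occupied_bins_bounded_by_organism_count(self, rng):
        traits = rng.random((40, 4))
        speeds = rng.random(40)
        grid = fitness_landscape(traits, speeds, bins=15)
        assert grid.occupied.sum() <= 40
        assert grid.counts.sum() == 40

    def test_projection_preserves_ordering_on_a_line(self, rng):
        t = np.linspace(0, 1, 25)
        traits = np.column_stack([t, 0.5 * t, np.zeros(25), np.ones(25)])
        with pytest.warns(UserWarning, match="zero-variance"):
            projection = TraitProjection().fit(traits)
        pc1 = projection.transform(traits)[:, 0]
        # PCA of collinear points is a monotone map of the line parameter
        assert np.all(np.diff(pc1) > 0) or np.all(np.diff(pc1) < 0)

    def test_shared_projection_for_method_comparison(self, rng):
        data = {
            "a": (rng.random((20, 4)), rng.random(20)),
            "b": (rng.random((20, 4)), rng.random(20)),
        }
        grids = landscapes_by_method(data, bins=8)
        assert set(grids) == {"a", "b"}
        assert np.array_equal(grids["a"].x_edges, grids["b"].x_edges)


def grid_from(values, counts=None):
    vals = np.asarray(values, dtype=float)
    counts = np.asarray(counts if counts is not None else ~np.isnan(vals), dtype=int)
    bins = vals.shape[0]
    edges = np.arange(bins + 1, dtype=float)
    return LandscapeGrid(vals, counts, edges, edges)


class TestRuggedness:
    def test_single_occupied_bin(self):
        vals = np.full((5, 5), np.nan)
        counts = np.zeros((5, 5), dtype=int)
        vals[2, 2], counts[2, 2] = 0.7, 3
        assert ruggedness(grid_from(vals, counts)) == 1

    def test_monotone_ramp_has_one_peak(self):
        vals = np.arange(36, dtype=float).reshape(6, 6)
        assert ruggedness(grid_from(vals)) == 1

    def test_two_maxima_separated_by_valley(self):
        vals = np.zeros((5, 5))
        vals[0, 0] = 2.0
        vals[4, 4] = 3.0
        assert ruggedness(grid_from(vals)) == 2

    def test_plateau_counts_once(self):
        vals = np.zeros((4, 4))
        vals[1, 1] = vals[1, 2] = 1.0
        assert ruggedness(grid_from(vals)) == 1

    def test_matches_enumeration_on_random_grids(self, rng):
        for _ in range(30):
            vals = rng.integers(0, 4, size=(6, 6)).astype(float)
            occ = rng.random((6, 6)) < 0.7
            vals[~occ] = np.nan
            if not occ.any():
                continue
            grid = grid_from(vals, occ.astype(int))
            # enumeration oracle: literal definition, applied per bin
            expected = 0
            for i in range(6):
                for j in range(6):
                    if not occ[i, j]:
                        continue
                    neigh = [
                        (i + di, j + dj)
                        for di in (-1, 0, 1)
                        for dj in (-1, 0, 1)
                        if (di, dj) != (0, 0)
                        and 0 <= i + di < 6
                        and 0 <= j + dj < 6
                        and occ[i + di, j + dj]
                    ]
                    if any(vals[p] > vals[i, j] for p in neigh):
                        continue
                    plateau = {(i, j)}
                    frontier = [(i, j)]
                    while frontier:
                        ci, cj = frontier.pop()
                        for di in (-1, 0, 1):
                            for dj in (-1, 0, 1):
                                p = (ci + di, cj + dj)
                                if (
                                    0 <= p[0] < 6 and 0 <= p[1] < 6
                                    and occ[p] and p not in plateau
                                    and vals[p] == vals[i, j]
                                ):
                                    plateau.add(p)
                                    frontier.append(p)
                    if min(a * 6 + b for a, b in plateau) == i * 6 + j:
                        expected += 1
            assert ruggedness(grid) == expected
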