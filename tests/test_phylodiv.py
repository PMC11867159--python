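"""PD, PD indices, field-of-bullets loss, and the phi_PD curve."""

import itertools
import math
from fractions import Fraction

import numpy as np
import pytest
from scipy import integrate, stats

from neutraldiv import birthdeath as bd
from neutraldiv import phylodiv as pv
from neutraldiv import treecore as tc
from neutraldiv.fixtures import random_tree_with_lengths


CATERPILLAR = "((a:1,b:1):1,c:2);"


def exact_tree(n, seed):
    """Random topology with small integer (hence exact) edge lengths."""
    tree = random_tree_with_lengths(n, seed)
    rng = np.random.default_rng(seed + 7)
    for e in tree.edges():
        e.length = Fraction(int(rng.integers(1, 9)))
    return tree


class TestPD:
    def test_examples(self):
        tree = tc.read_newick(CATERPILLAR, binary=True)
        assert pv.pd(tree, "abc") == pytest.approx(5.0)
        assert pv.pd(tree, "ac") == pytest.approx(4.0)
        assert pv.pd(tree, []) == 0

    def test_unknown_leaf_listed(self):
        tree = tc.read_newick(CATERPILLAR, binary=True)
        with pytest.raises(tc.TreeError, match="zz"):
            pv.pd(tree, ["a", "zz"])

    def test_monotone_and_submodular_exhaustive(self):
        for seed in range(4):
            tree = exact_tree(6, seed)
            labels = sorted(tree.leaf_labels)
            values = {}
            for r in range(7):
                for c in itertools.combinations(labels, r):
                    values[frozenset(c)] = pv.pd(tree, c)
            subsets = list(values)
            for y1 in subsets:
                for y2 in subsets:
                    assert values[y1 | y2] + values[y1 & y2] \
                        <= values[y1] + values[y2]
            for y1 in subsets:
                for x in labels:
                    assert values[y1 | {x}] >= values[y1]


class TestMaxPD:
    def test_full_set(self):
        tree = tc.read_newick(CATERPILLAR, binary=True)
        subset, value = pv.max_pd_subset(tree, 3)
        assert subset == {"a", "b", "c"}
        assert value == pytest.approx(5.0)

    def test_star_tree_picks_longest_pendants(self):
        star = tc.read_newick("(a:1,b:5,c:3,d:2);")
        subset, value = pv.max_pd_subset(star, 2)
        assert subset == {"b", "c"}
        assert value == pytest.approx(8.0)

    def test_greedy_equals_bruteforce(self):
        for seed in range(200):
            tree = random_tree_with_lengths(8, seed)
            k = 1 + seed % 7
            _, greedy = pv.max_pd_subset(tree, k)
            brute = max(float(pv.pd(tree, c)) for c in
                        itertools.combinations(sorted(tree.leaf_labels), k))
            assert greedy == pytest.approx(brute, rel=1e-12)

    def test_bounds(self):
        tree = tc.read_newick(CATERPILLAR, binary=True)
        with pytest.raises(tc.TreeError):
            pv.max_pd_subset(tree, 0)
        with pytest.raises(tc.TreeError):
            pv.max_pd_subset(tree, 4)


class TestPDIndices:
    def test_caterpillar_values(self):
        tree = tc.read_newick("((a:2,b:3):1,c:2);", binary=True)
        fp = pv.pd_index(tree, "fp")
        es = pv.pd_index(tree, "es")
        assert fp["a"] == pytest.approx(2.5)
        assert es["a"] == pytest.approx(2.5)  # binary: identical here
        assert fp["c"] == pytest.approx(2.0)

    @pytest.mark.parametrize("rule", ["fp", "es"])
    def test_conservation_exact(self, rule):
        for seed in range(6):
            tree = exact_tree(7, seed)
            vals = pv.pd_index(tree, rule)
            assert sum(vals.values()) == pv.pd(tree, tree.leaf_labels)

    def test_convex_mix_conserves(self):
        tree = exact_tree(6, 2)
        vals = pv.pd_index(tree, pv.PDIndexSpec("mix", alpha=0.3))
        assert float(sum(vals.values())) == pytest.approx(
            float(pv.pd(tree, tree.leaf_labels)))

    def test_fp_equals_shapley_all_small_trees(self):
        for n in (3, 4, 5):
            for tree in tc.enumerate_labeled_trees([str(i) for i in range(n)]):
                rng = np.random.default_rng(n)
                for e in tree.edges():
                    e.length = Fraction(int(rng.integers(1, 7)))
                fp = pv.pd_index(tree, "fp")
                for x in tree.leaf_labels:
                    assert pv.shapley_oracle(tree, x) == fp[x]

    def test_fp_equals_shapley_random_six_leaf(self):
        for seed in range(3):
            tree = exact_tree(6, seed)
            fp = pv.pd_index(tree, "fp")
            for x in sorted(tree.leaf_labels)[:3]:
                assert pv.shapley_oracle(tree, x) == fp[x]

    def test_index_subset_inequality(self):
        for seed in range(5):
            tree = exact_tree(7, seed)
            labels = sorted(tree.leaf_labels)
            for rule in ("fp", "es"):
                for r in range(8):
                    for c in itertools.combinations(labels, r):
                        _, _, gap = pv.index_subset_inequality_check(
                            tree, rule, c)
                        assert gap >= 0
                s, p, gap = pv.index_subset_inequality_check(
                    tree, rule, labels)
                assert gap == 0

    def test_star_tree_gap_zero(self):
        star = tc.read_newick("(a:1,b:2,c:3);")
        for c in (["a"], ["a", "b"], ["a", "b", "c"]):
            _, _, gap = pv.index_subset_inequality_check(star, "fp", c)
            assert gap == pytest.approx(0.0)


class TestExpectedPDLoss:
    def test_boundary_values(self):
        tree = tc.read_newick(CATERPILLAR, binary=True)
        assert pv.expected_pd_loss(tree, pv.ExtinctionModel.fob(1.0)) == 1
        assert pv.expected_pd_loss(tree, pv.ExtinctionModel.fob(0.0)) == 0

    def test_caterpillar_half(self):
        tree = tc.read_newick(CATERPILLAR, binary=True)
        loss = pv.expected_pd_loss(tree, pv.ExtinctionModel.fob(0.5))
        assert loss == pytest.approx(0.45)

    def test_matches_outcome_enumeration(self):
        rng = np.random.default_rng(3)
        for seed in range(4):
            tree = random_tree_with_lengths(7, seed)
            labels = sorted(tree.leaf_labels)
            eps = {x: float(rng.uniform(0.1, 0.9)) for x in labels}
            model = pv.ExtinctionModel(eps)
            total = float(tree.total_length())
            expect = 0.0
            for outcome in itertools.product([0, 1], repeat=len(labels)):
                prob = 1.0
                survivors = []
                for x, dead in zip(labels, outcome):
                    prob *= eps[x] if dead else 1 - eps[x]
                    if not dead:
                        survivors.append(x)
                expect += prob * (1 - float(pv.pd(tree, survivors)) / total)
            assert pv.expected_pd_loss(tree, model) \
                == pytest.approx(expect, rel=1e-10)

    def test_monotone_in_epsilon(self):
        tree = random_tree_with_lengths(8, 11)
        losses = [pv.expected_pd_loss(tree, pv.ExtinctionModel.fob(e))
                  for e in np.linspace(0, 1, 11)]
        assert all(b >= a for a, b in zip(losses, losses[1:]))

    def test_matches_monte_carlo(self):
        tree = random_tree_with_lengths(10, 5)
        model = pv.ExtinctionModel.fob(0.4)
        sims = pv.simulate_pd_loss(tree, model, 4000, seed=8)
        expect = pv.expected_pd_loss(tree, model)
        se = sims.std() / math.sqrt(len(sims))
        assert abs(sims.mean() - expect) < 3 * se

    def test_loss_distribution_tends_to_symmetry(self):
        # larger neutral trees: the loss distribution loses its skew
        def skew(n, seed):
            tree = random_tree_with_lengths(n, seed)
            sims = pv.simulate_pd_loss(
                tree, pv.ExtinctionModel.fob(0.5), 3000, seed=seed)
            return abs(stats.skew(sims))
        assert skew(200, 1) < skew(10, 1)


class TestPsi:
    def test_star_tree_psi_is_pendant(self):
        star = tc.read_newick("(a:1,b:2,c:3);")
        model = pv.ExtinctionModel.fob(0.5)
        assert pv.psi(star, model, "b") == pytest.approx(2.0)

    def test_caterpillar_value(self):
        tree = tc.read_newick("((a:2,b:1):3,c:2);", binary=True)
        model = pv.ExtinctionModel.fob(0.5)
        assert pv.psi(tree, model, "a") == pytest.approx(2 + 3 * 0.5)

    def test_zero_epsilon_gives_pendant(self):
        tree = random_tree_with_lengths(7, 2)
        model = pv.ExtinctionModel.fob(0.0)
        for x in tree.leaf_labels:
            pendant = float(tree.path_to_leaf(x)[-1].length)
            assert float(pv.psi(tree, model, x)) == pytest.approx(pendant)

    def test_psi_prime_identity(self):
        rng = np.random.default_rng(9)
        tree = random_tree_with_lengths(6, 4)
        eps = {x: float(rng.uniform(0, 1)) for x in tree.leaf_labels}
        model = pv.ExtinctionModel(eps)
        for x in tree.leaf_labels:
            assert pv.psi_prime(tree, model, x) \
                == pytest.approx(pv.psi(tree, model, x) * eps[x])

    def test_psi_matches_outcome_enumeration(self):
        rng = np.random.default_rng(17)
        tree = random_tree_with_lengths(6, 13)
        labels = sorted(tree.leaf_labels)
        eps = {x: float(rng.uniform(0.2, 0.8)) for x in labels}
        model = pv.ExtinctionModel(eps)
        x = labels[0]
        others = [y for y in labels if y != x]
        expect = 0.0
        for outcome in itertools.product([0, 1], repeat=len(others)):
            prob = 1.0
            alive = []
            for y, dead in zip(others, outcome):
                prob *= eps[y] if dead else 1 - eps[y]
                if not dead:
                    alive.append(y)
            gain = float(pv.pd(tree, alive + [x])) - float(pv.pd(tree, alive))
            expect += prob * gain
        assert float(pv.psi(tree, model, x)) == pytest.approx(expect,
                                                              rel=1e-10)

    def test_psi_is_not_a_pd_index(self):
        tree = tc.read_newick(CATERPILLAR, binary=True)
        model = pv.ExtinctionModel.fob(0.3)
        total = sum(float(pv.psi(tree, model, x)) for x in "abc")
        assert total != pytest.approx(float(pv.pd(tree, "abc")))


class TestFPPsiIdentity:
    def test_exact_identity(self):
        for seed in range(4):
            tree = exact_tree(6, seed)
            for x in sorted(tree.leaf_labels):
                fp, integral = pv.fp_as_expected_psi(tree, x)
                assert fp == integral

    def test_against_quadrature(self):
        tree = random_tree_with_lengths(6, 21)
        for x in sorted(tree.leaf_labels)[:3]:
            fp = float(pv.pd_index(tree, "fp")[x])

            def integrand(e):
                return float(pv.psi(tree, pv.ExtinctionModel.fob(e), x))

            val, _ = integrate.quad(integrand, 0, 1, epsabs=1e-12)
            assert val == pytest.approx(fp, abs=1e-10)


class TestPhiPD:
    def test_boundaries(self):
        assert pv.phi_pd(0.0, 1.0) == 0.0
        assert pv.phi_pd(1.0, 1.0) == 1.0

    def test_yule_log2(self):
        assert pv.phi_pd(0.5, 1.0) == pytest.approx(math.log(2), abs=1e-15)

    def test_matches_yh_sum_heuristic(self):
        for s in (0.2, 0.5, 0.8):
            assert pv.phi_pd(s, 1.0) \
                == pytest.approx(pv.phi_pd_yh_sum(s, 10 ** 6), abs=1e-5)

    def test_branch_continuity(self):
        for s in (0.2, 0.5, 0.8):
            mid = pv.phi_pd(s, 1.0, 1 - s)
            left = pv.phi_pd(s, 1.0, 1 - s - 1e-9)
            right = pv.phi_pd(s, 1.0, 1 - s + 1e-9)
            assert abs(mid - left) < 1e-8
            assert abs(mid - right) < 1e-8
            assert mid == pytest.approx((1 - s) / math.log(1 / s), rel=1e-12)
        # mu -> 0 joins the Yule branch
        assert pv.phi_pd(0.5, 1.0, 1e-13) \
            == pytest.approx(pv.phi_pd(0.5, 1.0, 0.0), abs=1e-9)

    @pytest.mark.parametrize("mu", [0.0, 0.3, 0.6, 0.9])
    def test_shape_properties(self, mu):
        grid = np.linspace(0.001, 0.999, 101)
        vals = [pv.phi_pd(s, 1.0, mu) for s in grid]
        diffs = np.diff(vals)
        assert np.all(diffs > 0)                       # increasing
        assert np.all(np.diff(diffs) <= 1e-9)          # concave
        for s, v in zip(grid, vals):
            assert v >= s - 1e-12                      # phi >= s

    def test_approaches_step_function_near_criticality(self):
        # the approach to the unit step is logarithmically slow in 1-rho
        vals = [pv.phi_pd(0.2, 1.0, mu)
                for mu in (0.0, 0.9, 0.999, 1 - 1e-9)]
        assert all(b > a for a, b in zip(vals, vals[1:]))
        assert vals[-1] > 0.9

    def test_yule_slope_at_one_is_half(self):
        h = 1e-6
        slope = (pv.phi_pd(1.0, 1.0) - pv.phi_pd(1.0 - h, 1.0)) / h
        assert slope == pytest.approx(0.5, abs=1e-4)

    def test_domain_errors(self):
        with pytest.raises(tc.TreeError):
            pv.phi_pd(0.5, 1.0, 1.0)
        with pytest.raises(tc.TreeError):
            pv.phi_pd(1.5, 1.0)

    def test_expected_edge_count_pendants(self):
        assert pv.expected_edges_with_k_descendants(50, 1) == 50


class TestPhiPDEmpirical:
    def test_s_equal_one_is_identity(self):
        out = pv.phi_pd_empirical(1.0, 0.0, 1.0, 2.0, 20, seed=3)
        assert np.allclose(out, 1.0, atol=1e-12)

    def test_mean_approaches_phi_pd(self):
        out = pv.phi_pd_empirical(1.0, 0.5, 0.5, 9.0, 250, seed=13)
        expect = pv.phi_pd(0.5, 1.0, 0.5)
        assert abs(out.mean() - expect) < 0.03


class TestMeanFPYule:
    def test_limits(self):
        assert pv.mean_fp_yule(2.0, 1e9) == pytest.approx(0.5)
        assert pv.mean_fp_yule(1.0, 0.0) == pytest.approx(2.0)

    def test_monte_carlo(self):
        rng = np.random.default_rng(5)
        params = bd.BDParams(lam=1.0, t=3.0)
        fps = []
        for _ in range(2500):
            tree = bd.simulate_bd(params, rng, condition="survival").reduce()
            if tree.n == 1:
                fps.append(tree.stem_length)
                continue
            vals = pv.pd_index(tree, "fp")
            labels = sorted(vals)
            fps.append(float(vals[labels[int(rng.integers(len(labels)))]]))
        se = np.std(fps) / math.sqrt(len(fps))
        assert abs(np.mean(fps) - pv.mean_fp_yule(1.0, 3.0)) < 3 * se
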