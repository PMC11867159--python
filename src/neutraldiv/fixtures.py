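"""Worked examples, seeded random fixtures, and the reproduce-all report.

The fixtures encode the two classic desk examples used throughout the test
suite: Harding's five-leaf tree (shape probability 1/6, labelled-tree
probability 1/90 under Yule–Harding) and a small synthetic gain/loss
scenario in which five features are present at the leaves, an extinction
event kills three leaves, and three features survive (ratio 3/5 = 0.6).
"""

from __future__ import annotations

import json
import math
import os
from fractions import Fraction

import numpy as np

from . import birthdeath, featurediv, fd_loss, neutral_models, phylodiv
from .treecore import RootedPhyloTree, TreeError, read_newick, shape_of


def harding_five_leaf_tree(with_lengths: bool = True) -> RootedPhyloTree:
    """Harding's 1971 five-leaf example: the root splits 4+1 and the
    four-leaf side is two cherries; s(τ)=3, YH shape probability 1/6,
    labelled-tree probability 1/90."""
    if with_lengths:
        nwk = "(((a:1,b:1):1,(c:1,d:1):1):1,e:3);"
    else:
        nwk = "(((a,b),(c,d)),e);"
    return read_newick(nwk, binary=True)


def feature_loss_scenario():
    """Synthetic gain/loss worked example (stand-in for a figure-style
    scenario): returns (tree, assignment, extinct_leaves).

    Six leaves; features alpha..epsilon are present among them; the
    extinction event removes x4, x5, x6.  Features delta (only in x5) and
    epsilon (only in x6) die with their carriers, so 3 of 5 features
    survive: ratio 0.6.
    """
    tree = read_newick(
        "(((x1:1,x2:1):1,x3:2):1,((x4:1,x5:1):1,x6:2):1);", binary=True)
    assignment = featurediv.FeatureAssignment({
        "x1": {"alpha"},
        "x2": {"beta"},
        "x3": {"gamma"},
        "x4": {"beta"},
        "x5": {"delta"},
        "x6": {"epsilon"},
    })
    extinct = frozenset({"x4", "x5", "x6"})
    return tree, assignment, extinct


def fixture_random(kind: str, n: int, seed) -> RootedPhyloTree:
    """Seeded random tree: "yh"/"pda" (no lengths), "yule" (fixed-n Yule
    with time edge lengths) or "bd" (reduced birth–death, λ=1, μ=0.5)."""
    rng = np.random.default_rng(seed)
    if kind == "yh":
        return neutral_models.yh_sample(n, rng)
    if kind == "pda":
        return neutral_models.pda_sample(n, rng)
    if kind == "yule":
        params = birthdeath.BDParams(lam=1.0)
        real = birthdeath.simulate_bd(params, rng, condition="fixed_n", n=n)
        return real.reduce()
    if kind == "bd":
        params = birthdeath.BDParams(lam=1.0, mu=0.5)
        real = birthdeath.simulate_bd(params, rng, condition="fixed_n", n=n)
        return real.reduce()
    raise TreeError(f"unknown fixture kind {kind!r}")


def random_tree_with_lengths(n: int, seed, mean_length: float = 1.0
                             ) -> RootedPhyloTree:
    """YH topology with i.i.d. exponential edge lengths (test workhorse)."""
    rng = np.random.default_rng(seed)
    tree = neutral_models.yh_sample(n, rng)
    for e in tree.edges():
        e.length = float(rng.exponential(mean_length))
    return tree


# ---------------------------------------------------------------------------
# reproduce-all report


def reproduce_all(out_dir=None, seed: int = 20250220) -> dict:
    """Recompute every printed worked example and report pass/fail.

    Returns a report dict; if ``out_dir`` is given, writes
    ``reproduction.json`` and a TSV table there.  All stochastic entries log
    the seed used.
    """
    rows = []

    def check(name, computed, expected, tol=0.0, seed_used=None):
        if tol == 0.0:
            ok = computed == expected
        else:
            ok = abs(float(computed) - float(expected)) <= tol
        rows.append({
            "id": name,
            "computed": str(computed),
            "expected": str(expected),
            "tolerance": tol,
            "seed": seed_used,
            "pass": bool(ok),
        })

    tree5 = harding_five_leaf_tree()
    shape5 = shape_of(tree5)
    check("yh_shape_probability_harding",
          neutral_models.yh_shape_probability(shape5), Fraction(1, 6))
    check("yh_tree_probability_harding",
          neutral_models.yh_tree_probability(tree5), Fraction(1, 90))
    from .treecore import enumerate_shapes
    check("five_leaf_shape_count", len(enumerate_shapes(5)), 3)

    d3 = neutral_models.depth_distribution(3, "reduced")
    check("depth3_reduced", (d3[1], d3[2]),
          (Fraction(1, 3), Fraction(2, 3)))
    d3e = neutral_models.depth_distribution(3, "evolutionary")
    check("depth3_evolutionary", (d3e[0], d3e[1], d3e[2]),
          (Fraction(1, 3), Fraction(1, 2), Fraction(1, 6)))

    _, assignment, extinct = feature_loss_scenario()
    all_leaves = assignment.leaf_labels
    survivors = all_leaves - extinct
    ratio = Fraction(featurediv.fd(assignment, survivors),
                     featurediv.fd(assignment, all_leaves))
    check("feature_survival_ratio", ratio, Fraction(3, 5))

    check("pda_single_leaf_root_n7",
          neutral_models.pda_single_leaf_root_probability(7),
          Fraction(7, 11))
    limit = float(neutral_models.pda_single_leaf_root_probability(10 ** 9))
    check("pda_single_leaf_root_limit", limit, 0.5, tol=1e-8)

    check("shortest_interior_halfpoint",
          birthdeath.shortest_interior_cdf(0.5), 0.5, tol=0.0)

    check("phi_pd_yule_half", phylodiv.phi_pd(0.5, 1.0), math.log(2),
          tol=1e-12)
    check("phi_fd_nu0_equals_phi_pd",
          fd_loss.phi_fd(0.3, 1.0, 0.2, 0.0),
          phylodiv.phi_pd(0.3, 1.0, 0.2), tol=1e-9)

    report = {"seed": seed, "results": rows,
              "all_pass": all(r["pass"] for r in rows)}
    if out_dir is not None:
        os.makedirs(out_dir, exist_ok=True)
        with open(os.path.join(out_dir, "reproduction.json"), "w") as fh:
            json.dump(report, fh, indent=2)
        with open(os.path.join(out_dir, "reproduction.tsv"), "w") as fh:
            fh.write("id\tcomputed\texpected\ttolerance\tseed\tpass\n")
            for r in rows:
                fh.write("\t".join(str(r[k]) for k in
                                   ("id", "computed", "expected",
                                    "tolerance", "seed", "pass")) + "\n")
    return report
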