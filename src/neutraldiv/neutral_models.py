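"""Yule–Harding shape/tree probabilities, depth laws and the PDA contrast.

All neutral cladogenesis models (constant-rate birth–death and its
time/state-dependent generalisations in which the speciating or dying lineage
is always chosen uniformly) induce one and the same distribution on binary
tree shapes, the Yule–Harding (YH) distribution.  Its closed form is

    p(τ) = 2^{n-1-s(τ)} / Π_{v ∈ IV(τ)} n_τ(v),

with s(τ) the number of symmetry vertices and n_τ(v) the number of descendant
leaves of interior vertex v minus one.  Multiplying by 2^{s(τ)}/n! gives the
probability of each labelled tree of that shape.

The depth of a random leaf follows Stirling-number laws: in a reduced tree
P(D_n = k) = 2^k c(n−1,k)/n!, and in a reduced evolutionary tree (which only
counts "new species" edges) P(D'_n = k) = c(n,k+1)/n!, with the exact mean
identity E[D'_n] = E[D_n]/2 = Σ_{i=2}^n 1/i and a Poisson(ln n + γ − 1)
limit for D'_n.

Probabilities use exact rational arithmetic (``fractions.Fraction``) for the
small-n regime where the printed worked examples (1/6, 1/90, 2/3 …) must be
bit-exact; large-n helpers return floats.

The PDA model (uniform over labelled binary trees) serves as the contrast
class: root splits, leaf depths and MRCA placement behave very differently.
"""

from __future__ import annotations

import math
from fractions import Fraction

import numpy as np

from .treecore import Node, RootedPhyloTree, TreeError, TreeShape, shape_of

EULER_GAMMA = 0.5772156649015328606


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# Shape and tree probabilities


def yh_shape_probability(shape: TreeShape) -> Fraction:
    """Exact YH probability of an unlabelled binary shape (n ≥ 2)."""
    if shape.n < 2:
        raise TreeError("shape probability requires n >= 2")
    denom = 1
    for c in shape.descendant_counts():
        denom *= c
    return Fraction(2 ** (shape.n - 1 - shape.symmetry_count), denom)


def yh_tree_probability(tree: RootedPhyloTree) -> Fraction:
    """Exact YH probability of a labelled binary tree: p(τ)·2^{s(τ)}/n!."""
    shape = shape_of(tree)
    if shape.n < 2:
        raise TreeError("tree probability requires n >= 2")
    return (yh_shape_probability(shape) * 2 ** shape.symmetry_count
            / math.factorial(shape.n))


# ---------------------------------------------------------------------------
# Samplers


def yh_sample(n: int, seed=None) -> RootedPhyloTree:
    """Sample a YH tree on labels ``1..n`` by uniform leaf attachment.

    Starting from a cherry, a uniformly chosen leaf is repeatedly replaced by
    a cherry containing itself and the next new leaf.  At every split one
    child is designated the offspring ("horizontal") lineage uniformly at
    random, so evolutionary depths can be read off the sample.
    """
    if n < 2:
        raise TreeError("yh_sample requires n >= 2")
    rng = _as_rng(seed)
    root = Node()
    a, b = Node("1"), Node("2")
    root.add(a)
    root.add(b)
    _designate(root, rng)
    leaves = [a, b]
    for k in range(3, n + 1):
        i = int(rng.integers(len(leaves)))
        old = leaves[i]
        new_leaf = Node(str(k))
        split = Node()
        parent = old.parent
        idx = parent.children.index(old)
        split.add(old)
        split.add(new_leaf)
        split.horizontal = old.horizontal
        split.parent = parent
        parent.children[idx] = split
        _designate(split, rng)
        leaves[i] = old
        leaves.append(new_leaf)
    return RootedPhyloTree(root, binary=True)


def _designate(split: Node, rng) -> None:
    off = int(rng.integers(2))
    split.children[off].horizontal = True
    split.children[1 - off].horizontal = False


def pda_sample(n: int, seed=None) -> RootedPhyloTree:
    """Uniform labelled binary tree on ``1..n`` (PDA model).

    Sequential uniform attachment over the 2k−1 possible graft positions
    (any edge, or above the root) yields each of the (2n−3)!! trees with
    equal probability.
    """
    if n < 2:
        raise TreeError("pda_sample requires n >= 2")
    rng = _as_rng(seed)
    root = Node()
    root.add(Node("1"))
    root.add(Node("2"))
    nodes = [root, root.children[0], root.children[1]]
    for k in range(3, n + 1):
        spot = nodes[int(rng.integers(len(nodes)))]
        split = Node()
        leaf = Node(str(k))
        if spot is root:
            split.add(root)
            split.add(leaf)
            root = split
        else:
            parent = spot.parent
            idx = parent.children.index(spot)
            split.add(spot)
            split.add(leaf)
            split.parent = parent
            parent.children[idx] = split
        nodes.append(split)
        nodes.append(leaf)
    return RootedPhyloTree(root, binary=True)


# ---------------------------------------------------------------------------
# Stirling numbers and depth distributions


_STIRLING_ROWS: list[list[int]] = [[1]]


def stirling_first_kind(n: int, k: int) -> int:
    """Unsigned Stirling number of the first kind c(n, k), exact.

    c(n,k) counts permutations of n elements with k cycles and obeys
    c(n,k) = c(n−1,k−1) + (n−1)·c(n−1,k).
    """
    if n < 0 or k < 0:
        raise TreeError("negative arguments to stirling_first_kind")
    if n > 500:
        raise TreeError("stirling_first_kind supports n <= 500")
    if k > n:
        return 0
    while len(_STIRLING_ROWS) <= n:
        m = len(_STIRLING_ROWS)
        prev = _STIRLING_ROWS[m - 1]
        row = [0] * (m + 1)
        for j in range(1, m + 1):
            row[j] = prev[j - 1] + (m - 1) * (prev[j] if j < m else 0)
        _STIRLING_ROWS.append(row)
    return _STIRLING_ROWS[n][k]


class DepthDistribution:
    """Exact law of the depth of a random extant leaf.

    ``variant="reduced"`` is the edge-count depth D_n in the reduced tree,
    supported on 1..n−1; ``variant="evolutionary"`` is the horizontal-edge
    count D'_n in the reduced evolutionary tree, supported on 0..n−1.
    """

    def __init__(self, n: int, variant: str, probs: dict[int, Fraction]):
        self.n = n
        self.variant = variant
        self.probs = probs

    def __getitem__(self, k: int) -> Fraction:
        return self.probs.get(k, Fraction(0))

    def support(self) -> list[int]:
        return sorted(k for k, p in self.probs.items() if p)

    def mean(self) -> Fraction:
        return sum((Fraction(k) * p for k, p in self.probs.items()),
                   Fraction(0))

    def as_floats(self) -> dict[int, float]:
        return {k: float(p) for k, p in self.probs.items()}

    def to_json_dict(self) -> dict:
        return {
            "n": self.n,
            "variant": self.variant,
            "probabilities": {
                str(k): ({"numerator": p.numerator,
                          "denominator": p.denominator,
                          "float": float(p)}
                         if isinstance(p, Fraction) else {"float": float(p)})
                for k, p in sorted(self.probs.items())
            },
        }


_EXACT_DEPTH_LIMIT = 150


def depth_distribution(n: int, variant: str = "reduced") -> DepthDistribution:
    """Depth law for a random leaf of an n-leaf neutral-model tree.

    Exact rationals up to n=150; beyond that the law is computed in floats
    through the cycle-count representation (the number of cycles of a
    uniform n-permutation is a sum of independent Bernoulli(1/i) variables,
    so the Stirling ratios c(n,k)/n! follow by sequential convolution).
    """
    if n < 2:
        raise TreeError("depth_distribution requires n >= 2")
    if variant not in ("reduced", "evolutionary"):
        raise TreeError(f"unknown depth variant {variant!r}")
    probs: dict[int, object] = {}
    if n <= _EXACT_DEPTH_LIMIT:
        nfact = math.factorial(n)
        if variant == "reduced":
            for k in range(1, n):
                probs[k] = Fraction(2 ** k * stirling_first_kind(n - 1, k),
                                    nfact)
        else:
            for k in range(0, n):
                probs[k] = Fraction(stirling_first_kind(n, k + 1), nfact)
        return DepthDistribution(n, variant, probs)
    if variant == "reduced":
        # P(D_n = k) = 2^k c(n-1,k)/n! = 2^k pmf_{n-1}(k)/n
        pmf = _cycle_count_pmf(n - 1)
        log2 = math.log(2.0)
        logn = math.log(n)
        for k in range(1, n):
            if pmf[k] > 0.0:
                probs[k] = math.exp(k * log2 + math.log(pmf[k]) - logn)
    else:
        # D'_n = (#cycles of a uniform n-permutation) - 1
        pmf = _cycle_count_pmf(n)
        for k in range(0, n):
            if pmf[k + 1] > 0.0:
                probs[k] = pmf[k + 1]
    return DepthDistribution(n, variant, probs)


def _cycle_count_pmf(m: int) -> np.ndarray:
    """pmf of Σ_{i=1}^m Bernoulli(1/i) (index = count), i.e. c(m,k)/m!."""
    pmf = np.zeros(m + 1)
    pmf[0] = 1.0
    for i in range(1, m + 1):
        p = 1.0 / i
        pmf[1:i + 1] = p * pmf[0:i] + (1 - p) * pmf[1:i + 1]
        pmf[0] *= (1 - p)
    return pmf


def harmonic_tail(n: int) -> Fraction:
    """Σ_{i=2}^{n} 1/i — the exact mean of D'_n (and half the mean of D_n)."""
    return sum((Fraction(1, i) for i in range(2, n + 1)), Fraction(0))


def poisson_depth_approximation_error(n: int) -> float:
    """Total-variation distance between D'_n and Poisson(ln n + γ − 1)."""
    dist = depth_distribution(n, "evolutionary")
    lam = math.log(n) + EULER_GAMMA - 1.0
    # sum |P(D'=k) − pois(k)| over a support comfortably covering both laws
    kmax = max(n, int(lam + 40 * math.sqrt(lam + 1)) + 10)
    log_lam = math.log(lam)
    tv = 0.0
    log_pois = -lam
    for k in range(0, kmax + 1):
        if k > 0:
            log_pois += log_lam - math.log(k)
        pois = math.exp(log_pois)
        p = float(dist[k]) if k < n else 0.0
        tv += abs(p - pois)
    return 0.5 * tv


# ---------------------------------------------------------------------------
# MRCA distance and top-of-tree shape


def mrca_geometric_limit(g: int) -> Fraction:
    """Limiting pmf (n → ∞) of the root-to-MRCA edge count for a uniform
    leaf pair of a YH tree: P(G = g) = (1/3)(2/3)^g."""
    if g < 0:
        raise TreeError("g must be >= 0")
    return Fraction(1, 3) * Fraction(2, 3) ** g


def mrca_root_distance_distribution(n: int, samples: int,
                                    seed=None) -> dict[int, float]:
    """Empirical law of the number of edges between the MRCA of a uniform
    leaf pair and the root, over YH samples."""
    if n < 2:
        raise TreeError("n must be >= 2")
    rng = _as_rng(seed)
    counts: dict[int, int] = {}
    for _ in range(samples):
        tree = yh_sample(n, rng)
        leaves = tree.leaves()
        i, j = rng.choice(len(leaves), size=2, replace=False)
        d = _mrca_depth(tree, leaves[int(i)], leaves[int(j)])
        counts[d] = counts.get(d, 0) + 1
    return {g: c / samples for g, c in sorted(counts.items())}


def _mrca_depth(tree: RootedPhyloTree, a: Node, b: Node) -> int:
    anc = set()
    v = a
    while v is not None:
        anc.add(id(v))
        v = v.parent
    v = b
    while id(v) not in anc:
        v = v.parent
    d = 0
    while v is not tree.root:
        v = v.parent
        d += 1
    return d


def top_shape_is_complete(tree: RootedPhyloTree, k: int) -> bool:
    """True iff the depth-≤k truncation of a binary tree is the complete
    shape τ_k (all 2^k truncation leaves at depth exactly k).

    For a binary tree this holds precisely when no leaf sits at depth < k.
    """
    if k < 1:
        raise TreeError("k must be >= 1")
    if not tree.is_binary():
        raise TreeError("top_shape_is_complete requires a binary tree")

    stack = [(tree.root, 0)]
    while stack:
        v, d = stack.pop()
        if v.is_leaf and d < k:
            return False
        if d < k:
            stack.extend((c, d + 1) for c in v.children)
    return True


# ---------------------------------------------------------------------------
# PDA facts and exhaustive-history oracles


def pda_single_leaf_root_probability(n: int) -> Fraction:
    """P(one of the two root subtrees is a single leaf) under PDA: n/(2n−3)."""
    if n < 2:
        raise TreeError("n must be >= 2")
    if n == 2:
        return Fraction(1)
    return Fraction(n, 2 * n - 3)


def root_split_size(tree: RootedPhyloTree, rng=None) -> int:
    """Leaf count of a uniformly chosen root subtree (binary tree)."""
    rng = _as_rng(rng)
    child = tree.root.children[int(rng.integers(2))]
    return len(tree.clade(child))


def has_single_leaf_root_subtree(tree: RootedPhyloTree) -> bool:
    return any(c.is_leaf for c in tree.root.children)


def enumerate_yh_histories(n: int):
    """Exhaustively enumerate YH attachment histories with offspring
    designations, each equally likely; yields (reduced_depths,
    evolutionary_depths) as leaf-indexed lists.

    This is the brute-force oracle behind the depth laws: there are
    2^{n-1}·(n−1)!/1 histories (choice of attachment leaf at each step and
    offspring designation at each split), every one with equal probability.
    """
    if not 2 <= n <= 8:
        raise TreeError("history enumeration supported for 2 <= n <= 8")

    # state: list of (reduced_depth, evol_depth) per current leaf
    def rec(leaves):
        if len(leaves) == n:
            yield ([d for d, _ in leaves], [e for _, e in leaves])
            return
        for i in range(len(leaves)):
            d, e = leaves[i]
            for off in range(2):
                # split leaf i: both children at reduced depth d+1;
                # the designated offspring gains one evolutionary step.
                child0 = (d + 1, e + off)
                child1 = (d + 1, e + (1 - off))
                yield from rec(leaves[:i] + [child0, child1]
                               + leaves[i + 1:])

    # root split: two leaves at reduced depth 1; one designated offspring
    for off in range(2):
        yield from rec([(1, off), (1, 1 - off)])


def exhaustive_depth_distribution(n: int, variant: str) -> dict[int, Fraction]:
    """Depth law computed by summing over every YH history (oracle path)."""
    totals: dict[int, Fraction] = {}
    histories = list(enumerate_yh_histories(n))
    m = len(histories)
    for red, evo in histories:
        depths = red if variant == "reduced" else evo
        for d in depths:
            totals[d] = totals.get(d, Fraction(0)) + Fraction(1, m * n)
    return totals


def shape_counts_from_samples(trees) -> dict[TreeShape, int]:
    counts: dict[TreeShape, int] = {}
    for t in trees:
        sh = shape_of(t)
        counts[sh] = counts.get(sh, 0) + 1
    return counts
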