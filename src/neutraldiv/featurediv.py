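"""Feature diversity on fixed trees: assignments, PD↔FD representability,
and a gain/loss model of feature evolution.

FD of a leaf subset Y is the total weight of the features carried by at
least one member of Y.  PD is the special case with one feature per edge
(weight ℓ_e, carried by the edge's descendant leaves); conversely an FD
function can be realized as PD on some tree iff the collection of feature
supports is nested (laminar) — equivalently, iff every feature admits a
single-gain/no-loss scenario.

The stochastic model: new features arise along edges as a Poisson process
with rate r per unit time (each feature arises exactly once in the tree) and
every feature copy is lost independently at rate ν along each branch; a loss
removes the feature from that branch's entire descendant subtree while
copies surviving on sibling branches persist.  Features may also arrive on a
stem edge above the root, with F_0 of them present at its very top.  Along a
single path of length L starting with no features, the count at the end is
Poisson with mean (r/ν)(1−e^{−νL}).

``expected_fd`` evaluates E[FD(Y)] exactly via an absence-probability
recursion, and ``edge_expected_feature_lengths`` builds the derived edge
weights ℓ'_e (expected number of features arising on e that reach at least
one leaf), the quantity through which expected-FD loss under a
field-of-bullets event is dominated by the corresponding PD(ℓ') loss.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

import numpy as np

from .treecore import Node, RootedPhyloTree, TreeError

_NU_SERIES_CUTOFF = 1e-8


class FeatureAssignment:
    """Leaf → feature-id sets plus strictly positive feature weights."""

    def __init__(self, features: Mapping[str, Iterable],
                 weights: Optional[Mapping] = None):
        self.features = {x: frozenset(fs) for x, fs in features.items()}
        all_features = frozenset().union(*self.features.values()) \
            if self.features else frozenset()
        if weights is None:
            weights = {f: 1 for f in all_features}
        self.weights = dict(weights)
        for f in all_features:
            if f not in self.weights:
                raise TreeError(f"feature {f!r} has no weight")
        for f, w in self.weights.items():
            if w <= 0:
                raise TreeError(f"feature {f!r} has non-positive weight")

    @property
    def leaf_labels(self) -> frozenset:
        return frozenset(self.features)

    @property
    def all_features(self) -> frozenset:
        return frozenset(self.weights)

    def support(self, f) -> frozenset:
        """X_f: the set of leaves carrying feature f."""
        return frozenset(x for x, fs in self.features.items() if f in fs)

    def supports(self) -> dict:
        return {f: self.support(f) for f in self.all_features}


def fd(assignment: FeatureAssignment, subset):
    """FD(Y): total weight of features present in at least one leaf of Y."""
    subset = frozenset(subset)
    unknown = subset - assignment.leaf_labels
    if unknown:
        raise TreeError(f"unknown leaves: {sorted(unknown)}")
    present = frozenset().union(*(assignment.features[x] for x in subset)) \
        if subset else frozenset()
    return sum(assignment.weights[f] for f in present)


# ---------------------------------------------------------------------------
# PD <-> FD representability


def pd_as_fd(tree: RootedPhyloTree) -> FeatureAssignment:
    """Encode PD as FD: one feature per edge with weight ℓ_e, carried by
    the edge's descendant leaves.  FD of the result equals PD for every
    subset."""
    if not tree.has_lengths():
        raise TreeError("edge lengths required")
    features = {x: set() for x in tree.leaf_labels}
    weights = {}
    for i, e in enumerate(tree.edges()):
        fid = f"edge{i}"
        weights[fid] = e.length
        for x in tree.clade(e):
            features[x].add(fid)
    return FeatureAssignment(features, weights)


def is_nested(assignment: FeatureAssignment) -> bool:
    """True iff the supports X_f form a laminar family
    (A∩B ∈ {A, B, ∅} for every pair)."""
    return _nested_violation(assignment) is None


def _nested_violation(assignment: FeatureAssignment):
    sups = list({s for s in assignment.supports().values()})
    for i in range(len(sups)):
        for j in range(i + 1, len(sups)):
            a, b = sups[i], sups[j]
            inter = a & b
            if inter and inter != a and inter != b:
                return (a, b)
    return None


def fd_to_pd_tree(assignment: FeatureAssignment):
    """Realize FD as PD on a tree when the supports are nested.

    Returns ``(tree, None)`` on success — a rooted tree with non-negative
    edge lengths (zero-length edges permitted here only) such that
    PD(Y) = FD(Y) for every subset Y — or ``(None, (A, B))`` with a
    violating support pair when the family is not laminar.
    """
    violation = _nested_violation(assignment)
    if violation is not None:
        return None, violation
    leaves = sorted(assignment.leaf_labels)
    weight_by_cluster: dict[frozenset, object] = {}
    for f, sup in assignment.supports().items():
        if not sup:
            continue
        weight_by_cluster[sup] = weight_by_cluster.get(sup, 0) \
            + assignment.weights[f]
    clusters = set(weight_by_cluster)
    clusters.add(frozenset(leaves))
    clusters.update(frozenset([x]) for x in leaves)
    ordered = sorted(clusters, key=lambda c: (-len(c), sorted(c)))
    nodes: dict[frozenset, Node] = {}
    for c in ordered:
        node = Node(label=next(iter(c)) if len(c) == 1 else None,
                    length=weight_by_cluster.get(c, 0))
        nodes[c] = node
        if len(c) < len(leaves):
            parent = min((p for p in ordered if len(p) > len(c) and c <= p),
                         key=len)
            nodes[parent].add(node)
    root = nodes[frozenset(leaves)]
    root.length = None  # any weight on the full set sits on the stem
    stem = weight_by_cluster.get(frozenset(leaves), 0)
    # collapse unary chains is unnecessary: PD sums are unaffected; but the
    # root must have out-degree >= 2 for a valid tree.
    while len(root.children) == 1:
        child = root.children[0]
        stem = stem + (child.length or 0)
        child.length = None
        child.parent = None
        root = child
    if root.is_leaf and root.label is None:
        return None, None  # degenerate: no leaves at all
    tree = RootedPhyloTree(root, stem_length=stem or None,
                           allow_zero_lengths=True)
    return tree, None


# ---------------------------------------------------------------------------
# Gain/loss simulation


@dataclass
class GainLossParams:
    """Feature gain rate r > 0 (per unit time per lineage), per-feature
    loss rate ν ≥ 0, and F_0 features present at the top of the stem."""
    r: float
    nu: float = 0.0
    f0: int = 0

    def __post_init__(self):
        if self.r <= 0:
            raise TreeError("gain rate r must be > 0")
        if self.nu < 0:
            raise TreeError("loss rate nu must be >= 0")
        if self.f0 < 0 or self.f0 != int(self.f0):
            raise TreeError("F_0 must be a non-negative integer")


@dataclass
class GainLossLog:
    """Event log of one simulation: where each feature arose and the leaf
    sets that retained it."""
    gains: list = field(default_factory=list)  # (feature id, edge idx, pos)
    retained: dict = field(default_factory=dict)  # feature id -> leaf set


def simulate_gain_loss(tree: RootedPhyloTree, params: GainLossParams,
                       seed=None):
    """Simulate the gain/loss process on a fixed tree (stem included).

    Returns ``(FeatureAssignment, GainLossLog)``: unit-weight features
    present at the leaves.  Gains on each edge are Poisson(r·ℓ) placed
    uniformly; each feature copy survives a branch of length ℓ with
    probability e^{−νℓ} independently per branch, and a loss silences the
    whole descendant subtree of that branch.
    """
    if not tree.has_lengths():
        raise TreeError("edge lengths required")
    rng = np.random.default_rng(seed) if not isinstance(
        seed, np.random.Generator) else seed
    log = GainLossLog()
    features: dict[str, set] = {x: set() for x in tree.leaf_labels}
    counter = [0]
    nu = params.nu

    def propagate(v: Node, fid) -> None:
        # feature present at the *top* of the edge above v; survive the edge
        if v.length and nu > 0 and rng.random() >= math.exp(-nu * v.length):
            return
        if v.is_leaf:
            log.retained.setdefault(fid, set()).add(v.label)
            features[v.label].add(fid)
        for c in v.children:
            propagate(c, fid)

    def seed_below(v: Node, fid) -> None:
        # feature present at the *bottom* of the edge above v
        if v.is_leaf:
            log.retained.setdefault(fid, set()).add(v.label)
            features[v.label].add(fid)
        for c in v.children:
            propagate(c, fid)

    edges = [("stem", tree.root, tree.stem_length or 0.0)]
    edges += [(i, e, e.length) for i, e in enumerate(tree.edges())]
    # F_0 features at the very top of the stem
    for _ in range(params.f0):
        counter[0] += 1
        fid = f"f{counter[0]}"
        log.gains.append((fid, "initial", 0.0))
        stem_len = tree.stem_length or 0.0
        if nu > 0 and stem_len > 0 and \
                rng.random() >= math.exp(-nu * stem_len):
            continue
        seed_below(tree.root, fid)
    for eid, bottom, length in edges:
        if length <= 0:
            continue
        k = rng.poisson(params.r * length)
        for _ in range(k):
            counter[0] += 1
            fid = f"f{counter[0]}"
            pos = rng.random() * length
            log.gains.append((fid, eid, pos))
            remaining = length - pos
            if nu > 0 and rng.random() >= math.exp(-nu * remaining):
                continue
            seed_below(bottom, fid)
    present = frozenset().union(*features.values()) if features else frozenset()
    assignment = FeatureAssignment(
        {x: fs for x, fs in features.items()},
        {f: 1 for f in present})
    return assignment, log


# ---------------------------------------------------------------------------
# Expected FD (exact recursion)


def _edge_gain_factor(r: float, nu: float, length) -> float:
    """Expected number of features that arise on an edge of this length and
    are still present at its bottom: r(1−e^{−νℓ})/ν, → rℓ as ν → 0."""
    if nu * length < _NU_SERIES_CUTOFF:
        return r * length * (1 - 0.5 * nu * length)
    return r * (1.0 - math.exp(-nu * length)) / nu


def _absence_probs(tree: RootedPhyloTree, nu: float, subset=None,
                   survival: Optional[float] = None) -> dict:
    """q_v = P(no leaf of interest below v retains a feature present at v).

    With ``subset`` the leaves of interest are fixed; with ``survival`` the
    FOB outcome is marginalized (q_leaf = 1−s).
    """
    if subset is not None:
        subset = frozenset(subset)
        unknown = subset - tree.leaf_labels
        if unknown:
            raise TreeError(f"unknown leaves: {sorted(unknown)}")
    q: dict[int, float] = {}
    for v in tree.postorder():
        if v.is_leaf:
            if survival is not None:
                q[id(v)] = 1.0 - survival
            else:
                q[id(v)] = 0.0 if v.label in subset else 1.0
        else:
            prod = 1.0
            for c in v.children:
                keep = math.exp(-nu * c.length) if nu > 0 else 1.0
                prod *= keep * q[id(c)] + (1.0 - keep)
            q[id(v)] = prod
    return q


def expected_fd(tree: RootedPhyloTree, params: GainLossParams,
                subset=None, survival: Optional[float] = None) -> float:
    """E[FD(Y)] (unit weights) under the gain/loss model, exactly.

    ``subset=None`` means Y = X.  ``survival=s`` instead marginalizes a FOB
    extinction with survival probability s over the leaves.  The stem edge
    and the F_0 initial features are included.
    """
    if not tree.has_lengths():
        raise TreeError("edge lengths required")
    if subset is None and survival is None:
        subset = tree.leaf_labels
    if survival is not None and not 0 <= survival <= 1:
        raise TreeError("survival must lie in [0, 1]")
    nu = params.nu
    q = _absence_probs(tree, nu, subset, survival)
    total = 0.0
    for e in tree.edges():
        total += _edge_gain_factor(params.r, nu, e.length) * (1 - q[id(e)])
    stem = tree.stem_length or 0.0
    qroot = q[id(tree.root)]
    if stem > 0:
        total += _edge_gain_factor(params.r, nu, stem) * (1 - qroot)
    if params.f0:
        keep = math.exp(-nu * stem) if nu > 0 else 1.0
        total += params.f0 * keep * (1 - qroot)
    return total


def edge_expected_feature_lengths(tree: RootedPhyloTree,
                                  params: GainLossParams) -> dict:
    """ℓ'_e: expected number of features arising on edge e that are present
    in at least one leaf of the tree.  Keys are edge handles (child nodes)
    plus ``"stem"``; Σ ℓ'_e = E[FD(X)] when F_0 = 0."""
    if not tree.has_lengths():
        raise TreeError("edge lengths required")
    nu = params.nu
    q = _absence_probs(tree, nu, tree.leaf_labels)
    out = {}
    for e in tree.edges():
        out[e] = _edge_gain_factor(params.r, nu, e.length) * (1 - q[id(e)])
    stem = tree.stem_length or 0.0
    out["stem"] = _edge_gain_factor(params.r, nu, stem) \
        * (1 - q[id(tree.root)]) if stem > 0 else 0.0
    return out


def proposition_fd_pd_gap(tree: RootedPhyloTree, params: GainLossParams,
                          s: float):
    """Compare expected-FD survival with the PD(ℓ') survival bound.

    Returns (lhs, rhs, gap) where
    lhs = E[FD(S)]/E[FD(X)] under FOB survival s,
    rhs = Σ_e ℓ'_e(1−(1−s)^{n_e}) / Σ_e ℓ'_e  (expected PD(ℓ') proportion),
    gap = rhs − lhs ≥ 0, with equality iff s ∈ {0,1} or the tree is a star.
    """
    if not 0 <= s <= 1:
        raise TreeError("s must lie in [0, 1]")
    p = GainLossParams(r=params.r, nu=params.nu, f0=0)
    denom = expected_fd(tree, p)
    lhs = expected_fd(tree, p, survival=s) / denom
    lengths = edge_expected_feature_lengths(tree, p)
    n = tree.n
    num = 0.0
    den = 0.0
    for e, lp in lengths.items():
        n_e = n if e == "stem" else len(tree.clade(e))
        num += lp * (1.0 - (1.0 - s) ** n_e)
        den += lp
    rhs = num / den
    return lhs, rhs, rhs - lhs


# alias matching the documented operation name
proposition5_check = proposition_fd_pd_gap
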