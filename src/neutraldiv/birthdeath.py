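"""Constant-rate (and hook-extensible neutral) birth–death tree simulation.

A realization starts from a single lineage at time 0.  Lineages split at per
capita rate λ and die at rate μ; at each split one daughter is designated the
*offspring* (new species) uniformly at random, so every realization carries
complete, reduced (reconstructed) and evolutionary views:

* complete tree — extinct and extant lineages;
* reduced tree — extinct lineages pruned, unary vertices suppressed
  (concatenating lengths), stem recorded separately;
* reduced evolutionary tree — additionally keeps the "new species" flags,
  dropping the flag of any lineage that branched off a lineage with no
  surviving descendants.

Rate hooks may replace the constant rates with functions of (time, lineage
count, event count); the per-lineage choice of who splits or dies stays
uniform, which is exactly the neutrality contract under which tree *shapes*
remain Yule–Harding distributed.

Edge-length laws for the Yule case (μ=0, sampled just before the n→n+1
split): a uniformly sampled pendant or interior edge is Exp(2λ); a root-child
edge has mean (1/λ)(1−1/n); the total length S_n is Gamma(n−1, λ).  For large
λt the longest pendant edge satisfies L_t/t → 1/2 in the reduced tree
(and → (1−μ/λ)/2 in the complete tree), while the shortest interior edge obeys
P(S_t ≥ x e^{−λt}/λ) → 1/(1+2x).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np

from .treecore import Node, RootedPhyloTree, TreeError

RateHook = Callable[[float, int, int], float]


@dataclass
class BDParams:
    """Birth–death parameters: λ > 0, μ ≥ 0 per lineage per unit time.

    ``birth_hook``/``death_hook`` optionally replace the constant rates with
    functions of (time, lineage count, event count); neutrality (uniform
    choice of the affected lineage) is built in and not overridable.
    """
    lam: float
    mu: float = 0.0
    t: Optional[float] = None
    birth_hook: Optional[RateHook] = None
    death_hook: Optional[RateHook] = None

    def __post_init__(self):
        if self.lam <= 0:
            raise TreeError("birth rate lambda must be > 0")
        if self.mu < 0:
            raise TreeError("death rate mu must be >= 0")
        if self.t is not None and self.t <= 0:
            raise TreeError("duration t must be > 0")

    def birth_rate(self, time: float, k: int, events: int) -> float:
        return self.birth_hook(time, k, events) if self.birth_hook else self.lam

    def death_rate(self, time: float, k: int, events: int) -> float:
        return self.death_hook(time, k, events) if self.death_hook else self.mu


class Lineage:
    __slots__ = ("parent", "children", "birth", "end", "extinct", "offspring")

    def __init__(self, parent, birth: float, offspring: bool):
        self.parent = parent
        self.children: list[Lineage] = []
        self.birth = birth
        self.end: Optional[float] = None
        self.extinct = False
        self.offspring = offspring

    @property
    def span(self) -> float:
        return self.end - self.birth


@dataclass
class BDRealization:
    """Full event history of one birth–death run plus derived tree views."""
    root: Lineage
    t: float
    params: BDParams
    seed_used: Optional[int] = None
    n_events: int = 0

    # -- basic queries --------------------------------------------------

    def extant_lineages(self) -> list[Lineage]:
        return [v for v in self._all() if not v.children and not v.extinct]

    def extinct_lineages(self) -> list[Lineage]:
        return [v for v in self._all() if v.extinct]

    @property
    def n_extant(self) -> int:
        return len(self.extant_lineages())

    def split_times(self) -> list[float]:
        """Sorted times of the splitting events (for a Yule run the gap
        between the k-th and (k+1)-th is Exp(kλ) while k lineages exist)."""
        return sorted(v.end for v in self._all() if v.children)

    def _all(self) -> list[Lineage]:
        out = []
        stack = [self.root]
        while stack:
            v = stack.pop()
            out.append(v)
            stack.extend(v.children)
        return out

    # -- views -----------------------------------------------------------

    def complete_tree(self, extinct_suffix: str = "*") -> RootedPhyloTree:
        """Tree over all lineages, extinct leaves tagged with a suffix."""
        counter = [0]

        def rec(lin: Lineage) -> Node:
            node = Node(length=lin.span if lin.span > 0 else None)
            node.horizontal = lin.offspring
            if lin.children:
                for c in lin.children:
                    node.add(rec(c))
            else:
                counter[0] += 1
                node.label = f"x{counter[0]}" + (
                    extinct_suffix if lin.extinct else "")
            return node

        root = rec(self.root)
        if root.is_leaf:
            # single lineage: the whole history is one (stem) edge
            stem = root.length
            root.length = None
            return RootedPhyloTree(root, stem_length=stem)
        return RootedPhyloTree(root, binary=True)

    def reduce(self) -> RootedPhyloTree:
        """Reduced (reconstructed) tree: extant lineages only, unary
        vertices suppressed, stem stored on ``stem_length``."""
        return self._reduced()

    def reduced_evolutionary(self) -> RootedPhyloTree:
        """Reduced tree whose edges carry ``horizontal`` (new species)
        flags after applying the no-surviving-taxa rule; use
        :func:`evolutionary_depth` for leaf depths."""
        return self._reduced()

    def _reduced(self) -> RootedPhyloTree:
        counter = [0]

        def rec(lin: Lineage) -> Optional[Node]:
            if not lin.children:
                if lin.extinct:
                    return None
                counter[0] += 1
                node = Node(f"x{counter[0]}", length=lin.span)
                node.horizontal = lin.offspring
                return node
            kids = [rec(c) for c in lin.children]
            kids = [k for k in kids if k is not None]
            if not kids:
                return None
            if len(kids) == 1:
                # suppressed split: the survivor continues the parent
                # lineage (it is not a new species if its sibling side
                # left no survivors), so the merged edge inherits this
                # lineage's own designation.
                child = kids[0]
                child.length += lin.span
                child.horizontal = lin.offspring
                return child
            node = Node(length=lin.span)
            node.horizontal = lin.offspring
            for k in kids:
                node.add(k)
            return node

        top = rec(self.root)
        if top is None:
            raise TreeError("realization is extinct: empty reduced tree")
        if top.is_leaf:
            stem = top.length
            top.length = None
            return RootedPhyloTree(top, stem_length=stem)
        stem = top.length
        top.length = None
        return RootedPhyloTree(top, stem_length=stem, binary=True)

    # -- length bookkeeping ----------------------------------------------

    def total_length_complete(self) -> float:
        return sum(v.span for v in self._all())

    def total_length_pruned(self) -> float:
        """Total lineage time removed when passing to the reduced view."""
        reduced = self.reduce()
        kept = reduced.total_length(include_stem=True)
        return self.total_length_complete() - kept


def evolutionary_depth(tree: RootedPhyloTree, label) -> int:
    """Number of new-species (horizontal) edges on the root path of a leaf."""
    return sum(1 for e in tree.path_to_leaf(label) if e.horizontal)


# ---------------------------------------------------------------------------
# Simulation


def simulate_bd(params: BDParams, seed=None, condition: str = "none",
                n: Optional[int] = None, max_tries: int = 100000
                ) -> BDRealization:
    """Exact Gillespie simulation of the birth–death tree.

    condition:
      * ``"none"`` — run for time ``params.t``;
      * ``"survival"`` — rejection-sample until N_t > 0;
      * ``"fixed_n"`` — run until the moment just before the split that
        would take the leaf count from ``n`` to ``n+1`` (the sampling
        convention under which the Yule edge-length laws hold).
    """
    rng = np.random.default_rng(seed) if not isinstance(
        seed, np.random.Generator) else seed
    if condition not in ("none", "survival", "fixed_n"):
        raise TreeError(f"unknown condition {condition!r}")
    if condition == "fixed_n":
        if n is None or n < 1:
            raise TreeError("fixed_n conditioning requires a target n >= 1")
    elif params.t is None:
        raise TreeError("duration t required unless conditioning on fixed_n")

    for attempt in range(max_tries):
        real = _run_once(params, rng, condition, n)
        if real is not None:
            return real
    raise TreeError(
        "conditioning failed within the retry cap; "
        "adjust rates, duration or the cap")


def _run_once(params, rng, condition, n_target):
    root = Lineage(None, 0.0, offspring=False)
    active = [root]
    time = 0.0
    events = 0
    t_end = params.t
    while True:
        k = len(active)
        if k == 0:
            if condition == "none":
                real = BDRealization(root, t_end, params, n_events=events)
                return real
            return None  # rejected (extinct)
        b = params.birth_rate(time, k, events)
        d = params.death_rate(time, k, events)
        total = k * (b + d)
        wait = rng.exponential(1.0 / total) if total > 0 else np.inf
        t_next = time + wait
        if condition != "fixed_n" and t_next >= t_end:
            for lin in active:
                lin.end = t_end
            real = BDRealization(root, t_end, params, n_events=events)
            if condition == "survival" and real.n_extant == 0:
                return None
            return real
        is_birth = (b + d <= 0) or (rng.random() < b / (b + d))
        if condition == "fixed_n" and k == n_target and is_birth:
            # sample the tree just before the n -> n+1 split
            for lin in active:
                lin.end = t_next
            return BDRealization(root, t_next, params, n_events=events)
        i = int(rng.integers(k))
        lin = active[i]
        lin.end = t_next
        if is_birth:
            off = int(rng.integers(2))
            for j in range(2):
                lin.children.append(Lineage(lin, t_next, offspring=(j == off)))
            active[i] = lin.children[0]
            active.append(lin.children[1])
        else:
            lin.extinct = True
            active[i] = active[-1]
            active.pop()
        time = t_next
        events += 1


# ---------------------------------------------------------------------------
# Edge-length statistics


def classify_edges(tree: RootedPhyloTree):
    """(pendant, interior, root_child) edge lists, stem excluded."""
    pendant, interior = [], []
    for e in tree.edges():
        (pendant if e.is_leaf else interior).append(e)
    root_children = list(tree.root.children)
    return pendant, interior, root_children


def edge_length_stats(trees, seed=None) -> dict:
    """Per-realization edge-length summaries over an ensemble of reduced
    trees (intended for fixed-n Yule ensembles).

    Returns arrays: a uniformly sampled pendant and interior edge length per
    tree, the root-child edge lengths, the total length S_n, the longest
    pendant and the shortest interior edge.
    """
    rng = np.random.default_rng(seed) if not isinstance(
        seed, np.random.Generator) else seed
    out = {"pendant_sample": [], "interior_sample": [], "root_child": [],
           "total_length": [], "longest_pendant": [], "shortest_interior": []}
    for tree in trees:
        pend, inter, rc = classify_edges(tree)
        if pend:
            out["pendant_sample"].append(
                pend[int(rng.integers(len(pend)))].length)
            out["longest_pendant"].append(max(e.length for e in pend))
        if inter:
            out["interior_sample"].append(
                inter[int(rng.integers(len(inter)))].length)
            out["shortest_interior"].append(min(e.length for e in inter))
        out["root_child"].extend(e.length for e in rc)
        out["total_length"].append(tree.total_length())
    return {k: np.asarray(v) for k, v in out.items()}


def longest_pendant_ratio(params: BDParams, seed=None, reps: int = 100,
                          view: str = "reduced") -> np.ndarray:
    """Ensemble of L_t/t ratios, conditioned on survival.

    ``view="reduced"`` measures the reconstructed tree (limit 1/2);
    ``view="complete"`` includes extinct lineages (limit (1−μ/λ)/2).
    """
    if params.lam <= params.mu:
        raise TreeError("longest_pendant_ratio requires lambda > mu")
    if view not in ("reduced", "complete"):
        raise TreeError(f"unknown view {view!r}")
    rng = np.random.default_rng(seed) if not isinstance(
        seed, np.random.Generator) else seed
    ratios = []
    for _ in range(reps):
        real = simulate_bd(params, rng, condition="survival")
        tree = real.reduce() if view == "reduced" else real.complete_tree()
        pend = [e for e in tree.edges() if e.is_leaf]
        if not pend:  # single-leaf tree: its only edge is the stem
            ratios.append(tree.stem_length / real.t)
            continue
        ratios.append(max(e.length for e in pend) / real.t)
    return np.asarray(ratios)


def shortest_interior_cdf(x: float) -> float:
    """Limiting P(S_t ≥ x e^{−λt}/λ) for the shortest interior edge of a
    Yule tree as λt → ∞: equals 1/(1+2x)."""
    if x < 0:
        raise TreeError("x must be >= 0")
    return 1.0 / (1.0 + 2.0 * x)


def shortest_interior_empirical(lam: float, t: float, x: float,
                                reps: int = 200, seed=None) -> float:
    """Monte Carlo estimate of P(S_t ≥ x e^{−λt}/λ) on simulated Yule trees.

    Uses a flat event-driven Yule pass (no tree objects): an interior edge
    is any edge that starts and ends at a split, the stem excluded, so the
    minimum is tracked from the split times alone.
    """
    rng = np.random.default_rng(seed) if not isinstance(
        seed, np.random.Generator) else seed
    threshold = x * np.exp(-lam * t) / lam
    hits = 0
    for _ in range(reps):
        if _yule_min_interior(lam, t, rng) >= threshold:
            hits += 1
    return hits / reps


def _yule_min_interior(lam: float, t: float, rng) -> float:
    # birth times of active lineages; index 0 is the initial lineage
    birth = np.zeros(4096)
    k = 1
    time = 0.0
    smin = np.inf
    # pre-draw in blocks to keep the loop lean
    while True:
        waits = rng.exponential(1.0, size=2048)
        picks = rng.random(size=2048)
        for w, p in zip(waits, picks):
            time += w / (k * lam)
            if time >= t:
                return smin
            i = int(p * k)
            b = birth[i]
            if b > 0.0:
                d = time - b
                if d < smin:
                    smin = d
            if k + 1 > birth.size:
                birth = np.resize(birth, birth.size * 2)
            birth[i] = time
            birth[k] = time
            k += 1
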