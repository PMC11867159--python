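"""Phylogenetic diversity: PD, PD maximization, PD indices, and loss of PD
under field-of-bullets extinction.

PD of a leaf subset Y on a rooted tree (T, ℓ) is the total length of the
edges whose descendant leaves intersect Y — i.e. the rooted spanning subtree.
PD is monotone and submodular, and a size-k subset of maximum PD is found by
a greedy algorithm (the strong exchange property makes greedy exact).

*PD indices* apportion total PD over the leaves: fair proportion (FP, a.k.a.
evolutionary distinctiveness) shares each edge equally among its descendant
leaves and equals the Shapley value of the induced cooperative game; equal
splits (ES) halves an edge's credit at every junction on the way down.

Under the (generalized) field-of-bullets model, species x survives a rapid
extinction event with probability 1−ε_x independently.  The expected
proportion of PD lost is  Σ_e ℓ_e Π_{x∈C(e)} ε_x / Σ_e ℓ_e,  and the
per-species expectations ψ_x (expected extra PD if x survives) and
ψ'_x = ψ_x·ε_x underpin the EDGE2 prioritisation protocol.  With a uniform
prior on a common ε, E[ψ_x(ε)] collapses to FP(x) exactly.

For birth–death trees, the limiting expected proportion of PD that survives
a field-of-bullets event with survival probability s is

    φ_PD(s) = s·ln(1/s)/(1−s)                      (Yule, μ=0)
    φ_PD(s) = ρs/(ρ+s−1) · ln(s/(1−ρ))/ln(1/(1−ρ))  (ρ=μ/λ ∉ {0, 1−s})
    φ_PD(s) = (1−s)/ln(1/s)                         (ρ = 1−s)

an increasing concave function with φ_PD(s) ≥ s.
"""

from __future__ import annotations

import itertools
import math
from fractions import Fraction
from typing import Iterable, Mapping, Union

import numpy as np

from .treecore import Node, RootedPhyloTree, TreeError
from .birthdeath import BDParams, simulate_bd


# ---------------------------------------------------------------------------
# Extinction models


class ExtinctionModel:
    """Independent per-leaf extinction probabilities (gFOB).

    ``ExtinctionModel.fob(eps)`` builds the constant-probability special
    case; ``survival`` gives the complementary view (s = 1−ε).
    """

    def __init__(self, eps: Mapping[str, float] = None, default=None):
        self.eps = dict(eps or {})
        self.default = default
        for x, e in self.eps.items():
            _check_prob(e, f"epsilon[{x}]")
        if default is not None:
            _check_prob(default, "epsilon")

    @classmethod
    def fob(cls, eps: float) -> "ExtinctionModel":
        return cls(default=eps)

    @classmethod
    def from_survival(cls, s: float) -> "ExtinctionModel":
        _check_prob(s, "s")
        return cls(default=1 - s)

    def epsilon(self, leaf: str):
        if leaf in self.eps:
            return self.eps[leaf]
        if self.default is None:
            raise TreeError(f"no extinction probability for leaf {leaf!r}")
        return self.default

    def sample_survivors(self, labels: Iterable[str], rng) -> frozenset:
        return frozenset(x for x in labels
                         if rng.random() >= float(self.epsilon(x)))


def _check_prob(p, name):
    if not 0 <= p <= 1:
        raise TreeError(f"{name} must lie in [0, 1], got {p}")


# ---------------------------------------------------------------------------
# PD and PD maximization


def pd(tree: RootedPhyloTree, subset, include_stem: bool = False):
    """Phylogenetic diversity of ``subset``: Σ ℓ_e over edges whose clade
    meets the subset.  Rooted convention: edges up to the root count even if
    the subset sits inside one subtree."""
    subset = frozenset(subset)
    unknown = subset - tree.leaf_labels
    if unknown:
        raise TreeError(f"unknown leaves in subset: {sorted(unknown)}")
    if not subset:
        return 0
    total = 0

    def rec(v: Node) -> bool:
        hit = (v.label in subset) if v.is_leaf else False
        for c in v.children:
            hit |= rec(c)
        nonlocal total
        if hit and v.parent is not None:
            if v.length is None:
                raise TreeError("edge lengths required for PD")
            total += v.length
        return hit

    rec(tree.root)
    if include_stem and tree.stem_length is not None:
        total += tree.stem_length
    return total


def max_pd_subset(tree: RootedPhyloTree, k: int):
    """Greedy PD-maximal subset of size k (provably optimal for PD).

    Ties are broken toward the lexicographically smallest leaf label so the
    output is deterministic.  Returns (subset, PD value).
    """
    labels = sorted(tree.leaf_labels)
    if not 1 <= k <= len(labels):
        raise TreeError(f"k must be in 1..{len(labels)}")
    chosen: list[str] = []
    current = 0
    for _ in range(k):
        best, best_gain = None, None
        for x in labels:
            if x in chosen:
                continue
            gain = pd(tree, chosen + [x]) - current
            if best_gain is None or gain > best_gain:
                best, best_gain = x, gain
        chosen.append(best)
        current += best_gain
    return frozenset(chosen), current


# ---------------------------------------------------------------------------
# PD indices


class PDIndexSpec:
    """Which apportionment rule to use: "fp", "es", or a convex mix."""

    def __init__(self, rule: str = "fp", alpha: float = None):
        if rule not in ("fp", "es", "mix"):
            raise TreeError(f"unknown PD index rule {rule!r}")
        if rule == "mix":
            if alpha is None or not 0 <= alpha <= 1:
                raise TreeError("mix rule needs a weight alpha in [0, 1]")
        self.rule = rule
        self.alpha = alpha


def pd_index(tree: RootedPhyloTree, spec: Union[PDIndexSpec, str] = "fp"
             ) -> dict:
    """Per-leaf PD index values; Σ_x I(x) = PD(X) by construction."""
    if isinstance(spec, str):
        spec = PDIndexSpec(spec)
    if not tree.has_lengths():
        raise TreeError("edge lengths required for PD indices")
    if spec.rule == "fp":
        return _fp(tree)
    if spec.rule == "es":
        return _es(tree)
    fp_vals, es_vals = _fp(tree), _es(tree)
    a = spec.alpha
    return {x: a * fp_vals[x] + (1 - a) * es_vals[x] for x in fp_vals}


def _fp(tree: RootedPhyloTree) -> dict:
    values = {x: 0 for x in tree.leaf_labels}
    for e in tree.edges():
        cl = tree.clade(e)
        share = e.length / len(cl)
        for x in cl:
            values[x] = values[x] + share
    return values


def _es(tree: RootedPhyloTree) -> dict:
    values = {x: 0 for x in tree.leaf_labels}

    def rec(v: Node, credit):
        # credit: amount arriving at the top of the edge above v
        total = credit + (v.length if v.parent is not None else 0)
        if v.is_leaf:
            values[v.label] = values[v.label] + total
            return
        share = total / len(v.children)
        for c in v.children:
            rec(c, share)

    # the root itself splits nothing: each child edge starts with 0 credit
    for c in tree.root.children:
        rec(c, 0)
    return values


def shapley_oracle(tree: RootedPhyloTree, leaf: str) -> Fraction:
    """Shapley value of a leaf in the PD cooperative game, by exhaustive
    subset enumeration (n ≤ 8); equals FP(x) exactly."""
    labels = sorted(tree.leaf_labels)
    n = len(labels)
    if n > 8:
        raise TreeError("shapley_oracle refuses n > 8")
    if leaf not in labels:
        raise TreeError(f"unknown leaf {leaf!r}")
    others = [x for x in labels if x != leaf]
    nfact = math.factorial(n)
    total = Fraction(0)
    for r in range(len(others) + 1):
        weight = Fraction(math.factorial(r) * math.factorial(n - r - 1),
                          nfact)
        for S in itertools.combinations(others, r):
            marginal = pd(tree, S + (leaf,)) - pd(tree, S)
            total += weight * Fraction(marginal)
    return total


def index_subset_inequality_check(tree: RootedPhyloTree, spec, subset):
    """(Σ_{x∈Y} I(x), PD(Y), gap).  The gap is always ≥ 0; it vanishes for
    Y = X and on star trees."""
    subset = frozenset(subset)
    vals = pd_index(tree, spec)
    s = sum(vals[x] for x in subset)
    p = pd(tree, subset)
    return s, p, p - s


# ---------------------------------------------------------------------------
# Expected PD loss and the psi indices


def expected_pd_loss(tree: RootedPhyloTree, model: ExtinctionModel):
    """Expected proportion of PD lost under the gFOB model:
    Σ_e ℓ_e Π_{x∈C(e)} ε_x / Σ_e ℓ_e."""
    num = 0
    den = 0
    for e in tree.edges():
        if e.length is None:
            raise TreeError("edge lengths required")
        den += e.length
        prod = 1
        for x in tree.clade(e):
            prod *= model.epsilon(x)
        num += e.length * prod
    return num / den


def simulate_pd_loss(tree: RootedPhyloTree, model: ExtinctionModel,
                     reps: int, seed=None) -> np.ndarray:
    """Monte Carlo proportions of PD lost over simulated extinction draws."""
    rng = np.random.default_rng(seed) if not isinstance(
        seed, np.random.Generator) else seed
    total = float(tree.total_length())
    labels = tree.leaf_labels
    out = np.empty(reps)
    for i in range(reps):
        survivors = model.sample_survivors(labels, rng)
        out[i] = 1.0 - float(pd(tree, survivors)) / total
    return out


def psi(tree: RootedPhyloTree, model: ExtinctionModel, leaf: str):
    """ψ_x = Σ_{e∈P(x)} ℓ_e Π_{s∈C(e)∖{x}} ε_s — expected additional PD if
    species x is present at the future time."""
    total = 0
    for e in tree.path_to_leaf(leaf):
        prod = 1
        for x in tree.clade(e):
            if x != leaf:
                prod *= model.epsilon(x)
        total += e.length * prod
    return total


def psi_prime(tree: RootedPhyloTree, model: ExtinctionModel, leaf: str):
    """ψ'_x = ψ_x · ε_x — expected additional PD of certainty about x."""
    return psi(tree, model, leaf) * model.epsilon(leaf)


def fp_as_expected_psi(tree: RootedPhyloTree, leaf: str):
    """(FP(x), ∫₀¹ ψ_x(ε) dε) with the integral done term-by-term on the
    polynomial ψ_x(ε) = Σ_e ℓ_e ε^{n_e−1}; the two agree exactly."""
    fp_val = pd_index(tree, "fp")[leaf]
    integral = 0
    for e in tree.path_to_leaf(leaf):
        n_e = len(tree.clade(e))
        integral += e.length * Fraction(1, n_e) if isinstance(
            e.length, Fraction) else e.length / n_e
    return fp_val, integral


def psi_polynomial(tree: RootedPhyloTree, leaf: str) -> dict[int, float]:
    """Coefficients {power: coeff} of ψ_x as a polynomial in a common ε."""
    coeffs: dict[int, float] = {}
    for e in tree.path_to_leaf(leaf):
        p = len(tree.clade(e)) - 1
        coeffs[p] = coeffs.get(p, 0) + e.length
    return coeffs


# ---------------------------------------------------------------------------
# phi_PD: limiting proportion of PD surviving a FOB event


_BRANCH_TOL = 1e-12


def phi_pd(s: float, lam: float, mu: float = 0.0) -> float:
    """Limiting expected proportion of PD surviving a FOB event with
    survival probability s on a large birth–death tree (λ > μ ≥ 0)."""
    if not 0 <= s <= 1:
        raise TreeError("s must lie in [0, 1]")
    if mu < 0 or lam <= mu:
        raise TreeError("phi_pd requires lambda > mu >= 0")
    if s == 0:
        return 0.0
    if s == 1:
        return 1.0
    rho = mu / lam
    if rho < _BRANCH_TOL:
        return s * math.log(1 / s) / (1 - s)
    delta = rho + s - 1
    if abs(delta) < 1e-6:
        # removable singularity at rho = 1-s: series in delta avoids the
        # catastrophic cancellation of the closed form
        series = 1 + delta / (2 * s) + delta ** 2 / (3 * s ** 2) \
            + delta ** 3 / (4 * s ** 3)
        return rho * series / math.log(1 / (1 - rho))
    return (rho * s / delta
            * math.log(s / (1 - rho)) / math.log(1 / (1 - rho)))


def expected_edges_with_k_descendants(n: int, k: int) -> float:
    """YH expectation of the number of edges with k ≤ n−1 descendant
    leaves, 2n/(k(k+1)); exact (= n, the pendant count) at k = 1."""
    if not 1 <= k <= n - 1:
        raise TreeError("k must lie in 1..n-1")
    return 2 * n / (k * (k + 1))


def phi_pd_yh_sum(s: float, n: int) -> float:
    """Finite-n YH heuristic Σ_k (1/(k(k+1)))(1−(1−s)^k) for φ_PD (Yule)."""
    return sum((1.0 - (1.0 - s) ** k) / (k * (k + 1))
               for k in range(1, n))


def phi_pd_empirical(lam: float, mu: float, s: float, t: float,
                     reps: int, seed=None) -> np.ndarray:
    """Ensemble of PD(Y_t)/PD(X_t) ratios over survival-conditioned
    birth–death trees with FOB survival probability s."""
    if lam <= mu:
        raise TreeError("requires lambda > mu")
    rng = np.random.default_rng(seed) if not isinstance(
        seed, np.random.Generator) else seed
    params = BDParams(lam=lam, mu=mu, t=t)
    model = ExtinctionModel.from_survival(s)
    out = np.empty(reps)
    for i in range(reps):
        real = simulate_bd(params, rng, condition="survival")
        tree = real.reduce()
        total = float(tree.total_length())
        if total == 0:  # single-leaf tree: only a stem
            out[i] = 1.0 if rng.random() < s else 0.0
            continue
        survivors = model.sample_survivors(tree.leaf_labels, rng)
        out[i] = float(pd(tree, survivors)) / total
    return out


def mean_fp_yule(lam: float, t: float) -> float:
    """E[FP of a random leaf] for a Yule tree grown for time t:
    (1/λ)(1 + e^{−λt}); converges to 1/λ as t → ∞."""
    if lam <= 0 or t < 0:
        raise TreeError("requires lambda > 0 and t >= 0")
    return (1.0 + math.exp(-lam * t)) / lam
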