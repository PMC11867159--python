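# Methods

This note records the modelling conventions, numerical choices and test
design behind `neutraldiv`, in the spirit of a model-documentation page.

## Tree model and conventions

A phylogenetic tree is rooted, edges directed away from the root, leaves
labelled, interior vertices of out-degree ≥ 2 (exactly 2 in the binary
case), and edge lengths strictly positive when present (time units).  An
optional *stem* edge above the root is stored as a flagged length rather
than an extra vertex; the stem is excluded from PD sums and from edge-length
statistics by default, because diversity measures are defined on the tree
proper while the feature process needs the stem only as a place where
features can arise before the first split.  Zero-length edges are permitted
in exactly one place: the tree constructed when an FD function is realized
as PD, where the construction requires non-negative rather than positive
lengths (structural edges carrying no feature weight).

The single-leaf tree is legal for the simulators (a birth–death run may end
before the first split); shape and probability operations require n ≥ 2.

Canonical shapes encode each subtree recursively and sort the two child
encodings, so isomorphism is string equality and the symmetry-vertex count
s(τ) is read off as the number of vertices with equal child encodings.  The
root counts as a symmetry vertex when its two child subtrees are isomorphic
— the convention fixed by the five-leaf worked example, whose shape has
s(τ)=3 including the cherries' parent but not the root.

## Exact versus floating arithmetic

All small-case probabilities (Yule–Harding shape and tree probabilities,
depth distributions, Stirling numbers) use `fractions.Fraction`, so the
worked examples (1/6, 1/90, 2/3, (1/3, 1/2, 1/6)) are bit-exact.  Depth
distributions switch to floats above n = 150, using the cycle-count
representation (the number of cycles of a uniform n-permutation is a sum of
independent Bernoulli(1/i), so the Stirling ratios c(n,k)/n! follow by an
O(n²) stable convolution) rather than big-integer tables; the two paths
agree to machine precision at the crossover.

## Birth–death simulation

Exact Gillespie simulation: with k lineages at time t the next event is
drawn at total rate k(λ+μ) and the affected lineage uniformly.  Rate hooks
may make λ and μ depend on (time, lineage count, event count); the uniform
per-lineage choice is built in, which is precisely the neutrality contract
under which reduced-tree shapes stay Yule–Harding distributed — the suite
verifies this for a strongly time-inhomogeneous birth rate λ(t) = λ₀(1+sin t).

Conditioning semantics:

* `survival` — rejection sampling on N_t > 0 (unbiased for conditional laws);
* `fixed_n` — the run stops at the instant just before the split that would
  take the leaf count from n to n+1; this is the sampling convention under
  which the Yule edge-length laws (Exp(2λ) sampled edges, Gamma(n−1, λ)
  total length, root-child mean (1/λ)(1−1/n)) hold.

At every split one daughter is designated the *offspring* (new species)
uniformly at random.  The reduced evolutionary tree prunes extinct lineages
and suppresses the resulting unary vertices; a suppressed split's surviving
child inherits the parent lineage's designation, implementing the rule that
a lineage is not a new species if it branched off a lineage with no
surviving descendants.  With uniform designation the discrete Yule–Harding
leaf-attachment sampler and the continuous-time simulator induce the same
evolutionary-depth law (the two designations at a split produce the same
depth multiset), which the exhaustive-history oracle confirms for n ≤ 6.

## Diversity measures

PD is rooted: an edge contributes to PD(Y) whenever its clade meets Y, so
root-path edges count even when Y lies inside one subtree.  Greedy subset
selection is provably optimal for PD and is made deterministic by breaking
ties toward the lexicographically smallest label.  Fair proportion and equal
splits are computed by direct coefficient evaluation; the Shapley value
(exhaustive over coalitions, n ≤ 8, exact rationals) is kept as an
independent oracle, never as the implementation.  ψ and ψ′ are deliberately
segregated from the PD-index API because they do not sum to PD(X).

The uniform-ε identity FP(x) = E[ψ_x(ε)] is evaluated symbolically: ψ_x(ε)
is the polynomial Σ_e ℓ_e ε^{n_e−1}, and term-wise integration gives
Σ_e ℓ_e/n_e exactly; adaptive quadrature of ψ_x(ε) is the independent
cross-check in the tests.

φ_PD branch handling: the main μ>0 expression has a removable singularity
at ρ = 1−s; within |ρ+s−1| < 10⁻⁶ a fourth-order series in δ = ρ+s−1 is
used, which restores one-sided continuity to better than 10⁻⁸ (the raw
closed form loses ~8 digits to cancellation at |δ| ≈ 10⁻⁹).

## Feature gain/loss model

New features arise along each edge as a Poisson process with rate r per
unit time (each feature arises exactly once in the whole tree); every
feature copy is lost independently at rate ν on each branch, and a loss on a
branch silences the feature in that branch's entire descendant subtree while
copies on sibling branches persist.  This is the reading that reproduces the
single-path law (count at the end of a path of length L, starting empty, is
Poisson with mean (r/ν)(1−e^{−νL})) and makes the per-feature carrier count
a linear birth–death process with birth λ and death θ = μ+ν on a growing
tree.  F₀ features may be present at the very top of the stem; the default
F₀ = 0 matches the convention that no features exist at time 0.

`expected_fd` is exact, via the absence-probability recursion
q_v = Π_children (e^{−νℓ_c} q_c + 1 − e^{−νℓ_c}) with q_leaf = 0 on leaves
of interest (or 1−s when a field-of-bullets outcome is marginalized), each
edge contributing r(1−e^{−νℓ})/ν · (1−q_bottom).  For νℓ < 10⁻⁸ the gain
factor switches to a second-order series to remain continuous with the ν=0
closed form rℓ.  The derived edge weights ℓ′_e (expected features arising
on e that reach at least one leaf) satisfy Σ_e ℓ′_e = E[FD(X)] by
construction, which the tests assert rather than assume.

### The FD-versus-PD(ℓ′) bound and star trees

The expected-FD surviving proportion is bounded by the corresponding
PD(ℓ′) proportion; per edge, the pendant terms are exact equalities while
interior-edge terms are strict for ν > 0 and 0 < s < 1.  A positive-length
stem behaves like an interior edge here, so a star tree *with* a stem gives
a strictly positive gap; the equality case "star tree" therefore refers to
stars without a stem (or zero-length stem), and that is how the equality
assertions are set up.  The inequality itself is swept over 10³ random
lengthed trees with stems and held with no violation.

## φ_FD numerics

Writing θ = μ+ν and using the sampled-survival probability R_u^s(λ,θ) of a
linear birth–death process, φ_FD(s) is the ratio
∫₀^∞ e^{−(λ−μ)u} R_u^s du / ∫₀^∞ e^{−(λ−μ)u} R_u^1 du.  This form is
branch-free across θ = λ (the R formula handles its own critical case), is
evaluated by adaptive quadrature at 10⁻¹¹ relative tolerance, and is exactly
equivalent to the s·I(s)/I(1) formulation with g_s in the denominator of the
integrand.  For ν > 0 the integral is not an elementary sum of exponentials
(the substitution u = e^{−(λ−μ−ν)τ} leads to an incomplete-Beta form), so
quadrature is the primary path; two closed forms serve as independent
cross-checks in the tests: ν = 0 must reproduce φ_PD (agreement to ≤ 10⁻⁹
across an s-grid), and the critical case ρ = (μ+ν)/λ = 1 has the
exponential-integral form I(s) = e^{a/(λs)}E₁(a/(λs))/(λs), a = λ−μ
(agreement to ≤ 10⁻⁸).  R_u^s itself is evaluated in a scaled form when
θ > λ so that no exponential overflows.

φ_FD does not depend on the gain rate r; the API encodes this by not taking
r at all.  The ν-monotonicity scan reports φ_FD along a ν grid, flags any
non-monotone pair and any point above φ_PD, and is a *reporting* tool: the
strict decrease in ν is proved only at ρ = 1 and conjectured elsewhere, so
violations would be surfaced rather than asserted away (none were observed).

## Synthetic data and what the tests do (and do not) show

All data are simulated or constructed; there are no empirical trees.  The
random-tree workhorse draws a Yule–Harding topology with i.i.d. exponential
edge lengths — a deliberately generic lengthed tree, not an ultrametric one,
matching the fixed-tree results which allow arbitrary positive lengths.
The gain/loss worked example (five features among six leaves, three leaves
extinct, three features surviving, ratio 0.6) is a synthetic scenario
constructed to match the published summary of that example; the five-lineage
event history used to exercise the reduced/evolutionary views is likewise
hand-built.  Passing tests validate the mathematics and the implementation
on neutral-model data; they say nothing about how well neutral models fit
real phylogenies (empirical trees are typically less balanced than
Yule–Harding predicts).

Monte Carlo problem sizes were chosen to give comfortable statistical power
on a single CPU: distributional tests run at α = 0.001 with 2000–8000
replicates (Kolmogorov–Smirnov and χ² against the exact laws), moment checks
use 3σ bands, and every stochastic test fixes its seed.  The three-layer
check of φ_FD runs at λ = 1, μ = 0.4, ν = 0.5, s = 0.5, t = 9 (λt = 9):
the positive death rate keeps conditioned trees at a few hundred leaves
while (λ−μ)t = 5.4 makes the finite-t bias (~e^{−(λ−μ)t}) negligible
against the ±0.02 acceptance band; a 1500-replicate ensemble reproduced
φ_FD = 0.6472 within 0.005 in pilot runs.

## Known limitations

* The asymptotic normality of PD loss on large trees is checked only as a
  skewness trend, not re-proved.
* Exact characterization of which tree shapes admit an exact PD
  representation of *expected* FD (beyond the ν=0 case and the nested
  combinatorial setting) is not implemented.
* Unrooted trees, phylogenetic networks, extinction cascades, correlated
  extinction risks, multi-origin features and Red-List-based extinction
  probabilities are out of scope.
* `fixed_n` conditioning with μ > 0 stops at the first n→n+1 transition;
  other conditioning conventions (e.g. uniform sampling among times with n
  leaves) are not offered.
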