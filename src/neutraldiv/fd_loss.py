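"""Loss of feature diversity on birth–death trees: the three-layer process.

Layers: (1) a birth–death tree grown for time t with rates λ, μ; (2) the
feature gain/loss process with rates r, ν running along its branches;
(3) a field-of-bullets extinction at the present with per-species survival
probability s.

The count of species carrying one particular feature (born at time t₀)
evolves as a linear birth–death process with birth rate λ and death rate
θ = μ + ν, sampled at the present with probability s per individual.  Its
survival probability is

    R_t^s(λ,θ) = s(λ−θ) / (sλ + (λ(1−s)−θ)e^{(θ−λ)t})   (λ ≠ θ)
               = s / (1 + λst)                            (λ = θ)

which gives the exact expected number of surviving features

    E[F_t^s] = ∫₀ᵗ r e^{(λ−μ)τ} R_{t−τ}^s(λ, μ+ν) dτ + F₀ R_t^s(λ, μ+ν).

Dividing by the s=1 case and letting t → ∞ yields the limiting surviving
proportion φ_FD(s) = lim E[F_t^s]/E[F_t].  Writing ρ = (μ+ν)/λ and

    g_s(τ) = (1−s−ρ) e^{−λ(1−ρ)τ} + s    (ρ ≠ 1),   1 + λsτ   (ρ = 1),

one has R_u^s = s(1−ρ)/g_s(u) (resp. s/g_s(u)), so φ_FD(s) = s·I(s)/I(1)
with I(s) = ∫₀^∞ e^{−(λ−μ)τ} / g_s(τ) dτ.  φ_FD is increasing and concave
with s ≤ φ_FD(s) ≤ 1, does not depend on r, equals φ_PD when ν = 0, and
tends to s as ν → ∞.  Numerically I(s) is evaluated by adaptive quadrature
on the R_u^s form (branch-free across ρ = 1); the exact ν = 0 (= φ_PD) and
ρ = 1 (exponential-integral) closed forms serve as cross-checks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import integrate, special

from .treecore import TreeError
from .birthdeath import BDParams, simulate_bd
from .featurediv import GainLossParams, simulate_gain_loss
from .phylodiv import phi_pd


@dataclass
class ThreeLayerParams:
    """Parameter bundle for the tree + feature + extinction layers."""
    lam: float
    mu: float = 0.0
    r: float = 1.0
    nu: float = 0.0
    s: float = 1.0
    t: float = 1.0
    f0: int = 0

    def __post_init__(self):
        if self.lam <= 0 or self.mu < 0 or self.nu < 0 or self.r <= 0:
            raise TreeError("rates must satisfy lambda, r > 0; mu, nu >= 0")
        if not 0 <= self.s <= 1:
            raise TreeError("s must lie in [0, 1]")
        if self.t <= 0:
            raise TreeError("t must be > 0")

    @property
    def theta(self) -> float:
        """Per-capita loss rate of a feature's carrier count: μ + ν."""
        return self.mu + self.nu

    @property
    def rho(self) -> float:
        return self.theta / self.lam


def r_survival(t: float, s: float, lam: float, theta: float) -> float:
    """R_t^s(λ,θ): probability that a linear birth–death process (birth λ,
    death θ) started from one individual has ≥1 sampled survivor at time t
    (each survivor sampled independently with probability s)."""
    if t < 0 or lam <= 0 or theta < 0:
        raise TreeError("require t >= 0, lambda > 0, theta >= 0")
    if not 0 <= s <= 1:
        raise TreeError("s must lie in [0, 1]")
    if s == 0:
        return 0.0
    if abs(lam - theta) < 1e-12 * lam:
        return s / (1.0 + lam * s * t)
    if theta < lam:
        return (s * (lam - theta)
                / (s * lam
                   + (lam * (1 - s) - theta) * math.exp((theta - lam) * t)))
    # theta > lam: scale by e^{(lam-theta)t} so nothing overflows
    decay = math.exp((lam - theta) * t)
    return (s * (lam - theta) * decay
            / (s * lam * decay + lam * (1 - s) - theta))


def expected_features_surviving(t: float, params: ThreeLayerParams,
                                rtol: float = 1e-8) -> float:
    """E[F_t^s]: expected number of features present among the post-FOB
    leaves, by quadrature of the exact integral formula."""
    lam, mu, theta, s = params.lam, params.mu, params.theta, params.s
    if s == 0:
        return 0.0

    def integrand(tau):
        return params.r * math.exp((lam - mu) * tau) \
            * r_survival(t - tau, s, lam, theta)

    val, err = integrate.quad(integrand, 0.0, t, epsrel=rtol, limit=200)
    if not math.isfinite(val) or (val > 0 and err > 1e-4 * max(val, 1.0)):
        raise TreeError(f"quadrature failed: value={val}, err={err}")
    return val + params.f0 * r_survival(t, s, lam, theta)


def _survival_integral(s: float, lam: float, mu: float, nu: float) -> float:
    """∫₀^∞ e^{−(λ−μ)u} R_u^s(λ, μ+ν) du, by adaptive quadrature."""
    theta = mu + nu

    def integrand(u):
        return math.exp(-(lam - mu) * u) * r_survival(u, s, lam, theta)

    val, err = integrate.quad(integrand, 0.0, np.inf,
                              epsabs=1e-13, epsrel=1e-11, limit=400)
    return val


def phi_fd(s: float, lam: float, mu: float = 0.0, nu: float = 0.0) -> float:
    """Limiting expected proportion of FD surviving a FOB event with
    survival probability s (λ > μ; independent of the gain rate r)."""
    if not 0 <= s <= 1:
        raise TreeError("s must lie in [0, 1]")
    if mu < 0 or nu < 0 or lam <= mu:
        raise TreeError("phi_fd requires lambda > mu >= 0 and nu >= 0")
    if s == 0:
        return 0.0
    if s == 1:
        return 1.0
    if nu == 0:
        return phi_pd(s, lam, mu)
    return _survival_integral(s, lam, mu, nu) \
        / _survival_integral(1.0, lam, mu, nu)


def phi_fd_critical(s: float, lam: float, mu: float, nu: float) -> float:
    """Closed form at the critical feature layer ρ = (μ+ν)/λ = 1, via the
    exponential integral: I(s) = e^{a/(λs)} E₁(a/(λs)) / (λs), a = λ−μ.
    Used as an independent cross-check of the quadrature path."""
    a = lam - mu
    if a <= 0:
        raise TreeError("requires lambda > mu")
    if abs(mu + nu - lam) > 1e-9 * lam:
        raise TreeError("phi_fd_critical requires mu + nu = lambda")

    def I(si):
        z = a / (lam * si)
        return math.exp(z) * special.exp1(z) / (lam * si)

    if s == 0:
        return 0.0
    if s == 1:
        return 1.0
    return s * I(s) / I(1.0)


def phi_fd_empirical(params: ThreeLayerParams, reps: int, seed=None) -> dict:
    """Monte Carlo of the three-layer process, conditioned on tree survival.

    Per repetition: grow the complete birth–death tree, run the gain/loss
    process along it (extinct lineages carry features too), then apply the
    FOB sampling to the extant leaves.  Returns per-rep arrays of F_t,
    F_t^s and N_t plus the F_t = 0 exclusion frequency; the ratio ensemble
    excludes repetitions with no features.
    """
    rng = np.random.default_rng(seed) if not isinstance(
        seed, np.random.Generator) else seed
    if params.lam <= params.mu:
        raise TreeError("requires lambda > mu")
    bd = BDParams(lam=params.lam, mu=params.mu, t=params.t)
    gl = GainLossParams(r=params.r, nu=params.nu, f0=params.f0)
    f_t = np.empty(reps)
    f_ts = np.empty(reps)
    n_t = np.empty(reps, dtype=int)
    for i in range(reps):
        real = simulate_bd(bd, rng, condition="survival")
        tree = real.complete_tree(extinct_suffix="*")
        assignment, _ = simulate_gain_loss(tree, gl, rng)
        extant = [x for x in tree.leaf_labels if not x.endswith("*")]
        present = set().union(*(assignment.features[x] for x in extant)) \
            if extant else set()
        survivors = [x for x in extant if rng.random() < params.s]
        surviving = set().union(*(assignment.features[x] for x in survivors)) \
            if survivors else set()
        f_t[i] = len(present)
        f_ts[i] = len(surviving)
        n_t[i] = len(extant)
    mask = f_t > 0
    ratios = f_ts[mask] / f_t[mask]
    return {
        "F_t": f_t, "F_t_s": f_ts, "N_t": n_t,
        "ratios": ratios,
        "excluded_zero_feature_fraction": 1.0 - mask.mean(),
    }


def nu_monotonicity_scan(lam: float, mu: float, s: float, nu_grid) -> dict:
    """φ_FD along a ν grid, with monotonicity and φ_FD ≤ φ_PD verdicts.

    φ_FD(s) is expected to decrease strictly in ν (proved at ρ = 1,
    conjectured generally), starting from φ_PD at ν = 0; any violation is
    reported rather than asserted away.
    """
    if not 0 < s < 1:
        raise TreeError("scan requires s strictly inside (0, 1)")
    nu_grid = sorted(float(v) for v in nu_grid)
    if any(v < 0 for v in nu_grid):
        raise TreeError("nu values must be >= 0")
    ref = phi_pd(s, lam, mu)
    values = [phi_fd(s, lam, mu, nu) for nu in nu_grid]
    non_monotone = [(nu_grid[i], nu_grid[i + 1])
                    for i in range(len(values) - 1)
                    if values[i + 1] >= values[i]]
    exceeds = [nu for nu, v in zip(nu_grid, values)
               if nu > 0 and v > ref + 1e-9]
    return {
        "nu": nu_grid,
        "phi_fd": values,
        "phi_pd": ref,
        "strictly_decreasing": not non_monotone,
        "non_monotone_pairs": non_monotone,
        "phi_fd_above_phi_pd": exceeds,
    }
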