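"""Spike-and-slab "collapse" tree priors for species delimitation.

The collapse prior is a per-node mixture over the n-1 internal node
heights of a time tree: with weight ``omega`` a node falls in the *spike*
(uniform on [0, epsilon), collapsing its descendant taxa into one
species), otherwise it contributes to the *slab*, a branching-process
density defined only above the threshold.  With k nodes below epsilon the
joint density factorises as

    (1 - omega)^(n-k-1) * slab(T) * (omega / epsilon)^k .

Three slabs are provided:

* a per-node exponential above epsilon (the generative picture: heights
  are iid epsilon + Exp(lambda)),
* the reconstructed birth-death process conditioned on an origin height
  (death rate 0 recovers the Yule model; the origin -> infinity limit of
  the Yule case is exactly the exponential slab),
* the Yule-skyline marginal: a pure-birth process whose per-epoch birth
  rates follow Gamma priors that are integrated out analytically, with
  sequential smoothing of the Gamma rate across epochs.

All densities are returned in log space; ``-inf`` signals zero density
and is never an error.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy.special import gammaln

from .tree import TimeTree, count_collapsed

__all__ = [
    "CollapseConfig",
    "BirthDeathParams",
    "SkylineConfig",
    "spike_log_density",
    "exp_slab_log_density",
    "collapse_log_prior",
    "bd_node_log_density",
    "birth_death_collapse_log_prior",
    "epoch_statistics",
    "ysc_slab_log_factor",
    "yule_skyline_log_marginal",
    "assemble_ranked_tree",
    "sample_tree_from_collapse_prior",
    "sample_tree_from_ysc_prior",
    "sample_ysc_joint",
]

NEG_INF = float("-inf")


@dataclass(frozen=True)
class CollapseConfig:
    """Collapse threshold epsilon (tree-height units) and spike weight omega."""

    epsilon: float
    omega: float

    def __post_init__(self) -> None:
        if not self.epsilon > 0:
            raise ValueError("epsilon must be > 0")
        if not 0.0 <= self.omega <= 1.0:
            raise ValueError("omega must lie in [0, 1]")


@dataclass(frozen=True)
class BirthDeathParams:
    """Birth rate, death rate and origin height of the conditioned birth-death slab.

    ``mu = 0`` recovers the Yule model.  The origin must exceed the root
    height of any tree the density is evaluated on.
    """

    lam: float
    mu: float
    origin: float

    def __post_init__(self) -> None:
        if not self.lam > 0:
            raise ValueError("birth rate lam must be > 0")
        if self.mu < 0:
            raise ValueError("death rate mu must be >= 0")
        if not self.origin > 0:
            raise ValueError("origin must be > 0")


@dataclass(frozen=True)
class SkylineConfig:
    """Epoch count and first-epoch Gamma(shape=alpha, rate=beta) birth-rate prior.

    Epochs are equal-width over [epsilon, root height], recomputed at every
    density evaluation so the grid tracks the moving root.
    """

    epochs: int
    alpha: float
    beta: float

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError("epoch count must be >= 1")
        if not (self.alpha > 0 and self.beta > 0):
            raise ValueError("gamma shape and rate must be > 0")


# ----------------------------------------------------------------------
# Per-node densities
# ----------------------------------------------------------------------

def spike_log_density(h: float, epsilon: float) -> float:
    """Log density of the spike: Uniform(0, epsilon); -inf for h >= epsilon."""
    if not epsilon > 0:
        raise ValueError("epsilon must be > 0")
    if h < 0:
        raise ValueError("height must be >= 0")
    return -math.log(epsilon) if h < epsilon else NEG_INF


def exp_slab_log_density(h: float, epsilon: float, lam: float) -> float:
    """Log density of the exponential slab, Exp(lam) shifted to start at epsilon."""
    if not lam > 0:
        raise ValueError("rate lam must be > 0")
    if not epsilon > 0:
        raise ValueError("epsilon must be > 0")
    if h < epsilon:
        return NEG_INF
    return math.log(lam) - lam * (h - epsilon)


def _weight_log_terms(n: int, k: int, cfg: CollapseConfig) -> float:
    """(n-k-1) log(1-omega) + k log(omega/epsilon) with 0*log 0 := 0."""
    omega, eps = cfg.omega, cfg.epsilon
    m1 = n - k - 1  # number of slab (>= epsilon) nodes
    lp = 0.0
    if m1 > 0:
        if omega == 1.0:
            return NEG_INF
        lp += m1 * math.log1p(-omega)
    if k > 0:
        if omega == 0.0:
            return NEG_INF
        lp += k * (math.log(omega) - math.log(eps))
    return lp


def collapse_log_prior(
    tree: TimeTree,
    slab_log_density: Callable[[float], float],
    cfg: CollapseConfig,
) -> float:
    """Log density of the collapse mixture with a per-node slab.

    ``slab_log_density`` is evaluated at every internal node height
    >= epsilon; nodes below epsilon contribute spike factors only.
    """
    n = tree.n_leaves
    k = count_collapsed(tree, cfg.epsilon)
    lp = _weight_log_terms(n, k, cfg)
    if lp == NEG_INF:
        return NEG_INF
    for i in tree.internal_nodes:
        h = float(tree.heights[i])
        if h >= cfg.epsilon:
            s = slab_log_density(h)
            if s == NEG_INF:
                return NEG_INF
            lp += s
    return lp


# ----------------------------------------------------------------------
# Birth-death slab conditioned on an origin height
# ----------------------------------------------------------------------

def _bd_log_p1(t: float, lam: float, mu: float) -> float:
    """log p1(t): probability density kernel that a lineage at time t in the
    past leaves exactly one sampled descendant (complete sampling)."""
    r = lam - mu
    if mu == 0.0:
        return -lam * t
    if abs(r) < 1e-12 * lam:  # critical case lam == mu
        return -2.0 * math.log1p(lam * t)
    return 2.0 * math.log(abs(r)) - r * t - 2.0 * math.log(abs(lam - mu * math.exp(-r * t)))


def _bd_norm(epsilon: float, origin: float, lam: float, mu: float) -> float:
    """integral_epsilon^origin lam * p1(t) dt (closed form)."""
    r = lam - mu
    if mu == 0.0:
        return math.exp(-lam * epsilon) - math.exp(-lam * origin)
    if abs(r) < 1e-12 * lam:
        return 1.0 / (1.0 + lam * epsilon) - 1.0 / (1.0 + lam * origin)
    f = lambda t: r / (lam - mu * math.exp(-r * t))
    return (lam / mu) * (f(epsilon) - f(origin))


def bd_node_log_density(h: float, params: BirthDeathParams, epsilon: float) -> float:
    """Per-node slab factor of the conditioned birth-death process.

    The node-height density of a reconstructed birth-death tree with
    complete sampling, truncated and renormalised to [epsilon, origin].
    With mu=0 and origin -> infinity this is exactly the exponential slab.
    """
    if h < epsilon or h > params.origin:
        return NEG_INF
    z = _bd_norm(epsilon, params.origin, params.lam, params.mu)
    return math.log(params.lam) + _bd_log_p1(h, params.lam, params.mu) - math.log(z)


def birth_death_collapse_log_prior(
    tree: TimeTree, params: BirthDeathParams, cfg: CollapseConfig
) -> float:
    """Collapse mixture with the origin-conditioned birth-death slab."""
    if not params.origin > tree.root_height:
        raise ValueError(
            f"origin {params.origin} must exceed the root height {tree.root_height}"
        )
    return collapse_log_prior(
        tree, lambda h: bd_node_log_density(h, params, cfg.epsilon), cfg
    )


# ----------------------------------------------------------------------
# Yule-skyline slab: gamma-integrated epoch birth rates
# ----------------------------------------------------------------------

def epoch_statistics(
    tree: TimeTree, epsilon: float, grid: Sequence[float]
) -> tuple[np.ndarray, np.ndarray]:
    """Per-epoch birth counts b_j and lineage-time totals L_j above the threshold.

    ``grid`` holds E+1 ascending epoch boundaries spanning
    [epsilon, root height].  Collapsed clades count as a single lineage
    from epsilon upward, so the lineage count at height t >= epsilon is
    (number of above-threshold nodes with height > t) + 1.
    """
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 1 or grid.size < 2 or np.any(np.diff(grid) < 0):
        raise ValueError("grid must be >= 2 ascending boundaries")
    if not math.isclose(grid[0], epsilon, rel_tol=1e-9, abs_tol=1e-12):
        raise ValueError("grid must start at epsilon")
    hs = np.sort(tree.heights[tree.n_leaves:])
    hs = hs[hs >= epsilon]
    if hs.size and grid[-1] < hs[-1] - 1e-9 * max(1.0, hs[-1]):
        raise ValueError("grid must span up to the root height")
    E = grid.size - 1
    b = np.zeros(E, dtype=np.int64)
    L = np.zeros(E)
    # birth counts: half-open epochs [g_{j-1}, g_j), last epoch closed
    idx = np.searchsorted(grid[1:-1], hs, side="right")
    for j in idx:
        b[j] += 1
    # lineage count at t: hs.size + 1 lineages at epsilon, minus nodes passed
    for j in range(E):
        lo, hi = grid[j], grid[j + 1]
        pts = np.concatenate(([lo], hs[(hs > lo) & (hs < hi)], [hi]))
        for a, c in zip(pts[:-1], pts[1:]):
            count = hs.size + 1 - np.searchsorted(hs, a, side="right")
            L[j] += count * (c - a)
    return b, L


def ysc_slab_log_factor(tree: TimeTree, epsilon: float, sky: SkylineConfig) -> float:
    """Log of the epoch-factorised Yule-skyline marginal over above-threshold heights.

    Each epoch j contributes the Gamma-Poisson-process marginal

        beta_j^alpha Gamma(alpha + b_j) / (Gamma(alpha) (beta_j + L_j)^(alpha + b_j))

    where b_j births occur over L_j lineage-time; the rate hyperparameter
    is smoothed sequentially so the prior mean of epoch j+1 equals the
    posterior mean of epoch j (shape alpha held fixed).  Trees whose
    nodes all sit below epsilon contribute an empty product (0 in log
    space).
    """
    # plain-Python hot path: trees are small and numpy overhead dominates
    hs = sorted(h for h in tree.heights[tree.n_leaves:].tolist() if h >= epsilon)
    M = len(hs)
    if M == 0:
        return 0.0
    root = hs[-1]
    E = sky.epochs
    width = root - epsilon
    b = [0] * E
    if width > 0:
        for h in hs:
            j = int((h - epsilon) * E / width)
            b[min(j, E - 1)] += 1
    else:
        b[-1] = M
    # F(t) = integral_eps^t count(s) ds with count(t) = M + 1 - #{h <= t}
    L = [0.0] * E
    ci = 0
    csum = 0.0
    prev_f = 0.0
    for j in range(1, E + 1):
        g = epsilon + width * j / E
        while ci < M and hs[ci] <= g:
            csum += hs[ci]
            ci += 1
        f = (M + 1) * (g - epsilon) - (ci * g - csum)
        L[j - 1] = f - prev_f
        prev_f = f
    a = sky.alpha
    lg_a = math.lgamma(a)
    beta = sky.beta
    lp = 0.0
    for j in range(E):
        denom = beta + L[j]
        lp += a * math.log(beta) + math.lgamma(a + b[j]) - lg_a - (a + b[j]) * math.log(denom)
        beta = a * denom / (a + b[j])
    return lp


def yule_skyline_log_marginal(
    tree: TimeTree, cfg: CollapseConfig, sky: SkylineConfig
) -> float:
    """Collapse mixture with the Yule-skyline slab (the YSC prior)."""
    n = tree.n_leaves
    k = count_collapsed(tree, cfg.epsilon)
    lp = _weight_log_terms(n, k, cfg)
    if lp == NEG_INF:
        return NEG_INF
    return lp + ysc_slab_log_factor(tree, cfg.epsilon, sky)


# ----------------------------------------------------------------------
# Simulation from the prior
# ----------------------------------------------------------------------

def assemble_ranked_tree(
    heights: Sequence[float],
    labels: Sequence[str],
    rng: np.random.Generator,
) -> TimeTree:
    """Assemble n-1 internal heights into a tree with a uniform ranked topology.

    Heights are sorted ascending and at each height two of the currently
    active lineages are joined uniformly at random (coalescent-style
    pairing), which makes every ranked labelled topology equally likely.
    """
    heights = np.sort(np.asarray(heights, dtype=float))
    n = heights.size + 1
    if len(labels) != n:
        raise ValueError("need n labels for n-1 heights")
    m = 2 * n - 1
    parent = np.full(m, -1, dtype=np.int64)
    left = np.full(m, -1, dtype=np.int64)
    right = np.full(m, -1, dtype=np.int64)
    hv = np.zeros(m)
    active = list(range(n))
    for j, h in enumerate(heights):
        i = int(rng.integers(len(active)))
        a = active.pop(i)
        i = int(rng.integers(len(active)))
        b = active.pop(i)
        node = n + j
        hv[node] = h
        left[node], right[node] = a, b
        parent[a] = parent[b] = node
        active.append(node)
    return TimeTree(labels, parent, left, right, hv)


def _default_labels(n: int) -> list[str]:
    return [f"t{i + 1}" for i in range(n)]


def sample_tree_from_collapse_prior(
    n: int,
    cfg: CollapseConfig,
    lam: float,
    rng: np.random.Generator,
    labels: Sequence[str] | None = None,
) -> TimeTree:
    """Draw a tree from the exponential-slab collapse prior.

    Each internal node height is, independently, Uniform(0, epsilon) with
    probability omega and epsilon + Exp(lam) otherwise; the ranked
    topology is uniform.
    """
    if n < 2:
        raise ValueError("need n >= 2 taxa")
    if not lam > 0:
        raise ValueError("rate lam must be > 0")
    spike = rng.random(n - 1) < cfg.omega
    heights = np.where(
        spike,
        rng.random(n - 1) * cfg.epsilon,
        cfg.epsilon + rng.exponential(1.0 / lam, size=n - 1),
    )
    return assemble_ranked_tree(heights, labels or _default_labels(n), rng)


def sample_ysc_joint(
    n: int,
    epsilon: float,
    omega_prior: tuple[float, float],
    sky: SkylineConfig,
    rng: np.random.Generator,
    labels: Sequence[str] | None = None,
    n_particles: int = 2048,
    min_weight_ess: float = 50.0,
) -> tuple[float, TimeTree]:
    """Draw (omega, tree) jointly from the Yule-skyline collapse prior.

    The Yule-skyline slab is an unnormalised product over the
    above-threshold subtree, so its tree-space normaliser depends on
    omega; the joint density Beta(omega) * f(tree | omega) therefore has
    an omega marginal tilted away from the Beta hyperprior.  Sampling
    must respect that joint -- it is exactly what the MCMC sampler
    targets -- so each importance particle carries its own omega draw
    and (omega, tree) pairs are resampled together.
    """
    if n < 2:
        raise ValueError("need n >= 2 taxa")
    labels = list(labels) if labels is not None else _default_labels(n)
    a_w, b_w = omega_prior
    a, b1 = sky.alpha, sky.beta
    lg_a = gammaln(a)

    def one_pass(P: int):
        pairs: list[tuple[float, TimeTree]] = []
        logw = np.empty(P)
        for p in range(P):
            omega = float(rng.beta(a_w, b_w))
            lam = rng.gamma(a, 1.0 / b1)
            spike = rng.random(n - 1) < omega
            heights = np.where(
                spike,
                rng.random(n - 1) * epsilon,
                epsilon + rng.exponential(1.0 / lam, size=n - 1),
            )
            t = assemble_ranked_tree(heights, labels, rng)
            slab_h = heights[heights >= epsilon]
            m = slab_h.size
            S = float(np.sum(slab_h - epsilon))
            log_prop = (
                a * math.log(b1) + gammaln(a + m) - lg_a - (a + m) * math.log(b1 + S)
            )
            logw[p] = ysc_slab_log_factor(t, epsilon, sky) - log_prop
            pairs.append((omega, t))
        return pairs, logw

    pairs, logw = one_pass(n_particles)
    w = np.exp(logw - logw.max())
    ess = w.sum() ** 2 / np.square(w).sum()
    if ess < min_weight_ess:
        pairs, logw = one_pass(4 * n_particles)
        w = np.exp(logw - logw.max())
    w /= w.sum()
    idx = int(rng.choice(len(pairs), p=w))
    return pairs[idx]


def sample_tree_from_ysc_prior(
    n: int,
    cfg: CollapseConfig,
    sky: SkylineConfig,
    rng: np.random.Generator,
    labels: Sequence[str] | None = None,
    n_particles: int = 2048,
    min_weight_ess: float = 50.0,
) -> TimeTree:
    """Draw a tree from the Yule-skyline collapse prior by importance resampling.

    The YSC prior has no closed-form direct simulator (the epoch grid
    depends on the root height), so we draw ``n_particles`` trees from a
    tractable proposal -- the collapse prior whose slab is the
    single-epoch Gamma(alpha, beta) marginal of iid shifted-exponential
    heights -- weight each by YSC density / proposal density, and
    resample one tree.  If the weight effective sample size falls below
    ``min_weight_ess`` the particle count is quadrupled once.
    """
    if n < 2:
        raise ValueError("need n >= 2 taxa")
    labels = list(labels) if labels is not None else _default_labels(n)
    a, b1 = sky.alpha, sky.beta
    lg_a = gammaln(a)

    def one_pass(P: int):
        trees: list[TimeTree] = []
        logw = np.empty(P)
        for p in range(P):
            lam = rng.gamma(a, 1.0 / b1)
            spike = rng.random(n - 1) < cfg.omega
            heights = np.where(
                spike,
                rng.random(n - 1) * cfg.epsilon,
                cfg.epsilon + rng.exponential(1.0 / lam, size=n - 1),
            )
            t = assemble_ranked_tree(heights, labels, rng)
            slab_h = heights[heights >= cfg.epsilon]
            m = slab_h.size
            S = float(np.sum(slab_h - cfg.epsilon))
            # lambda-marginalised proposal slab density for this height multiset
            log_prop = (
                a * math.log(b1) + gammaln(a + m) - lg_a - (a + m) * math.log(b1 + S)
            )
            logw[p] = ysc_slab_log_factor(t, cfg.epsilon, sky) - log_prop
            trees.append(t)
        return trees, logw

    trees, logw = one_pass(n_particles)
    w = np.exp(logw - logw.max())
    ess = w.sum() ** 2 / np.square(w).sum()
    if ess < min_weight_ess:
        trees, logw = one_pass(4 * n_particles)
        w = np.exp(logw - logw.max())
    w /= w.sum()
    idx = int(rng.choice(len(trees), p=w))
    return trees[idx]
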