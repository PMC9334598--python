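"""Metropolis-Hastings sampler over (species tree, omega, Ne, substitution scalars).

The sampler targets the collapse tree prior (exponential, birth-death or
Yule-skyline slab) times a Beta prior on the collapse weight omega, and
optionally an MSC likelihood over fixed gene trees, or MSC + HKY with
gene-tree node heights sampled as well.

The ThresholdUniform kernel is the delimitation-specific move: it slides
one internal node height across the threshold epsilon, lumping two
clusters or splitting one without changing the topology.  Its Hastings
ratio accounts for the direction-dependent eligible sets and window
lengths:

    log HR = log|E_fwd| + log len_fwd - log|E_rev| - log len_rev .

Lumping the root below epsilon has an empty reverse eligible set, so the
ratio is -inf and the move auto-rejects; all-collapsed states are still
reachable through the generic height and scale operators.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.special import gammaln

from .coalescent import PopSizeMap, msc_log_density
from .experiment import GeneReplicate
from .hky import HKYParams, hky_log_likelihood
from .priors import (
    BirthDeathParams,
    CollapseConfig,
    SkylineConfig,
    birth_death_collapse_log_prior,
    collapse_log_prior,
    exp_slab_log_density,
    sample_tree_from_collapse_prior,
    sample_tree_from_ysc_prior,
    yule_skyline_log_marginal,
)
from .tree import TimeTree, count_collapsed, tree_statistics

__all__ = [
    "McmcState",
    "ProposalResult",
    "CollapseModel",
    "Trace",
    "InitializationError",
    "threshold_uniform_propose",
    "standard_proposals",
    "lump_eligible",
    "split_eligible",
    "run_mcmc",
]

NEG_INF = float("-inf")


class InitializationError(RuntimeError):
    """The initial MCMC state has zero probability; the message names the factor."""


# ----------------------------------------------------------------------
# State and model
# ----------------------------------------------------------------------

@dataclass
class McmcState:
    """One point of the chain; cached log prior/likelihood travel with it."""

    tree: TimeTree
    omega: float
    pops: PopSizeMap | None = None
    gene_trees: list[TimeTree] | None = None
    hky: list[HKYParams] | None = None
    log_prior: float = math.nan
    log_likelihood: float = 0.0

    @property
    def log_posterior(self) -> float:
        return self.log_prior + self.log_likelihood

    def shallow(self) -> "McmcState":
        return replace(self)


@dataclass
class CollapseModel:
    """Prior + likelihood specification for :func:`run_mcmc`.

    ``slab`` selects the collapse-prior slab; ``likelihood`` is one of
    ``"none"`` (prior-only), ``"msc"`` (fixed gene trees, MSC density) or
    ``"msc_hky"`` (gene-tree heights sampled, MSC + pruning likelihood).
    """

    epsilon: float
    omega_prior: tuple[float, float] = (1.0, 2.0)
    slab: str = "yule_skyline"
    #: taxon labels of the species tree (prior-only mode; defaults to 6 taxa)
    taxa: list[str] | None = None
    exp_lam: float = 10.0
    bd: BirthDeathParams | None = None
    sky: SkylineConfig | None = None
    likelihood: str = "none"
    genes: list[GeneReplicate] | None = None
    init_pops: PopSizeMap | None = None
    sample_pops: bool = False
    #: pairwise coalescent rate ~ Gamma(shape, rate); Ne = 2/rate (prior when sampled)
    ne_rate_gamma: tuple[float, float] = (100.0, 0.01)
    sample_hky: bool = False
    kappa_lognormal: tuple[float, float] = (1.0, 1.25)
    nu_lognormal: tuple[float, float] = (-0.18, 0.6)
    freq_dirichlet: float = 10.0

    def __post_init__(self) -> None:
        if self.slab not in ("exponential", "birth_death", "yule_skyline"):
            raise ValueError(f"unknown slab {self.slab!r}")
        if self.likelihood not in ("none", "msc", "msc_hky"):
            raise ValueError(f"unknown likelihood mode {self.likelihood!r}")
        if self.slab == "yule_skyline" and self.sky is None:
            self.sky = SkylineConfig(4, 2.0, 0.2)
        if self.slab == "birth_death" and self.bd is None:
            raise ValueError("birth_death slab needs BirthDeathParams")
        if self.likelihood != "none" and not self.genes:
            raise ValueError("likelihood modes need gene replicates")

    # -- prior ----------------------------------------------------------
    def tree_log_prior(self, tree: TimeTree, omega: float) -> float:
        cfg = CollapseConfig(self.epsilon, omega)
        if self.slab == "exponential":
            return collapse_log_prior(
                tree, lambda h: exp_slab_log_density(h, self.epsilon, self.exp_lam), cfg
            )
        if self.slab == "birth_death":
            if not self.bd.origin > tree.root_height:
                return NEG_INF
            return birth_death_collapse_log_prior(tree, self.bd, cfg)
        return yule_skyline_log_marginal(tree, cfg, self.sky)

    def omega_log_prior(self, omega: float) -> float:
        a, b = self.omega_prior
        if not 0.0 < omega < 1.0:
            return NEG_INF
        return (
            (a - 1.0) * math.log(omega)
            + (b - 1.0) * math.log1p(-omega)
            + math.lgamma(a + b) - math.lgamma(a) - math.lgamma(b)
        )

    def ne_log_prior(self, pops: PopSizeMap) -> float:
        if not self.sample_pops:
            return 0.0
        shape, rate = self.ne_rate_gamma
        lp = 0.0
        for ne in pops.sizes.values():
            r = 2.0 / ne
            # density of Ne via the change of variables r = 2/Ne
            lp += (
                shape * math.log(rate)
                - gammaln(shape)
                + (shape - 1.0) * math.log(r)
                - rate * r
                + math.log(2.0)
                - 2.0 * math.log(ne)
            )
        return lp

    def hky_log_prior(self, hky_list: Sequence[HKYParams] | None) -> float:
        if not self.sample_hky or hky_list is None:
            return 0.0
        lp = 0.0
        mk, sk = self.kappa_lognormal
        mn, sn = self.nu_lognormal
        for h in hky_list:
            lp += float(sps.lognorm.logpdf(h.kappa, sk, scale=math.exp(mk)))
            lp += float(sps.lognorm.logpdf(h.nu, sn, scale=math.exp(mn)))
            lp += float(sps.dirichlet.logpdf(h.freqs, [self.freq_dirichlet] * 4))
        return lp

    def log_prior(self, state: McmcState) -> float:
        lp = self.tree_log_prior(state.tree, state.omega)
        if lp == NEG_INF:
            return NEG_INF
        lp += self.omega_log_prior(state.omega)
        if lp == NEG_INF:
            return NEG_INF
        if state.pops is not None:
            lp += self.ne_log_prior(state.pops)
        lp += self.hky_log_prior(state.hky)
        return lp

    # -- likelihood -----------------------------------------------------
    def log_likelihood(self, state: McmcState) -> float:
        if self.likelihood == "none":
            return 0.0
        pops = state.pops
        ll = 0.0
        for g, gene in enumerate(self.genes):
            gt = gene.gene_tree if state.gene_trees is None else state.gene_trees[g]
            ll += msc_log_density(gt, state.tree, pops, gene.mapping)
            if ll == NEG_INF:
                return NEG_INF
            if self.likelihood == "msc_hky":
                hky = gene.hky if state.hky is None else state.hky[g]
                ll += hky_log_likelihood(gt, gene.alignment, hky, gene.branch_rates)
        return ll

    def evaluate(self, state: McmcState) -> McmcState:
        state.log_prior = self.log_prior(state)
        state.log_likelihood = (
            self.log_likelihood(state) if state.log_prior > NEG_INF else NEG_INF
        )
        return state


# ----------------------------------------------------------------------
# ThresholdUniform
# ----------------------------------------------------------------------

def lump_eligible(tree: TimeTree, epsilon: float) -> list[int]:
    """Internal nodes at or above epsilon whose children are both below it."""
    out = []
    for i in tree.internal_nodes:
        if tree.heights[i] >= epsilon:
            l, r = tree.children(i)
            if tree.heights[l] < epsilon and tree.heights[r] < epsilon:
                out.append(i)
    return out


def split_eligible(tree: TimeTree, epsilon: float) -> list[int]:
    """Internal nodes below epsilon whose parent is at or above it."""
    out = []
    for i in tree.internal_nodes:
        p = tree.parent[i]
        if p >= 0 and tree.heights[i] < epsilon and tree.heights[p] >= epsilon:
            out.append(i)
    return out


@dataclass
class ProposalResult:
    """A proposed state with its log Hastings ratio; ``accepted`` is set by the MH step."""

    proposed: McmcState | None
    log_hastings: float
    operator: str = ""
    accepted: bool | None = None


def _threshold_uniform_tree(
    tree: TimeTree, epsilon: float, rng: np.random.Generator
) -> tuple[TimeTree, float] | None:
    B = int(rng.integers(2))
    if B == 0:  # lump: move a node from the slab side below epsilon
        elig = lump_eligible(tree, epsilon)
        if not elig:
            return None
        x = elig[int(rng.integers(len(elig)))]
        l, r = tree.children(x)
        t0 = max(float(tree.heights[l]), float(tree.heights[r]))
        t1 = epsilon
        h_new = t0 + (t1 - t0) * rng.random()
        new = tree.copy()
        new.heights[x] = h_new
        rev = split_eligible(new, epsilon)
        if not rev:  # lumping the root: irreversible, auto-reject
            return new, NEG_INF
        p = tree.parent[x]
        len_rev = float(tree.heights[p]) - epsilon
        log_hr = (
            math.log(len(elig)) + math.log(t1 - t0)
            - math.log(len(rev)) - math.log(len_rev)
        )
        return new, log_hr
    # split: move a node from the spike side above epsilon
    elig = split_eligible(tree, epsilon)
    if not elig:
        return None
    x = elig[int(rng.integers(len(elig)))]
    p = tree.parent[x]
    t0 = epsilon
    t1 = float(tree.heights[p])
    h_new = t0 + (t1 - t0) * rng.random()
    new = tree.copy()
    new.heights[x] = h_new
    rev = lump_eligible(new, epsilon)
    l, r = tree.children(x)
    len_rev = epsilon - max(float(tree.heights[l]), float(tree.heights[r]))
    log_hr = (
        math.log(len(elig)) + math.log(t1 - t0)
        - math.log(len(rev)) - math.log(len_rev)
    )
    return new, log_hr


def threshold_uniform_propose(
    state: McmcState, epsilon: float, rng: np.random.Generator
) -> ProposalResult:
    """One ThresholdUniform proposal (topology-preserving lump/split across epsilon)."""
    res = _threshold_uniform_tree(state.tree, epsilon, rng)
    if res is None:
        return ProposalResult(None, NEG_INF, "threshold_uniform")
    new_tree, log_hr = res
    new = state.shallow()
    new.tree = new_tree
    return ProposalResult(new, log_hr, "threshold_uniform")


# ----------------------------------------------------------------------
# Standard proposals
# ----------------------------------------------------------------------

def _node_height_tree(
    tree: TimeTree,
    rng: np.random.Generator,
    *,
    side_preserving: bool = False,
    epsilon: float | None = None,
) -> tuple[TimeTree, float] | None:
    """Uniform height shift of a non-root internal node within its valid window.

    With ``side_preserving`` the window is intersected with the node's
    current side of epsilon, so the move never changes the cluster count.
    """
    cands = [i for i in tree.internal_nodes if i != tree.root]
    if not cands:
        return None
    x = cands[int(rng.integers(len(cands)))]
    l, r = tree.children(x)
    lo = max(float(tree.heights[l]), float(tree.heights[r]))
    hi = float(tree.heights[tree.parent[x]])
    if side_preserving:
        if epsilon is None:
            raise ValueError("side_preserving needs epsilon")
        if tree.heights[x] >= epsilon:
            lo = max(lo, epsilon)
        else:
            hi = min(hi, epsilon)
    if not hi > lo:
        return None
    new = tree.copy()
    new.heights[x] = lo + (hi - lo) * rng.random()
    return new, 0.0


def _root_gap_scale_tree(
    tree: TimeTree,
    rng: np.random.Generator,
    *,
    delta: float = 0.75,
    floor: float | None = None,
) -> tuple[TimeTree, float]:
    """Scale the gap between the root and its taller child: h' = lo + (h-lo)c."""
    l, r = tree.children(tree.root)
    lo = max(float(tree.heights[l]), float(tree.heights[r]))
    if floor is not None:
        lo = max(lo, floor)
    gap = float(tree.heights[tree.root]) - lo
    if gap <= 0:
        gap = 1e-300
    c = math.exp(delta * (2.0 * rng.random() - 1.0))
    new = tree.copy()
    new.heights[tree.root] = lo + gap * c
    return new, math.log(c)


def _tree_scale(
    tree: TimeTree, rng: np.random.Generator, *, delta: float = 0.5
) -> tuple[TimeTree, float]:
    c = math.exp(delta * (2.0 * rng.random() - 1.0))
    new = tree.copy()
    new.heights[tree.n_leaves:] *= c
    return new, (tree.n_leaves - 1) * math.log(c)


def _omega_walk(
    omega: float, rng: np.random.Generator, *, sigma: float = 0.8
) -> tuple[float, float]:
    """Random walk on logit(omega); returns (omega', log Jacobian ratio)."""
    z = math.log(omega) - math.log1p(-omega)
    z2 = z + sigma * rng.standard_normal()
    w2 = 1.0 / (1.0 + math.exp(-z2))
    log_j = (math.log(w2) + math.log1p(-w2)) - (math.log(omega) + math.log1p(-omega))
    return w2, log_j


def _scale_factor(rng: np.random.Generator, delta: float = 0.7) -> tuple[float, float]:
    c = math.exp(delta * (2.0 * rng.random() - 1.0))
    return c, math.log(c)


# Each operator takes (state, model, rng) and returns (new_state, log_hr) or None.
def _op_threshold(state, model, rng):
    res = _threshold_uniform_tree(state.tree, model.epsilon, rng)
    if res is None:
        return None
    new = state.shallow()
    new.tree, log_hr = res
    return new, log_hr


def _op_node_height(state, model, rng):
    res = _node_height_tree(state.tree, rng)
    if res is None:
        return None
    new = state.shallow()
    new.tree, log_hr = res
    return new, log_hr


def _op_root_gap(state, model, rng):
    new = state.shallow()
    new.tree, log_hr = _root_gap_scale_tree(state.tree, rng)
    return new, log_hr


def _op_tree_scale(state, model, rng):
    new = state.shallow()
    new.tree, log_hr = _tree_scale(state.tree, rng)
    return new, log_hr


def _op_omega(state, model, rng):
    new = state.shallow()
    new.omega, log_hr = _omega_walk(state.omega, rng)
    return new, log_hr


def _beta_logpdf(x: float, a: float, b: float) -> float:
    return (
        (a - 1.0) * math.log(x)
        + (b - 1.0) * math.log1p(-x)
        + math.lgamma(a + b) - math.lgamma(a) - math.lgamma(b)
    )


def _op_omega_gibbs(state, model, rng):
    """Draw omega from its full conditional Beta(a + k, b + n - k - 1).

    The collapse weight enters the posterior only through the mixture
    weight terms, so the conditional is conjugate given the current k;
    the Hastings ratio cancels the posterior ratio exactly and the move
    always accepts.
    """
    a, b = model.omega_prior
    n = state.tree.n_leaves
    k = count_collapsed(state.tree, model.epsilon)
    a2, b2 = a + k, b + (n - k - 1)
    w2 = float(rng.beta(a2, b2))
    if not 0.0 < w2 < 1.0:
        return None
    log_hr = _beta_logpdf(state.omega, a2, b2) - _beta_logpdf(w2, a2, b2)
    new = state.shallow()
    new.omega = w2
    return new, log_hr


def _op_ne_scale(state, model, rng):
    branches = list(state.pops.sizes)
    b = branches[int(rng.integers(len(branches)))]
    c, log_hr = _scale_factor(rng)
    new = state.shallow()
    sizes = dict(state.pops.sizes)
    sizes[b] = sizes[b] * c
    new.pops = PopSizeMap(sizes)
    return new, log_hr


def _op_kappa_scale(state, model, rng):
    g = int(rng.integers(len(state.hky)))
    c, log_hr = _scale_factor(rng)
    new = state.shallow()
    hl = list(state.hky)
    hl[g] = HKYParams(hl[g].kappa * c, hl[g].freqs, hl[g].nu)
    new.hky = hl
    return new, log_hr


def _op_nu_scale(state, model, rng):
    g = int(rng.integers(len(state.hky)))
    c, log_hr = _scale_factor(rng)
    new = state.shallow()
    hl = list(state.hky)
    hl[g] = HKYParams(hl[g].kappa, hl[g].freqs, hl[g].nu * c)
    new.hky = hl
    return new, log_hr


def _op_freq_walk(state, model, rng, conc: float = 200.0):
    g = int(rng.integers(len(state.hky)))
    f = state.hky[g].freqs
    f2 = rng.dirichlet(conc * f)
    if np.any(f2 <= 1e-8):
        return None
    log_hr = float(
        sps.dirichlet.logpdf(f, conc * f2) - sps.dirichlet.logpdf(f2, conc * f)
    )
    new = state.shallow()
    hl = list(state.hky)
    hl[g] = HKYParams(hl[g].kappa, f2 / f2.sum(), hl[g].nu)
    new.hky = hl
    return new, log_hr


def _op_heights_resample(state, model, rng):
    """Independence-style resample of the whole height multiset.

    New heights are drawn iid from the collapse proposal used by the
    importance sampler (spike w.p. omega, otherwise the
    Gamma-marginalised shifted-exponential slab for the Yule-skyline
    target, or the exact exponential slab) and mapped onto the fixed
    topology rank-for-rank, which preserves parent>child ordering.  The
    Hastings ratio is the proposal-density ratio of the two multisets.
    """
    tree = state.tree
    n = tree.n_leaves
    eps = model.epsilon
    omega = state.omega
    if not 0.0 < omega < 1.0:
        return None

    if model.slab == "yule_skyline":
        a, b1 = model.sky.alpha, model.sky.beta
        lam = rng.gamma(a, 1.0 / b1)
    elif model.slab == "exponential":
        lam = model.exp_lam
    else:
        return None
    spike = rng.random(n - 1) < omega
    new_h = np.where(
        spike,
        rng.random(n - 1) * eps,
        eps + rng.exponential(1.0 / lam, size=n - 1),
    )

    def log_q(heights: np.ndarray) -> float:
        k = int(np.count_nonzero(heights < eps))
        m = n - 1 - k
        lq = k * (math.log(omega) - math.log(eps)) + m * math.log1p(-omega)
        slab = heights[heights >= eps]
        if model.slab == "exponential":
            lam_ = model.exp_lam
            return lq + m * math.log(lam_) - lam_ * float(np.sum(slab - eps))
        S = float(np.sum(slab - eps))
        return lq + (
            a * math.log(b1) + math.lgamma(a + m) - math.lgamma(a)
            - (a + m) * math.log(b1 + S)
        )

    old_sorted = np.sort(tree.heights[tree.n_leaves:])
    new_sorted = np.sort(new_h)
    log_hr = log_q(old_sorted) - log_q(new_sorted)
    # rank-preserving assignment onto the fixed topology
    order = np.argsort(tree.heights[tree.n_leaves:], kind="stable")
    new = state.shallow()
    new.tree = tree.copy()
    new.tree.heights[tree.n_leaves + order] = new_sorted
    return new, log_hr


def _op_topology_resample(state, model, rng):
    """Redraw the ranked topology uniformly at the current height multiset.

    The collapse priors depend on the heights only, so the proposal is
    symmetric (uniform over the compatible ranked labelled topologies)
    and accepts on the likelihood ratio alone; in prior-only mode it is
    an exact Gibbs move.  Without it, cluster supports would be
    conditional on the initial topology instead of marginal.
    """
    from .priors import assemble_ranked_tree

    tree = state.tree
    heights = tree.heights[tree.n_leaves:]
    new = state.shallow()
    new.tree = assemble_ranked_tree(heights, tree.labels, rng)
    return new, 0.0


def _op_gene_height(state, model, rng):
    g = int(rng.integers(len(state.gene_trees)))
    gt = state.gene_trees[g]
    if int(rng.integers(4)) == 0:  # occasionally rescale the gene root gap
        new_gt, log_hr = _root_gap_scale_tree(gt, rng)
    else:
        res = _node_height_tree(gt, rng)
        if res is None:
            return None
        new_gt, log_hr = res
    new = state.shallow()
    trees = list(state.gene_trees)
    trees[g] = new_gt
    new.gene_trees = trees
    return new, log_hr


_OPERATORS: dict[str, Callable] = {
    "threshold_uniform": _op_threshold,
    "node_height": _op_node_height,
    "root_scale": _op_root_gap,
    "tree_scale": _op_tree_scale,
    "omega_walk": _op_omega,
    "omega_gibbs": _op_omega_gibbs,
    "heights_resample": _op_heights_resample,
    "topology_resample": _op_topology_resample,
    "ne_scale": _op_ne_scale,
    "kappa_scale": _op_kappa_scale,
    "nu_scale": _op_nu_scale,
    "freq_walk": _op_freq_walk,
    "gene_height": _op_gene_height,
}

#: default schedule weights; inapplicable operators are dropped and the
#: rest renormalised.
DEFAULT_WEIGHTS = {
    "threshold_uniform": 0.20,
    "node_height": 0.30,
    "root_scale": 0.12,
    "tree_scale": 0.12,
    "omega_walk": 0.04,
    "omega_gibbs": 0.06,
    "heights_resample": 0.15,
    "topology_resample": 0.10,
    "ne_scale": 0.06,
    "kappa_scale": 0.03,
    "nu_scale": 0.03,
    "freq_walk": 0.02,
    "gene_height": 0.02,
}


def standard_proposals(
    state: McmcState, model: CollapseModel, rng: np.random.Generator
) -> ProposalResult:
    """One draw from the weighted schedule of standard (non-threshold) moves."""
    names, probs = _build_schedule(state, model, None)
    keep = [i for i, nm in enumerate(names) if nm != "threshold_uniform"]
    names = [names[i] for i in keep]
    probs = np.asarray([probs[i] for i in keep])
    probs /= probs.sum()
    nm = names[int(rng.choice(len(names), p=probs))]
    res = _OPERATORS[nm](state, model, rng)
    if res is None:
        return ProposalResult(None, NEG_INF, nm)
    return ProposalResult(res[0], res[1], nm)


def _build_schedule(state, model, weights):
    w = dict(DEFAULT_WEIGHTS)
    if weights:
        w.update(weights)
    applicable = {"threshold_uniform", "node_height", "root_scale", "tree_scale",
                  "omega_walk", "omega_gibbs", "topology_resample"}
    if model.likelihood == "none" and model.slab in ("yule_skyline", "exponential"):
        applicable.add("heights_resample")
    if state.pops is not None and model.sample_pops:
        applicable.add("ne_scale")
    if state.hky is not None and model.sample_hky:
        applicable |= {"kappa_scale", "nu_scale", "freq_walk"}
    if state.gene_trees is not None:
        applicable.add("gene_height")
    names = [nm for nm in w if nm in applicable and w[nm] > 0]
    probs = np.asarray([w[nm] for nm in names], dtype=float)
    return names, probs / probs.sum()


# ----------------------------------------------------------------------
# Trace and driver
# ----------------------------------------------------------------------

@dataclass
class Trace:
    """Logged scalar states, tree log, and per-operator acceptance counts."""

    scalars: pd.DataFrame
    trees: list[str]
    acceptance: dict[str, tuple[int, int]] = field(default_factory=dict)
    burnin_fraction: float = 0.5

    def post_burnin(self) -> pd.DataFrame:
        cut = int(len(self.scalars) * self.burnin_fraction)
        return self.scalars.iloc[cut:]

    def post_burnin_trees(self) -> list[str]:
        cut = int(len(self.trees) * self.burnin_fraction)
        return self.trees[cut:]

    def write_scalars(self, path) -> None:
        self.scalars.to_csv(path, sep="\t", index=False)

    def write_trees(self, path, labels=None) -> None:
        from .tree import parse_newick, write_tree_log

        write_tree_log([parse_newick(t) for t in self.trees], path)


def _single_linkage_init_tree(genes: Sequence[GeneReplicate]) -> TimeTree:
    """Species tree from single-linkage clustering of cross-species gene
    coalescence times.

    The distance between two species is the minimum MRCA height of any
    cross pair over all gene trees.  Single-linkage cophenetic distances
    never exceed the input distances, so the resulting tree (scaled just
    below the merge heights) satisfies every MSC constraint -- a valid,
    data-shaped starting state.
    """
    from scipy.cluster.hierarchy import linkage
    from scipy.spatial.distance import squareform

    species = sorted({sp for g in genes for sp in g.mapping.values()})
    idx = {sp: i for i, sp in enumerate(species)}
    ns = len(species)
    dist = np.full((ns, ns), np.inf)
    for gene in genes:
        gt = gene.gene_tree
        # MRCA heights of all leaf pairs by walking up from each leaf
        anc: list[dict[int, float]] = []
        for leaf in range(gt.n_leaves):
            path = {}
            node = leaf
            while node >= 0:
                path[node] = float(gt.heights[node])
                node = int(gt.parent[node])
            anc.append(path)
        for a in range(gt.n_leaves):
            sa = idx[gene.mapping[gt.labels[a]]]
            for b in range(a + 1, gt.n_leaves):
                sb = idx[gene.mapping[gt.labels[b]]]
                if sa == sb:
                    continue
                node = b
                while node not in anc[a]:
                    node = int(gt.parent[node])
                h = anc[a][node]
                if h < dist[sa, sb]:
                    dist[sa, sb] = dist[sb, sa] = h
    z = linkage(squareform(dist, checks=False), method="single")
    m = 2 * ns - 1
    parent = np.full(m, -1, dtype=np.int64)
    left = np.full(m, -1, dtype=np.int64)
    right = np.full(m, -1, dtype=np.int64)
    heights = np.zeros(m)
    floor = 0.0
    for j, (a, b, h, _) in enumerate(z):
        node = ns + j
        h = h * (1.0 - 1e-6)
        if h <= floor:  # enforce strictly increasing merge heights
            h = floor * (1.0 + 1e-9) + 1e-300
        floor = h
        heights[node] = h
        left[node], right[node] = int(a), int(b)
        parent[int(a)] = parent[int(b)] = node
    return TimeTree(species, parent, left, right, heights)


def _init_state(model: CollapseModel, rng: np.random.Generator) -> McmcState:
    a, b = model.omega_prior
    omega = a / (a + b)
    if model.likelihood != "none":
        # taxa are the species named in the sample maps
        species = sorted({sp for g in model.genes for sp in g.mapping.values()})
    elif model.taxa is not None:
        species = list(model.taxa)
    else:
        species = [f"t{i + 1}" for i in range(6)]
    n = len(species)
    cfg = CollapseConfig(model.epsilon, omega)
    if model.likelihood != "none":
        # data-shaped start: single-linkage tree from gene coalescence times
        tree = _single_linkage_init_tree(model.genes)
    elif model.slab == "yule_skyline":
        tree = sample_tree_from_ysc_prior(
            n, cfg, model.sky, rng, labels=species, n_particles=256
        )
    elif model.slab == "exponential":
        tree = sample_tree_from_collapse_prior(n, cfg, model.exp_lam, rng, labels=species)
    else:
        for _ in range(200):
            tree = sample_tree_from_collapse_prior(
                n, cfg, model.bd.lam, rng, labels=species
            )
            if tree.root_height < model.bd.origin:
                break
        else:
            raise InitializationError("could not draw a tree below the origin height")
    state = McmcState(tree=tree, omega=omega)
    if model.likelihood != "none":
        state.pops = model.init_pops
        if state.pops is None:
            raise InitializationError("likelihood mode needs init_pops")
        if model.likelihood == "msc_hky":
            state.gene_trees = [g.gene_tree.copy() for g in model.genes]
            if model.sample_hky:
                state.hky = [g.hky for g in model.genes]
    return state


def run_mcmc(
    model: CollapseModel,
    chain_length: int,
    log_every: int,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    init: McmcState | None = None,
    weights: dict[str, float] | None = None,
    ess_target: float | None = None,
    max_extensions: int = 3,
    audit_every: int = 1000,
    break_hastings: bool = False,
) -> Trace:
    """Run the Metropolis-Hastings chain and return its trace.

    The trace logs every ``log_every`` steps (state 0 included).  When
    ``ess_target`` is set, the chain is extended (doubling, up to
    ``max_extensions`` times) until the effective sample size of the
    posterior column after a 50% burn-in exceeds the target.

    ``break_hastings`` zeroes every log Hastings ratio; this deliberately
    broken sampler exists for negative-control validation only.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    state = model.evaluate(init.shallow() if init else _init_state(model, rng))
    if state.log_prior == NEG_INF:
        raise InitializationError("initial state has zero prior density")
    if state.log_likelihood == NEG_INF:
        raise InitializationError("initial state has zero likelihood")

    names, probs = _build_schedule(state, model, weights)
    accept: dict[str, list[int]] = {nm: [0, 0] for nm in names}
    rows: list[dict] = []
    trees: list[str] = []
    step = 0

    def log_state() -> None:
        h, ln = tree_statistics(state.tree)
        row = {
            "Sample": step,
            "posterior": state.log_posterior,
            "likelihood": state.log_likelihood,
            "prior": state.log_prior,
            "TreeHeight": h,
            "TreeLength": ln,
            "omega": state.omega,
            "k": count_collapsed(state.tree, model.epsilon),
        }
        if state.pops is not None:
            row["mu_N"] = state.pops.mean
        rows.append(row)
        trees.append(state.tree.to_newick(precision=12))

    cum = np.cumsum(probs)

    def run_segment(n_steps: int) -> None:
        nonlocal state, step
        for _ in range(n_steps):
            step += 1
            nm = names[int(np.searchsorted(cum, rng.random()))]
            accept[nm][1] += 1
            res = _OPERATORS[nm](state, model, rng)
            if res is not None:
                proposal, log_hr = res
                if break_hastings:
                    log_hr = 0.0
                if log_hr > NEG_INF:
                    model.evaluate(proposal)
                    delta = proposal.log_posterior - state.log_posterior
                    if delta + log_hr >= 0 or rng.random() < math.exp(
                        min(0.0, delta + log_hr)
                    ):
                        state = proposal
                        accept[nm][0] += 1
            if step % log_every == 0:
                log_state()
            if audit_every and step % audit_every == 0:
                cached = state.log_posterior
                model.evaluate(state)
                if not math.isclose(
                    cached, state.log_posterior, rel_tol=1e-8, abs_tol=1e-8
                ):
                    raise RuntimeError(
                        f"cache drift at step {step}: {cached} vs {state.log_posterior}"
                    )

    log_state()
    run_segment(chain_length)
    if ess_target is not None:
        from .validate import effective_sample_size

        total = chain_length
        for _ in range(max_extensions):
            post = np.asarray(
                [r["posterior"] for r in rows[len(rows) // 2:]], dtype=float
            )
            if post.size >= 10 and effective_sample_size(post) >= ess_target:
                break
            run_segment(total)
            total *= 2

    return Trace(
        scalars=pd.DataFrame(rows),
        trees=trees,
        acceptance={nm: (a, t) for nm, (a, t) in accept.items()},
    )
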