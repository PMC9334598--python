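"""Shared independent oracles used by several test modules."""

import itertools
import math

import numpy as np
from scipy.linalg import expm

from speciesdelim.hky import hky_rate_matrix
from speciesdelim.mcmc import (
    _node_height_tree,
    _root_gap_scale_tree,
    _threshold_uniform_tree,
)
from speciesdelim.priors import (
    collapse_log_prior,
    exp_slab_log_density,
    sample_tree_from_collapse_prior,
)
from speciesdelim.tree import count_collapsed

BASES = "ACGT"


def run_isolated_threshold_chain(n, cfg, lam, steps, thin, seed):
    """Manual MH chain over the exponential-slab collapse prior using only
    the ThresholdUniform kernel plus side-preserving height moves and a
    root scale (the complementary reachability operators)."""
    rng = np.random.default_rng(seed)
    tree = sample_tree_from_collapse_prior(n, cfg, lam, rng)
    target = lambda t: collapse_log_prior(
        t, lambda h: exp_slab_log_density(h, cfg.epsilon, lam), cfg
    )
    lp = target(tree)
    ks, roots = [], []
    for step in range(steps):
        u = rng.random()
        if u < 0.5:
            res = _threshold_uniform_tree(tree, cfg.epsilon, rng)
        elif u < 0.8:
            res = _node_height_tree(
                tree, rng, side_preserving=True, epsilon=cfg.epsilon
            )
        else:
            res = _root_gap_scale_tree(tree, rng)
        if res is not None:
            new, log_hr = res
            lp_new = target(new)
            if log_hr > -math.inf and math.log(rng.random()) < lp_new - lp + log_hr:
                tree, lp = new, lp_new
        if step % thin == 0:
            ks.append(count_collapsed(tree, cfg.epsilon))
            roots.append(tree.root_height)
    return np.array(ks), np.array(roots)


def brute_force_loglik(tree, alignment, hky):
    """Pruning-likelihood oracle: sum over all internal state assignments
    (practical for trees with <= 4 leaves)."""
    q = hky_rate_matrix(hky)
    mats = {
        i: expm(q * hky.nu * tree.branch_length(i))
        for i in range(tree.n_nodes)
        if i != tree.root
    }
    L = len(next(iter(alignment.values())))
    total = 0.0
    internals = list(tree.internal_nodes)
    for site in range(L):
        p_site = 0.0
        for assign in itertools.product(range(4), repeat=len(internals)):
            states = {i: assign[j] for j, i in enumerate(internals)}
            for leaf in range(tree.n_leaves):
                states[leaf] = BASES.index(alignment[tree.labels[leaf]][site])
            p = hky.freqs[states[tree.root]]
            for i in range(tree.n_nodes):
                if i != tree.root:
                    p *= mats[i][states[int(tree.parent[i])], states[i]]
            p_site += p
        total += math.log(p_site)
    return total
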