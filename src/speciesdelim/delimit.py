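"""Posterior summaries of species boundaries, hypothesis-space accounting,
and threshold-selection guidance.

A posterior tree log is reduced to species assignments by cutting every
sampled tree at the threshold epsilon; the resulting partitions are
tallied into partition supports, per-cluster marginal supports, a
maximal-posterior (MAP) clustering, and a pairwise co-species
probability matrix.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
import numpy as np
import pandas as pd

from .tree import Partition, TimeTree, extract_clusters, read_tree_log

__all__ = [
    "ClusteringSummary",
    "partition_frequencies",
    "map_clustering",
    "cospecies_matrix",
    "bell_number",
    "bayes_factor",
    "epsilon_guidance",
    "convert_epsilon_units",
]


def _load(tree_log, burnin_fraction: float) -> list[TimeTree]:
    if isinstance(tree_log, (str,)) or hasattr(tree_log, "__fspath__"):
        trees = read_tree_log(tree_log)
    else:
        trees = list(tree_log)
    if not trees:
        raise ValueError("empty tree log")
    if not 0.0 <= burnin_fraction < 1.0:
        raise ValueError("burnin_fraction must be in [0, 1)")
    cut = int(len(trees) * burnin_fraction)
    trees = trees[cut:]
    if not trees:
        raise ValueError("no post-burn-in samples")
    return trees


def partition_frequencies(
    tree_log, epsilon: float, burnin_fraction: float = 0.5
) -> dict[Partition, float]:
    """Relative frequency of each canonical partition in the post-burn-in log."""
    trees = _load(tree_log, burnin_fraction)
    counts = Counter(extract_clusters(t, epsilon) for t in trees)
    total = sum(counts.values())
    return {p: c / total for p, c in counts.items()}


@dataclass
class ClusteringSummary:
    """MAP partition with supports; ``ties`` lists co-maximal partitions, if any."""

    partition: Partition
    support: float
    cluster_marginals: dict[tuple[str, ...], float]
    epsilon: float
    ties: list[Partition] = field(default_factory=list)


def map_clustering(
    tree_log, epsilon: float, burnin_fraction: float = 0.5
) -> ClusteringSummary:
    """Maximal-posterior partition; ties broken lexicographically on canonical form.

    Each cluster's marginal support is the fraction of samples in which
    that exact cluster appears (exact set equality).
    """
    trees = _load(tree_log, burnin_fraction)
    parts = [extract_clusters(t, epsilon) for t in trees]
    counts = Counter(parts)
    best = max(counts.values())
    winners = sorted(
        [p for p, c in counts.items() if c == best], key=lambda p: p.clusters
    )
    chosen = winners[0]
    cluster_counts: Counter = Counter()
    for p in parts:
        cluster_counts.update(p.clusters)
    marginals = {
        c: cluster_counts[c] / len(parts) for c in chosen.clusters
    }
    return ClusteringSummary(
        partition=chosen,
        support=best / len(parts),
        cluster_marginals=marginals,
        epsilon=epsilon,
        ties=winners[1:],
    )


def cospecies_matrix(
    tree_log, epsilon: float, burnin_fraction: float = 0.5
) -> pd.DataFrame:
    """Taxon-by-taxon probability of sharing a cluster (symmetric, unit diagonal)."""
    trees = _load(tree_log, burnin_fraction)
    taxa = sorted(trees[0].labels)
    idx = {t: i for i, t in enumerate(taxa)}
    mat = np.zeros((len(taxa), len(taxa)))
    for t in trees:
        for cluster in extract_clusters(t, epsilon):
            for a in cluster:
                for b in cluster:
                    mat[idx[a], idx[b]] += 1
    mat /= len(trees)
    return pd.DataFrame(mat, index=taxa, columns=taxa)


def bell_number(n: int) -> int:
    """Exact Bell number B_n (number of set partitions) via the Bell triangle."""
    if n < 0:
        raise ValueError("n must be >= 0")
    row = [1]
    for _ in range(n):
        nxt = [row[-1]]
        for v in row:
            nxt.append(nxt[-1] + v)
        row = nxt
    return row[0]


def bayes_factor(ml_alt: float, ml_base: float) -> float:
    """BF = 2 (ln ML_alt - ln ML_base), the SNP Bayes-factor-delimitation convention."""
    if not (math.isfinite(ml_alt) and math.isfinite(ml_base)):
        raise ValueError("marginal likelihoods must be finite")
    return 2.0 * (ml_alt - ml_base)


def epsilon_guidance(pairwise_divergence: float) -> float:
    """Upper bound on epsilon from a known between-species pairwise divergence.

    The threshold should be *much less than* half the divergence (half,
    because both lineages contribute to the pairwise distance).  Returns
    divergence / 2; read the result as "epsilon << value".
    """
    if not pairwise_divergence > 0:
        raise ValueError("divergence must be > 0")
    return pairwise_divergence / 2.0


#: conversion factors to years for the time-like units
_TO_YEARS = {
    "years": 1.0,
    "millennia": 1e3,
    "millions_of_years": 1e6,
}


def convert_epsilon_units(
    epsilon: float,
    from_units: str,
    to_units: str,
    clock_rate: float | None = None,
) -> float:
    """Convert a threshold between height units.

    Units: ``years``, ``millennia``, ``millions_of_years`` or
    ``substitutions_per_site``.  Converting between time and
    substitutions requires ``clock_rate`` in substitutions per site per
    year.
    """
    units = set(_TO_YEARS) | {"substitutions_per_site"}
    for u in (from_units, to_units):
        if u not in units:
            raise ValueError(f"unknown units {u!r}; choose from {sorted(units)}")
    if from_units == to_units:
        return epsilon
    # hub through years
    if from_units == "substitutions_per_site":
        if clock_rate is None:
            raise ValueError("time <-> substitutions conversion needs a clock_rate")
        years = epsilon / clock_rate
    else:
        years = epsilon * _TO_YEARS[from_units]
    if to_units == "substitutions_per_site":
        if clock_rate is None:
            raise ValueError("time <-> substitutions conversion needs a clock_rate")
        return years * clock_rate
    return years / _TO_YEARS[to_units]
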