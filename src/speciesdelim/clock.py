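"""Molecular clock models: strict, and species-branch lognormal relaxed rates.

Under the relaxed mode each species-tree branch carries an iid rate
r ~ Lognormal(mu=-S^2/2, sigma=S), a mean-one parameterisation so the
expected branch rate is 1 for any stdev S.  A gene-tree branch inherits
the time-weighted average of the species-branch rates it traverses, so
no per-gene rate parameters are introduced.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .coalescent import gene_edge_species_intervals
from .tree import TimeTree

__all__ = ["ClockModel", "simulate_branch_rates", "gene_branch_rates"]


@dataclass(frozen=True)
class ClockModel:
    """Strict clock (constant ``rate``) or species-branch lognormal relaxed clock.

    ``stdev`` is the lognormal sigma S of the relaxed mode (mean-one
    parameterisation, mu = -S^2/2); ignored when ``mode == "strict"``.
    """

    mode: str = "strict"
    rate: float = 1.0
    stdev: float | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("strict", "relaxed_lognormal"):
            raise ValueError(f"unknown clock mode {self.mode!r}")
        if not self.rate > 0:
            raise ValueError("clock rate must be > 0")
        if self.mode == "relaxed_lognormal" and not (self.stdev and self.stdev > 0):
            raise ValueError("relaxed clock needs stdev S > 0")


def simulate_branch_rates(
    species_tree: TimeTree, S: float, rng: np.random.Generator
) -> dict[int, float]:
    """Draw iid Lognormal(-S^2/2, S) rates, one per species branch (root stem included)."""
    if not S > 0:
        raise ValueError("stdev S must be > 0")
    mu = -0.5 * S * S
    return {
        i: float(rng.lognormal(mu, S)) for i in range(species_tree.n_nodes)
    }


def gene_branch_rates(
    gene_tree: TimeTree,
    species_tree: TimeTree,
    mapping: Mapping[str, str],
    species_rates: Mapping[int, float],
) -> dict[int, float]:
    """Time-weighted average species rate along each gene branch.

    Returns a rate per non-root gene node (the branch above it).  A
    zero-length gene branch inherits the rate of the species branch its
    base sits in.
    """
    intervals = gene_edge_species_intervals(gene_tree, species_tree, mapping)
    rates: dict[int, float] = {}
    for c, segs in intervals.items():
        total = sum(t1 - t0 for _, t0, t1 in segs if math.isfinite(t1))
        if total <= 0:
            rates[c] = float(species_rates[segs[0][0]])
            continue
        acc = sum(
            species_rates[v] * (t1 - t0) for v, t0, t1 in segs if math.isfinite(t1)
        )
        rates[c] = float(acc / total)
    return rates
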