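"""HKY nucleotide substitution: simulation and Felsenstein pruning likelihood.

The HKY rate matrix has transition rate kappa * f_j and transversion
rate f_j into state j, is normalised to one expected substitution per
unit time at stationarity, and is then scaled by the substitution rate
nu and any per-branch clock rate.  Gaps, ``N`` and ``?`` are missing
data (partial likelihood 1 in every state).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy.linalg import expm

from .tree import TimeTree

__all__ = ["HKYParams", "hky_rate_matrix", "simulate_alignment", "hky_log_likelihood"]

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}
MISSING = set("-N?n")
#: transitions are A<->G and C<->T
_TRANSITION = np.zeros((4, 4), dtype=bool)
for _a, _b in ((0, 2), (1, 3)):
    _TRANSITION[_a, _b] = _TRANSITION[_b, _a] = True


@dataclass(frozen=True)
class HKYParams:
    """Transition-transversion ratio kappa, base frequencies f, substitution rate nu."""

    kappa: float
    freqs: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))
    nu: float = 1.0

    def __post_init__(self) -> None:
        f = np.asarray(self.freqs, dtype=float)
        object.__setattr__(self, "freqs", f)
        if f.shape != (4,) or np.any(f < 0) or abs(f.sum() - 1.0) > 1e-12:
            raise ValueError("freqs must be 4 nonnegative reals summing to 1")
        if not self.kappa > 0:
            raise ValueError("kappa must be > 0")
        if not self.nu > 0:
            raise ValueError("nu must be > 0")


def hky_rate_matrix(hky: HKYParams) -> np.ndarray:
    """Normalised HKY generator Q (rows sum to 0; 1 expected substitution/unit time)."""
    f = hky.freqs
    q = np.where(_TRANSITION, hky.kappa, 1.0) * f[None, :]
    np.fill_diagonal(q, 0.0)
    np.fill_diagonal(q, -q.sum(axis=1))
    mu = -float(np.dot(f, np.diag(q)))
    return q / mu


def _branch_matrices(
    tree: TimeTree, hky: HKYParams, branch_rates: Mapping[int, float] | None
) -> dict[int, np.ndarray]:
    q = hky_rate_matrix(hky)
    mats: dict[int, np.ndarray] = {}
    for i in range(tree.n_nodes):
        if i == tree.root:
            continue
        rate = 1.0 if branch_rates is None else float(branch_rates[i])
        t = tree.branch_length(i) * hky.nu * rate
        mats[i] = expm(q * t)
    return mats


def simulate_alignment(
    gene_tree: TimeTree,
    hky: HKYParams,
    L: int,
    rng: np.random.Generator,
    branch_rates: Mapping[int, float] | None = None,
) -> dict[str, str]:
    """Simulate an L-site alignment down the gene tree (iid sites).

    Root states are drawn from the stationary frequencies; states mutate
    along each branch with the matrix exponential of the scaled HKY
    generator.  Returns ``{leaf label: sequence}``.
    """
    if L < 1:
        raise ValueError("need at least one site")
    mats = _branch_matrices(gene_tree, hky, branch_rates)
    states = np.empty((gene_tree.n_nodes, L), dtype=np.int64)
    states[gene_tree.root] = rng.choice(4, size=L, p=hky.freqs)
    order = sorted(
        range(gene_tree.n_nodes), key=lambda i: -gene_tree.heights[i]
    )
    u = rng.random((gene_tree.n_nodes, L))
    for i in order:
        if i == gene_tree.root:
            continue
        p = mats[i]  # rows: parent state
        cum = np.cumsum(p, axis=1)
        parent_states = states[gene_tree.parent[i]]
        states[i] = (u[i][:, None] > cum[parent_states]).sum(axis=1)
    return {
        gene_tree.labels[leaf]: "".join(BASES[s] for s in states[leaf])
        for leaf in range(gene_tree.n_leaves)
    }


def _leaf_partials(seq: str) -> np.ndarray:
    out = np.zeros((len(seq), 4))
    for j, ch in enumerate(seq):
        c = ch.upper()
        if c in BASE_INDEX:
            out[j, BASE_INDEX[c]] = 1.0
        elif ch in MISSING:
            out[j, :] = 1.0
        else:
            raise ValueError(f"unknown character {ch!r} in alignment")
    return out


def hky_log_likelihood(
    tree: TimeTree,
    alignment: Mapping[str, str],
    hky: HKYParams,
    branch_rates: Mapping[int, float] | None = None,
) -> float:
    """Felsenstein pruning log likelihood of an alignment on a time tree.

    Site patterns are compressed before pruning; per-node scaling keeps
    partials in range.  Alignment keys must match the tree's leaf labels
    exactly.
    """
    if set(alignment) != set(tree.labels):
        missing = set(tree.labels) ^ set(alignment)
        raise ValueError(f"alignment/tree leaf mismatch: {sorted(missing)}")
    lengths = {len(s) for s in alignment.values()}
    if len(lengths) != 1:
        raise ValueError("ragged alignment")
    (L,) = lengths
    if L < 1:
        raise ValueError("empty alignment")

    cols = list(zip(*[alignment[lab] for lab in tree.labels]))
    patterns: dict[tuple[str, ...], int] = {}
    counts: list[int] = []
    for col in cols:
        if col in patterns:
            counts[patterns[col]] += 1
        else:
            patterns[col] = len(counts)
            counts.append(1)
    P = len(counts)
    weights = np.asarray(counts, dtype=float)

    mats = _branch_matrices(tree, hky, branch_rates)
    partials = np.empty((tree.n_nodes, P, 4))
    for leaf in range(tree.n_leaves):
        seq = "".join(col[leaf] for col in patterns)
        partials[leaf] = _leaf_partials(seq)

    log_scale = np.zeros(P)
    order = sorted(tree.internal_nodes, key=lambda i: tree.heights[i])
    for i in order:
        l, r = tree.children(i)
        pl = partials[l] @ mats[l].T
        pr = partials[r] @ mats[r].T
        vals = pl * pr
        mx = vals.max(axis=1)
        mx = np.where(mx > 0, mx, 1.0)
        partials[i] = vals / mx[:, None]
        log_scale += np.log(mx)

    # n == 1 degenerate case: likelihood is just the root frequencies
    site = partials[tree.root] @ hky.freqs
    if np.any(site <= 0):
        return float("-inf")
    return float(np.dot(weights, np.log(site) + log_scale))
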