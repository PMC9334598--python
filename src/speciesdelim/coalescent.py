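"""Multispecies coalescent (MSC): gene-tree simulation and log density.

Gene trees evolve inside a species tree.  Within the branch above a
species-tree node, each pair of gene lineages coalesces at rate 1/Ne
(Ne in tree-time units); lineages that fail to coalesce are handed to
the parent branch, and above the species root a single panmictic
population with the root-stem Ne absorbs the remainder.

The package stores effective population sizes Ne directly.  SNP-style
"coalescent rate" parameterisations (rate r with theta = 2/r) are
converted via :meth:`PopSizeMap.from_coalescent_rates`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .tree import TimeTree

__all__ = [
    "PopSizeMap",
    "MSCIncompatibleError",
    "simulate_gene_tree",
    "msc_log_density",
    "gene_edge_species_intervals",
]

NEG_INF = float("-inf")


class MSCIncompatibleError(ValueError):
    """A gene tree violates its species-tree constraints."""


@dataclass
class PopSizeMap:
    """Effective population size per species-tree branch.

    One entry per node id of the species tree (the branch *above* that
    node; the root entry is the root stem governing coalescence above
    the species root).
    """

    sizes: dict[int, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for i, ne in self.sizes.items():
            if not ne > 0:
                raise ValueError(f"Ne for branch {i} must be > 0, got {ne}")

    def __getitem__(self, node: int) -> float:
        return self.sizes[node]

    @classmethod
    def constant(cls, tree: TimeTree, ne: float) -> "PopSizeMap":
        return cls({i: float(ne) for i in range(tree.n_nodes)})

    @classmethod
    def from_coalescent_rates(cls, rates: Mapping[int, float]) -> "PopSizeMap":
        """Convert per-branch pairwise coalescent rates r to Ne = 2/r."""
        return cls({i: 2.0 / r for i, r in rates.items()})

    @property
    def mean(self) -> float:
        return float(np.mean(list(self.sizes.values())))


# ----------------------------------------------------------------------
# Simulation
# ----------------------------------------------------------------------

def simulate_gene_tree(
    species_tree: TimeTree,
    pops: PopSizeMap,
    samples_per_species: int | Mapping[str, int],
    rng: np.random.Generator,
) -> tuple[TimeTree, dict[str, str]]:
    """Simulate one gene tree under the MSC inside ``species_tree``.

    Returns the gene tree (leaves labelled ``"<species>_<i>"``) and the
    sample-to-species map.  Species with zero samples contribute no
    lineages.
    """
    n_sp = species_tree.n_leaves
    if isinstance(samples_per_species, int):
        counts = {lab: samples_per_species for lab in species_tree.labels}
    else:
        counts = {lab: int(samples_per_species.get(lab, 0)) for lab in species_tree.labels}
    if any(c < 0 for c in counts.values()):
        raise ValueError("sample counts must be >= 0")
    total = sum(counts.values())
    if total < 1:
        raise ValueError("at least one sample is required")

    labels: list[str] = []
    mapping: dict[str, str] = {}
    leaf_of_species: dict[int, list[int]] = {}
    for sp_leaf in range(n_sp):
        sp = species_tree.labels[sp_leaf]
        ids = []
        for j in range(counts[sp]):
            lab = f"{sp}_{j + 1}"
            mapping[lab] = sp
            ids.append(len(labels))
            labels.append(lab)
        leaf_of_species[sp_leaf] = ids

    m = 2 * total - 1
    parent = np.full(m, -1, dtype=np.int64)
    left = np.full(m, -1, dtype=np.int64)
    right = np.full(m, -1, dtype=np.int64)
    heights = np.zeros(m)
    next_id = total

    pending: dict[int, list[int]] = {}  # species node -> gene lineages entering its branch
    order = sorted(range(species_tree.n_nodes), key=lambda i: (species_tree.heights[i], i))
    for v in order:
        lineages = list(pending.pop(v, []))
        if species_tree.is_leaf(v):
            lineages.extend(leaf_of_species[v])
        t = float(species_tree.heights[v])
        pv = int(species_tree.parent[v])
        t_top = math.inf if pv < 0 else float(species_tree.heights[pv])
        ne = pops[v]
        while len(lineages) > 1:
            npairs = len(lineages) * (len(lineages) - 1) / 2.0
            t = t + rng.exponential(ne / npairs)
            if t >= t_top:
                break
            i = int(rng.integers(len(lineages)))
            a = lineages.pop(i)
            i = int(rng.integers(len(lineages)))
            b = lineages.pop(i)
            node = next_id
            next_id += 1
            heights[node] = t
            left[node], right[node] = a, b
            parent[a] = parent[b] = node
            lineages.append(node)
        if pv >= 0:
            pending.setdefault(pv, []).extend(lineages)
    assert next_id == m, "coalescent bookkeeping failed"
    gene_tree = TimeTree(labels, parent, left, right, heights)
    return gene_tree, mapping


# ----------------------------------------------------------------------
# Density
# ----------------------------------------------------------------------

def _locate(
    gene_tree: TimeTree,
    species_tree: TimeTree,
    mapping: Mapping[str, str],
) -> tuple[dict[int, int], dict[int, list[tuple[int, float, float]]]]:
    """Assign gene-tree coalescences and edge segments to species branches.

    Returns ``(event_branch, edge_intervals)`` where ``event_branch``
    maps each gene internal node to the species node whose branch hosts
    the coalescence, and ``edge_intervals[c]`` lists
    ``(species_node, t0, t1)`` segments of the branch above gene node
    ``c``.  Raises :class:`MSCIncompatibleError` on constraint violation.
    """
    sp_index = {lab: i for i, lab in enumerate(species_tree.labels)}
    sp_h = species_tree.heights
    sp_parent = species_tree.parent

    base_branch: dict[int, int] = {}
    for g_leaf, lab in enumerate(gene_tree.labels):
        sp = mapping.get(lab)
        if sp is None:
            raise MSCIncompatibleError(f"sample {lab!r} missing from the species map")
        if sp not in sp_index:
            raise MSCIncompatibleError(f"species {sp!r} not in the species tree")
        base_branch[g_leaf] = sp_index[sp]

    def climb(v: int, h: float) -> int:
        while sp_parent[v] >= 0 and sp_h[sp_parent[v]] <= h:
            v = int(sp_parent[v])
        return v

    event_branch: dict[int, int] = {}
    cur: dict[int, int] = dict(base_branch)
    for g in sorted(gene_tree.internal_nodes, key=lambda i: gene_tree.heights[i]):
        h = float(gene_tree.heights[g])
        c1, c2 = gene_tree.children(g)
        v1 = climb(cur[c1], h)
        v2 = climb(cur[c2], h)
        if v1 != v2:
            raise MSCIncompatibleError(
                f"gene coalescence at height {h:.6g} predates the species-tree "
                "ancestor of its descendants"
            )
        event_branch[g] = v1
        base_branch[g] = v1
        cur[g] = v1

    edge_intervals: dict[int, list[tuple[int, float, float]]] = {}
    for c in range(gene_tree.n_nodes):
        if c == gene_tree.root:
            continue
        h0 = float(gene_tree.heights[c])
        h1 = float(gene_tree.heights[gene_tree.parent[c]])
        v = base_branch[c]
        segs: list[tuple[int, float, float]] = []
        t = h0
        while True:
            top = math.inf if sp_parent[v] < 0 else float(sp_h[sp_parent[v]])
            hi = min(h1, top)
            if hi > t:
                segs.append((v, t, hi))
                t = hi
            if h1 <= top or sp_parent[v] < 0:
                break
            v = int(sp_parent[v])
        edge_intervals[c] = segs
    return event_branch, edge_intervals


def gene_edge_species_intervals(
    gene_tree: TimeTree, species_tree: TimeTree, mapping: Mapping[str, str]
) -> dict[int, list[tuple[int, float, float]]]:
    """Species-branch segments traversed by each gene-tree branch.

    Used by the relaxed-clock machinery to time-average species branch
    rates along gene branches.
    """
    _, intervals = _locate(gene_tree, species_tree, mapping)
    return intervals


def msc_log_density(
    gene_tree: TimeTree,
    species_tree: TimeTree,
    pops: PopSizeMap,
    mapping: Mapping[str, str],
) -> float:
    """Rannala-Yang MSC log density of a gene tree given the species tree.

    Product over species branches of per-event factors 1/Ne and survival
    factors exp(-C(i,2) dt / Ne).  Incompatible gene trees get -inf (a
    legal zero density, not an error).
    """
    try:
        event_branch, edge_intervals = _locate(gene_tree, species_tree, mapping)
    except MSCIncompatibleError:
        return NEG_INF

    # per species branch: occupancy breakpoints and event count
    events: dict[int, int] = {}
    for g, v in event_branch.items():
        events[v] = events.get(v, 0) + 1
    points: dict[int, list[tuple[float, int]]] = {}
    for segs in edge_intervals.values():
        for v, t0, t1 in segs:
            points.setdefault(v, []).append((t0, +1))
            points.setdefault(v, []).append((t1, -1))

    lp = 0.0
    for v, pts in points.items():
        ne = pops[v]
        pts.sort()
        active = 0
        prev = None
        for t, d in pts:
            if prev is not None and active >= 2 and t > prev:
                lp -= active * (active - 1) / 2.0 * (t - prev) / ne
            active += d
            prev = t
        lp -= events.get(v, 0) * math.log(ne)
    # branches hosting events but no recorded occupancy cannot occur:
    # every event lies on some gene edge except the gene root, whose
    # children edges still cover the branch below it.
    return float(lp)
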