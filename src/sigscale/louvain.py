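"""Louvain-style multi-level greedy optimization of Significance or Modularity.

The procedure is the classic two-phase loop: repeated single-node moves to the
best strictly-improving neighboring community (or to isolation), followed by
aggregation of communities into supernodes, until a level produces no merge.
Because Significance depends on the number of *original* vertices and the
internal density of each community, supernodes carry their original vertex
count and internal edge count and the original global density is held fixed
across levels.

An exhaustive set-partition enumerator is provided as a ground-truth oracle for
small graphs (n <= 12).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Hashable, Mapping

import networkx as nx
import numpy as np

from .quality import PartitionState, ResolutionConfig, _null_density, _sig_term

__all__ = [
    "OptimizerSettings",
    "AggregatedGraph",
    "optimize",
    "aggregate",
    "exhaustive_optimum",
]


@dataclass(frozen=True)
class OptimizerSettings:
    """Reproducibility and convergence knobs for :func:`optimize`.

    The same seed on the same input yields the identical partition.  A level
    ends when a full sweep makes no move or ``max_sweeps_per_level`` is hit;
    the algorithm ends when aggregation produces no change (or after
    ``max_levels`` levels if set).
    """

    config: ResolutionConfig = field(default_factory=ResolutionConfig)
    seed: int = 0
    max_sweeps_per_level: int = 100
    max_levels: int | None = None

    def __post_init__(self) -> None:
        if self.max_sweeps_per_level < 1:
            raise ValueError("max_sweeps_per_level must be >= 1")


@dataclass
class AggregatedGraph:
    """Coarse graph whose supernodes carry original vertex/edge bookkeeping.

    ``sizes[i]`` counts original vertices inside supernode i, ``internal[i]``
    counts original edges inside it, and ``adj[i][j]`` is the original edge
    multiplicity between supernodes i and j.  ``n_total``/``m_total`` are the
    ORIGINAL graph's counts, so scoring the trivial partition of an aggregate
    equals scoring the inducing partition on the original graph.
    """

    sizes: list[int]
    internal: list[int]
    adj: list[dict[int, int]]
    n_total: int
    m_total: int

    @classmethod
    def from_graph(cls, graph: nx.Graph) -> tuple["AggregatedGraph", list[Hashable]]:
        nodes = list(graph.nodes)
        index = {v: i for i, v in enumerate(nodes)}
        k = len(nodes)
        adj: list[dict[int, int]] = [dict() for _ in range(k)]
        m = 0
        for u, v in graph.edges:
            if u == v:
                continue
            iu, iv = index[u], index[v]
            adj[iu][iv] = adj[iu].get(iv, 0) + 1
            adj[iv][iu] = adj[iv].get(iu, 0) + 1
            m += 1
        return cls([1] * k, [0] * k, adj, k, m), nodes

    def number_of_supernodes(self) -> int:
        return len(self.sizes)

    def trivial_score(self, config: ResolutionConfig) -> float:
        """Score of the each-supernode-alone partition (equals the score of the
        inducing partition on the original graph)."""
        state = PartitionState(
            self.sizes, self.internal, self.adj, self.n_total, self.m_total, config
        )
        return state.score()


def aggregate(
    graph: nx.Graph | AggregatedGraph, partition: Mapping | list
) -> AggregatedGraph:
    """Merge each community of ``partition`` into one supernode.

    ``partition`` maps nodes (for a Graph) or supernode indices (for an
    AggregatedGraph) to community labels.  Sizes and internal edge counts
    accumulate; the original global density is carried through unchanged.
    """
    if isinstance(graph, nx.Graph):
        agg, nodes = AggregatedGraph.from_graph(graph)
        membership_src = [partition[v] for v in nodes]
    else:
        agg = graph
        if isinstance(partition, Mapping):
            membership_src = [partition[i] for i in range(agg.number_of_supernodes())]
        else:
            membership_src = list(partition)
        if len(membership_src) != agg.number_of_supernodes():
            raise ValueError("partition does not cover all supernodes")
    labels: dict[Hashable, int] = {}
    comm = []
    for c in membership_src:
        if c not in labels:
            labels[c] = len(labels)
        comm.append(labels[c])
    k = len(labels)
    sizes = [0] * k
    internal = [0] * k
    adj: list[dict[int, int]] = [dict() for _ in range(k)]
    for i in range(len(comm)):
        ci = comm[i]
        sizes[ci] += agg.sizes[i]
        internal[ci] += agg.internal[i]
        for j, w in agg.adj[i].items():
            if j > i:
                continue
            cj = comm[j]
            if ci == cj:
                internal[ci] += w
            else:
                adj[ci][cj] = adj[ci].get(cj, 0) + w
                adj[cj][ci] = adj[cj].get(ci, 0) + w
    return AggregatedGraph(sizes, internal, adj, agg.n_total, agg.m_total)


def _local_phase(
    state: PartitionState, rng: np.random.Generator, max_sweeps: int
) -> bool:
    """Greedy single-node sweeps in seeded shuffled order; True if any move."""
    k = len(state.comm)
    moved_any = False
    for _ in range(max_sweeps):
        order = rng.permutation(k)
        moved = False
        for i in order:
            target, delta = state.best_move(int(i))
            if target is not None and delta > 0.0:
                state.apply_move(int(i), target)
                moved = True
        moved_any = moved_any or moved
        if not moved:
            break
    return moved_any


def _split_pass(
    fine: AggregatedGraph,
    membership: list[int],
    config: ResolutionConfig,
    rng: np.random.Generator,
    max_sweeps: int,
) -> tuple[list[int], bool]:
    """Try to split each community by re-optimizing its induced sub-state.

    Greedy growth can fuse two well-separated blocks into one community that
    no single-node move can take apart; re-running the local phase inside the
    community (global density held fixed, external degree mass carried as an
    offset for Modularity) detects and applies profitable splits.
    """
    comms: dict[int, list[int]] = {}
    for i, c in enumerate(membership):
        comms.setdefault(c, []).append(i)
    changed = False
    next_label = max(membership) + 1
    out = list(membership)
    for c, members in comms.items():
        if len(members) < 2:
            continue
        local = {g_idx: l_idx for l_idx, g_idx in enumerate(members)}
        sub_adj: list[dict[int, int]] = [dict() for _ in members]
        offsets = [0] * len(members)
        for g_idx in members:
            l_idx = local[g_idx]
            for j, w in fine.adj[g_idx].items():
                if j in local:
                    sub_adj[l_idx][local[j]] = w
                else:
                    offsets[l_idx] += w
        state = PartitionState(
            [fine.sizes[i] for i in members],
            [fine.internal[i] for i in members],
            sub_adj,
            fine.n_total,
            fine.m_total,
            config,
            deg_offset=offsets,
        )
        whole = PartitionState(
            [fine.sizes[i] for i in members],
            [fine.internal[i] for i in members],
            sub_adj,
            fine.n_total,
            fine.m_total,
            config,
            membership=[0] * len(members),
            deg_offset=offsets,
        )
        _local_phase(state, rng, max_sweeps)
        if state.score() > whole.score() + 1e-10:
            sub = state.membership()
            if len(set(sub)) > 1:
                for g_idx in members:
                    out[g_idx] = next_label + sub[local[g_idx]]
                next_label += max(sub) + 1
                changed = True
    return out, changed


def optimize(graph: nx.Graph, settings: OptimizerSettings) -> dict:
    """Greedy multi-level maximization; returns a node -> community-id dict.

    Each level alternates supernode moves on the aggregated graph with a
    single-node refinement pass on the original graph, so misassignments are
    corrected before aggregation freezes them; after convergence a split pass
    re-optimizes each community's interior and the cycle repeats while any
    profitable split is found.  Starts from all singletons, hence the
    returned partition never scores below the singleton partition, and at
    convergence no single-node move at the finest level can improve the
    score.  Deterministic given ``settings.seed``.
    """
    if graph.number_of_nodes() == 0:
        raise ValueError("cannot optimize an empty graph")
    rng = np.random.default_rng(settings.seed)
    fine, nodes = AggregatedGraph.from_graph(graph)
    membership = list(range(len(nodes)))
    while True:
        membership = _multilevel(fine, membership, settings, rng)
        membership, split_changed = _split_pass(
            fine, membership, settings.config, rng, settings.max_sweeps_per_level
        )
        if not split_changed:
            break
    return {v: membership[i] for i, v in enumerate(nodes)}


def _multilevel(
    fine: AggregatedGraph,
    membership: list[int],
    settings: OptimizerSettings,
    rng: np.random.Generator,
) -> list[int]:
    level = 0
    while True:
        agg = aggregate(fine, membership)
        state = PartitionState(
            agg.sizes, agg.internal, agg.adj, agg.n_total, agg.m_total, settings.config
        )
        coarse_moved = _local_phase(state, rng, settings.max_sweeps_per_level)
        coarse = state.membership()
        # relabel supernode ids: membership values are community ids of the
        # previous round in first-appearance order, matching aggregate()
        relabel: dict[int, int] = {}
        for c in membership:
            if c not in relabel:
                relabel[c] = len(relabel)
        membership = [coarse[relabel[c]] for c in membership]
        # single-node refinement at the finest level
        fstate = PartitionState(
            fine.sizes,
            fine.internal,
            fine.adj,
            fine.n_total,
            fine.m_total,
            settings.config,
            membership=membership,
        )
        fine_moved = _local_phase(fstate, rng, settings.max_sweeps_per_level)
        membership = fstate.membership()
        level += 1
        if not (coarse_moved or fine_moved):
            break
        if settings.max_levels is not None and level >= settings.max_levels:
            break
    return membership


def _set_partitions(n: int):
    """Yield all restricted-growth strings (set partitions) of range(n)."""
    labels = [0] * n
    maxima = [0] * n  # maxima[i] = max(labels[:i])
    while True:
        yield labels
        # advance to next RGS
        i = n - 1
        while i > 0 and labels[i] == maxima[i] + 1:
            i -= 1
        if i == 0:
            return
        labels[i] += 1
        m = max(maxima[i], labels[i])
        for j in range(i + 1, n):
            labels[j] = 0
            maxima[j] = m


def exhaustive_optimum(
    graph: nx.Graph, config: ResolutionConfig
) -> tuple[dict, float]:
    """True global maximizer by enumeration of all set partitions (n <= 12)."""
    nodes = list(graph.nodes)
    n = len(nodes)
    if n > 12:
        raise ValueError(f"exhaustive search refused for n = {n} > 12")
    index = {v: i for i, v in enumerate(nodes)}
    edges = [(index[u], index[v]) for u, v in graph.edges if u != v]
    m = len(edges)
    if m == 0:
        raise ValueError("graph has no edges")
    p = m / (n * (n - 1) / 2.0)
    ptilde = _null_density(p, config.gamma)
    degs = [0] * n
    for u, v in edges:
        degs[u] += 1
        degs[v] += 1
    modular = config.measure == "modularity"
    gamma = config.gamma
    two_m = 2.0 * m

    best_score = float("-inf")
    best_labels: list[int] | None = None
    sizes = [0] * n
    ms = [0] * n
    ds = [0] * n
    for labels in _set_partitions(n):
        k = max(labels) + 1
        for c in range(k):
            sizes[c] = 0
            ms[c] = 0
            ds[c] = 0
        for i in range(n):
            c = labels[i]
            sizes[c] += 1
            ds[c] += degs[i]
        for u, v in edges:
            if labels[u] == labels[v]:
                ms[labels[u]] += 1
        if modular:
            score = sum(
                ms[c] / m - gamma * (ds[c] / two_m) ** 2 for c in range(k)
            )
        else:
            score = sum(_sig_term(sizes[c], ms[c], ptilde) for c in range(k))
        if score > best_score + 1e-12:
            best_score = score
            best_labels = labels.copy()
    assert best_labels is not None
    return {nodes[i]: best_labels[i] for i in range(n)}, best_score
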