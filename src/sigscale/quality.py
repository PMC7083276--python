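"""Partition quality measures: Significance and Modularity, single- and multi-resolution.

Significance scores a partition of an undirected simple graph by summing, over
communities, the number of vertex pairs times the binary Kullback-Leibler
divergence between the community's internal link density ``p_s`` and the global
link density ``p``::

    S = sum_s  C(n_s, 2) * D(p_s || p),
    D(q || p0) = q ln(q/p0) + (1-q) ln((1-q)/(1-p0)).

The multi-resolution variant rescales the reference density to ``p~ = gamma*p``;
``gamma = 1`` recovers the plain measure and larger ``gamma`` favours finer
communities.  Modularity is the classic within-community edge fraction minus
its degree-preserving null expectation; its multi-resolution form rescales the
null term: ``Q(gamma) = sum_s [ m_s/m - gamma*(d_s/2m)^2 ]``.

The module also provides :class:`PartitionState`, an incremental bookkeeping
structure whose single-(super)node move deltas agree with full recomputation to
float tolerance; it is the engine behind the multi-level greedy optimizer.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Hashable, Mapping

import networkx as nx

log = logging.getLogger(__name__)

__all__ = [
    "ResolutionError",
    "ResolutionConfig",
    "CommunityStats",
    "GlobalDensity",
    "bernoulli_kl",
    "binary_entropy",
    "community_stats",
    "significance",
    "modularity",
    "PartitionState",
]

_DELTA_TOL = 1e-12


class ResolutionError(ValueError):
    """Raised when ``gamma * p`` leaves the valid range of the rescaled null density."""

def bernoulli_kl(q: float, p0: float) -> float:
    """Binary KL divergence D(q || p0) in nats, with the 0*ln(0) = 0 convention.

    Parameters
    ----------
    q : float in [0, 1]
        Observed Bernoulli probability (e.g. a community's internal density).
    p0 : float in (0, 1)
        Reference probability (e.g. the rescaled global density).
    """
    if not 0.0 <= q <= 1.0:
        raise ValueError(f"q must lie in [0, 1], got {q}")
    if not 0.0 < p0 < 1.0:
        raise ValueError(f"p0 must lie in (0, 1), got {p0}")
    out = 0.0
    if q > 0.0:
        out += q * math.log(q / p0)
    if q < 1.0:
        out += (1.0 - q) * math.log((1.0 - q) / (1.0 - p0))
    # guard against tiny negative round-off; D is non-negative
    return out if out > 0.0 else 0.0


def binary_entropy(y: float) -> float:
    """Binary (information) entropy H(y) = -y ln y - (1-y) ln(1-y) in nats."""
    if not 0.0 <= y <= 1.0:
        raise ValueError(f"y must lie in [0, 1], got {y}")
    out = 0.0
    if y > 0.0:
        out -= y * math.log(y)
    if y < 1.0:
        out -= (1.0 - y) * math.log(1.0 - y)
    return out if out > 0.0 else 0.0


@dataclass(frozen=True)
class CommunityStats:
    """Per-community statistics of a partition.

    ``p_s`` is the internal link density m_s / C(n_s, 2); a singleton community
    has zero pair weight and ``p_s = 0`` by convention.  ``d_s`` (sum of member
    degrees) is used only by Modularity.
    """

    community_id: Hashable
    n_s: int
    m_s: int
    p_s: float
    d_s: int


@dataclass(frozen=True)
class GlobalDensity:
    """Whole-graph vertex/edge counts and link density p = m / C(n, 2)."""

    n: int
    m: int
    p: float


@dataclass(frozen=True)
class ResolutionConfig:
    """Which measure to score and at which resolution.

    ``gamma`` rescales the null density (Significance) or the null term
    (Modularity); for Significance ``gamma * p < 1`` must hold on the graph
    being scored.
    """

    gamma: float = 1.0
    measure: str = "significance"

    def __post_init__(self) -> None:
        if self.gamma <= 0:
            raise ValueError(f"gamma must be positive, got {self.gamma}")
        if self.measure not in ("significance", "modularity"):
            raise ValueError(f"unknown measure {self.measure!r}")


def _check_partition(graph: nx.Graph, partition: Mapping) -> None:
    for node in graph.nodes:
        if node not in partition:
            raise ValueError(f"node {node!r} missing from partition")


def community_stats(
    graph: nx.Graph, partition: Mapping
) -> tuple[list[CommunityStats], GlobalDensity]:
    """Per-community (n_s, m_s, p_s, d_s) plus the global density record.

    Every node of ``graph`` must appear in ``partition``; self-loops are
    ignored with a warning.  Edges between communities count toward the global
    edge total only.
    """
    _check_partition(graph, partition)
    n = graph.number_of_nodes()
    loops = nx.number_of_selfloops(graph)
    if loops:
        log.warning("ignoring %d self-loop(s)", loops)
    m = graph.number_of_edges() - loops

    sizes: dict[Hashable, int] = {}
    internal: dict[Hashable, int] = {}
    degsum: dict[Hashable, int] = {}
    for node in graph.nodes:
        c = partition[node]
        sizes[c] = sizes.get(c, 0) + 1
        internal.setdefault(c, 0)
        deg = graph.degree(node) - (2 if graph.has_edge(node, node) else 0)
        degsum[c] = degsum.get(c, 0) + deg
    for u, v in graph.edges:
        if u == v:
            continue
        cu, cv = partition[u], partition[v]
        if cu == cv:
            internal[cu] += 1

    stats = []
    for c in sizes:
        n_s, m_s = sizes[c], internal[c]
        pairs = n_s * (n_s - 1) / 2
        p_s = m_s / pairs if pairs else 0.0
        stats.append(CommunityStats(c, n_s, m_s, p_s, degsum[c]))
    p = m / (n * (n - 1) / 2) if n >= 2 else 0.0
    return stats, GlobalDensity(n, m, p)


def _null_density(p: float, gamma: float) -> float:
    """Validate and return the rescaled null density p~ = gamma*p.

    The degenerate complete-graph case (p = 1, gamma = 1) is passed through and
    handled by the term evaluators (every induced density is then also 1 and
    each KL term vanishes in the limit).
    """
    ptilde = gamma * p
    if p == 1.0:
        # complete graph: every induced density is also 1 and each KL term
        # vanishes in the limit, but only at the unrescaled resolution
        if gamma == 1.0:
            return 1.0
        raise ResolutionError(
            f"complete graph (p = 1) is only scored at gamma = 1, got {gamma}"
        )
    if ptilde >= 1.0:
        raise ResolutionError(
            f"gamma*p = {ptilde:.6g} >= 1: resolution gamma={gamma} out of range "
            f"for a graph with density p={p:.6g}"
        )
    return ptilde


def _sig_term(n_s: float, m_s: float, ptilde: float) -> float:
    if n_s < 2:
        return 0.0
    pairs = n_s * (n_s - 1) / 2.0
    q = m_s / pairs
    if ptilde == 1.0:
        # complete-graph limit: D(1 || 1) -> 0
        return 0.0
    out = 0.0
    if q > 0.0:
        out += q * math.log(q / ptilde)
    if q < 1.0:
        out += (1.0 - q) * math.log((1.0 - q) / (1.0 - ptilde))
    return pairs * (out if out > 0.0 else 0.0)


def significance(graph: nx.Graph, partition: Mapping, gamma: float = 1.0) -> float:
    """Multi-resolution Significance S(gamma) of a partition, in nats.

    S(gamma) = sum_s C(n_s,2) * D(p_s || gamma*p).  Non-negative; invariant
    under community relabeling; singleton communities contribute zero.
    """
    stats, dens = community_stats(graph, partition)
    if dens.m == 0:
        raise ValueError("significance is undefined on a graph with no edges")
    ptilde = _null_density(dens.p, gamma)
    return sum(_sig_term(s.n_s, s.m_s, ptilde) for s in stats)


def modularity(graph: nx.Graph, partition: Mapping, gamma: float = 1.0) -> float:
    """Multi-resolution Modularity Q(gamma) = sum_s [m_s/m - gamma*(d_s/2m)^2]."""
    stats, dens = community_stats(graph, partition)
    if dens.m == 0:
        raise ValueError("modularity is undefined on a graph with no edges")
    m = dens.m
    return sum(s.m_s / m - gamma * (s.d_s / (2.0 * m)) ** 2 for s in stats)


class PartitionState:
    """Incremental partition state supporting O(deg) single-node move deltas.

    Nodes may be weighted supernodes carrying ``size`` original vertices and
    ``internal`` original edges, so the same engine scores both a plain graph
    and the aggregated graphs of a multi-level optimizer.  The global density
    of the *original* graph is held fixed throughout (Significance depends on
    original vertex counts and densities, not on the coarse graph alone).
    """

    def __init__(
        self,
        sizes: list[int],
        internal: list[int],
        adjacency: list[dict[int, int]],
        n_total: int,
        m_total: int,
        config: ResolutionConfig,
        membership: list[int] | None = None,
        deg_offset: list[int] | None = None,
    ) -> None:
        k = len(sizes)
        if not (len(internal) == len(adjacency) == k):
            raise ValueError("sizes, internal and adjacency must have equal length")
        if m_total <= 0:
            raise ValueError("the underlying graph must have at least one edge")
        self.sizes = list(sizes)
        self.internal = list(internal)
        self.adj = adjacency
        # deg_offset carries degree mass toward nodes outside this state (used
        # when scoring an induced sub-state under Modularity)
        self.deg = [
            2 * internal[i]
            + sum(adjacency[i].values())
            + (deg_offset[i] if deg_offset else 0)
            for i in range(k)
        ]
        self.n_total = n_total
        self.m_total = m_total
        self.p = m_total / (n_total * (n_total - 1) / 2.0)
        self.config = config
        self.ptilde = _null_density(self.p, config.gamma)
        self._modular = config.measure == "modularity"
        self.comm = list(range(k)) if membership is None else list(membership)
        if len(self.comm) != k:
            raise ValueError("membership length mismatch")
        # per-community aggregates
        self.c_n: dict[int, int] = {}
        self.c_m: dict[int, float] = {}
        self.c_d: dict[int, float] = {}
        for i in range(k):
            c = self.comm[i]
            self.c_n[c] = self.c_n.get(c, 0) + self.sizes[i]
            self.c_m[c] = self.c_m.get(c, 0) + self.internal[i]
            self.c_d[c] = self.c_d.get(c, 0) + self.deg[i]
        for i in range(k):
            ci = self.comm[i]
            for j, w in self.adj[i].items():
                if j > i and self.comm[j] == ci:
                    self.c_m[ci] += w
        self._next_label = k

    # -- construction -------------------------------------------------------

    @classmethod
    def from_graph(
        cls, graph: nx.Graph, partition: Mapping, config: ResolutionConfig
    ) -> "PartitionState":
        """Build a state over the original (unit-weight) vertices of ``graph``."""
        _check_partition(graph, partition)
        nodes = list(graph.nodes)
        index = {v: i for i, v in enumerate(nodes)}
        k = len(nodes)
        adjacency: list[dict[int, int]] = [dict() for _ in range(k)]
        m = 0
        for u, v in graph.edges:
            if u == v:
                continue
            iu, iv = index[u], index[v]
            adjacency[iu][iv] = adjacency[iu].get(iv, 0) + 1
            adjacency[iv][iu] = adjacency[iv].get(iu, 0) + 1
            m += 1
        labels = {}
        membership = []
        for v in nodes:
            c = partition[v]
            if c not in labels:
                labels[c] = len(labels)
            membership.append(labels[c])
        state = cls([1] * k, [0] * k, adjacency, k, m, config, membership)
        state.node_labels = nodes
        return state

    # -- scoring ------------------------------------------------------------

    def _term(self, n_s: float, m_s: float, d_s: float) -> float:
        if self._modular:
            return m_s / self.m_total - self.config.gamma * (d_s / (2.0 * self.m_total)) ** 2
        return _sig_term(n_s, m_s, self.ptilde)

    def score(self) -> float:
        """Current total score under the configured measure."""
        return sum(
            self._term(self.c_n[c], self.c_m[c], self.c_d[c]) for c in self.c_n
        )

    # -- moves --------------------------------------------------------------

    def _neighbor_weights(self, i: int) -> dict[int, float]:
        w: dict[int, float] = {}
        comm = self.comm
        for j, wt in self.adj[i].items():
            cj = comm[j]
            w[cj] = w.get(cj, 0) + wt
        return w

    def _delta(self, i: int, a: int, c: int, e_ia: float, e_ic: float) -> float:
        z, b, k = self.sizes[i], self.internal[i], self.deg[i]
        n_a, m_a, d_a = self.c_n[a], self.c_m[a], self.c_d[a]
        n_c = self.c_n.get(c, 0)
        m_c = self.c_m.get(c, 0)
        d_c = self.c_d.get(c, 0)
        before = self._term(n_a, m_a, d_a) + self._term(n_c, m_c, d_c)
        after = self._term(n_a - z, m_a - b - e_ia, d_a - k) + self._term(
            n_c + z, m_c + b + e_ic, d_c + k
        )
        return after - before

    def move_delta(self, i: int, target: int) -> float:
        """Score change of moving node ``i`` to community ``target``.

        ``target`` may be an existing community or a fresh (empty) label.
        Equals ``score(after) - score(before)`` to float tolerance.
        """
        if not 0 <= i < len(self.comm):
            raise ValueError(f"unknown node index {i}")
        a = self.comm[i]
        if target == a:
            return 0.0
        if target not in self.c_n and target != self._next_label:
            raise ValueError(f"unknown community {target!r}")
        w = self._neighbor_weights(i)
        return self._delta(i, a, target, w.get(a, 0), w.get(target, 0))

    def best_move(self, i: int) -> tuple[int | None, float]:
        """Best strictly-improving target for node ``i`` (or ``(None, 0.0)``).

        Candidates are the communities of neighbors plus a fresh empty
        community (isolation); among positive deltas the largest wins, first
        encountered on ties.
        """
        a = self.comm[i]
        w = self._neighbor_weights(i)
        e_ia = w.get(a, 0)
        best_c: int | None = None
        best_delta = 0.0
        for c, e_ic in w.items():
            if c == a:
                continue
            d = self._delta(i, a, c, e_ia, e_ic)
            if d > best_delta + _DELTA_TOL:
                best_c, best_delta = c, d
        if self.c_n[a] > self.sizes[i]:  # isolation is distinct from staying
            d = self._delta(i, a, self._next_label, e_ia, 0)
            if d > best_delta + _DELTA_TOL:
                best_c, best_delta = self._next_label, d
        return best_c, best_delta

    def apply_move(self, i: int, target: int) -> None:
        a = self.comm[i]
        if target == a:
            return
        w = self._neighbor_weights(i)
        z, b, k = self.sizes[i], self.internal[i], self.deg[i]
        self.c_n[a] -= z
        self.c_m[a] -= b + w.get(a, 0)
        self.c_d[a] -= k
        if self.c_n[a] == 0:
            del self.c_n[a], self.c_m[a], self.c_d[a]
        self.c_n[target] = self.c_n.get(target, 0) + z
        self.c_m[target] = self.c_m.get(target, 0) + b + w.get(target, 0)
        self.c_d[target] = self.c_d.get(target, 0) + k
        self.comm[i] = target
        if target == self._next_label:
            self._next_label += 1

    def membership(self) -> list[int]:
        """Community labels renumbered 0..Nd-1 by first appearance."""
        relabel: dict[int, int] = {}
        out = []
        for c in self.comm:
            if c not in relabel:
                relabel[c] = len(relabel)
            out.append(relabel[c])
        return out
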