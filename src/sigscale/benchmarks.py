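"""Seeded generators for the benchmark network families with ground truths.

Families
--------
- community loop: r equal Bernoulli communities on a ring (the analytic
  testbed of the critical-point theory);
- FB four-block networks: two large and two small blocks on a ring joined by
  single edges (the classic first/second-type resolution-limit fixture);
- homogeneous hierarchical: 256 vertices, 16 groups of 16 nested in 4 groups
  of 64, expected per-vertex link counts k_in0 / k_in1 / 1 at the three scopes;
- heterogeneous hierarchical: 1000 vertices, power-law degrees (mean 20, max
  50), micro communities of 10-25 nested in macro communities of 50-100, with
  mixing fractions mu1 (cross-macro) and mu2 (same-macro cross-micro);
- RB-LFR: an LFR seed graph replicated into a multi-level hierarchy with
  seed-replica connector edges, optionally thinned per level.

Every generator returns string-labelled :class:`networkx.Graph` objects plus
ground-truth partitions (node -> community id dicts) for every defined level,
and is deterministic for a given integer seed.
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .critical import LoopParams

__all__ = [
    "HierarchySpec",
    "HeteroParams",
    "RBLFRParams",
    "community_loop_graph",
    "fb_graph",
    "homogeneous_hierarchical_graph",
    "heterogeneous_hierarchical_graph",
    "rb_lfr_graph",
]


@dataclass
class HierarchySpec:
    """Ordered ground-truth partitions, finest to coarsest, with labels.

    ``named`` carries additional named ground truths (e.g. the RB-LFR
    "S-R*2" / "R*2-S" / "Flat" assemblies).
    """

    levels: list[dict]
    labels: list[str]
    named: dict[str, dict] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.levels) != len(self.labels):
            raise ValueError("one label per level required")


def _bernoulli_pairs(rng: np.random.Generator, pairs: list, prob: float):
    if prob <= 0.0 or not pairs:
        return []
    keep = rng.random(len(pairs)) < prob
    return [pairs[i] for i in np.flatnonzero(keep)]


def community_loop_graph(
    params: LoopParams, seed: int | None = None
) -> tuple[nx.Graph, dict]:
    """Sample a community-loop network and its planted r-block partition.

    Intra-community pairs link independently with probability ``p_i``; pairs
    spanning ring-adjacent communities with probability ``p_o``; non-adjacent
    communities are never linked.
    """
    rng = np.random.default_rng(seed)
    r, n_c = params.r, params.n_c
    nodes = [f"v{i}" for i in range(r * n_c)]
    block = lambda s: nodes[s * n_c : (s + 1) * n_c]
    graph = nx.Graph()
    graph.add_nodes_from(nodes)
    for s in range(r):
        members = block(s)
        graph.add_edges_from(
            _bernoulli_pairs(rng, list(itertools.combinations(members, 2)), params.p_i)
        )
        nxt = block((s + 1) % r)
        graph.add_edges_from(
            _bernoulli_pairs(
                rng, [(u, v) for u in members for v in nxt], params.p_o
            )
        )
    partition = {v: i // n_c for i, v in enumerate(nodes)}
    return graph, partition


def fb_graph(
    n1: int,
    n2: int,
    block_type: str = "clique",
    p_block: float | None = None,
    seed: int | None = None,
) -> tuple[nx.Graph, dict]:
    """Four-block ring [large, large, small, small] joined by single edges.

    Blocks are cliques by default (the classic resolution-limit fixture) or
    Bernoulli blocks with density ``p_block``.  The two small blocks are
    adjacent on the ring; consecutive blocks share exactly one edge, so the
    clique variant with (n1, n2) = (20, 5) has 2*C(20,2)+2*C(5,2)+4 = 404
    edges.  Ground truth is the four blocks.
    """
    if not n1 >= n2 >= 3:
        raise ValueError("need n1 >= n2 >= 3")
    if block_type not in ("clique", "bernoulli"):
        raise ValueError(f"unknown block_type {block_type!r}")
    rng = np.random.default_rng(seed)
    sizes = [n1, n1, n2, n2]
    offsets = np.concatenate([[0], np.cumsum(sizes)])
    nodes = [f"v{i}" for i in range(int(offsets[-1]))]
    graph = nx.Graph()
    graph.add_nodes_from(nodes)
    partition = {}
    for b, size in enumerate(sizes):
        members = nodes[offsets[b] : offsets[b + 1]]
        for v in members:
            partition[v] = b
        pairs = list(itertools.combinations(members, 2))
        if block_type == "clique":
            graph.add_edges_from(pairs)
        else:
            if p_block is None:
                raise ValueError("bernoulli blocks need p_block")
            graph.add_edges_from(_bernoulli_pairs(rng, pairs, p_block))
    for b in range(4):
        u = nodes[offsets[b]]  # first node of block b
        v = nodes[offsets[(b + 1) % 4] + 1]  # second node of the next block
        graph.add_edge(u, v)
    return graph, partition


def homogeneous_hierarchical_graph(
    k_in0: float = 13.0, k_in1: float = 4.0, seed: int | None = None
) -> tuple[nx.Graph, HierarchySpec]:
    """256-vertex two-level benchmark: 16 groups of 16 nested in 4 groups of 64.

    Realized as Bernoulli links with pair probabilities matching the expected
    per-vertex link counts: ``k_in0/15`` within the own 16-vertex L1 group,
    ``k_in1/48`` within the own L2 group outside the L1 group, and ``1/192``
    toward the 192 vertices outside the L2 group (one random external link per
    vertex in expectation).
    """
    if not 0 <= k_in0 <= 15:
        raise ValueError("k_in0 must fit a 16-vertex group (0 <= k_in0 <= 15)")
    if not 0 <= k_in1 <= 48:
        raise ValueError("k_in1 must fit the 48 same-L2 outside-L1 vertices")
    rng = np.random.default_rng(seed)
    n = 256
    idx = np.arange(n)
    g1 = idx // 16  # L1 group of each vertex
    g2 = idx // 64  # L2 group
    iu, iv = np.triu_indices(n, k=1)
    same1 = g1[iu] == g1[iv]
    same2 = g2[iu] == g2[iv]
    prob = np.where(same1, k_in0 / 15.0, np.where(same2, k_in1 / 48.0, 1.0 / 192.0))
    keep = rng.random(len(iu)) < prob
    nodes = [f"v{i}" for i in range(n)]
    graph = nx.Graph()
    graph.add_nodes_from(nodes)
    graph.add_edges_from(
        (nodes[int(u)], nodes[int(v)]) for u, v in zip(iu[keep], iv[keep])
    )
    l1 = {nodes[i]: int(g1[i]) for i in range(n)}
    l2 = {nodes[i]: int(g2[i]) for i in range(n)}
    return graph, HierarchySpec([l1, l2], ["L1", "L2"])


@dataclass(frozen=True)
class HeteroParams:
    """Heterogeneous two-level benchmark parameters.

    Degrees follow a truncated power law with exponent ``tau_degree`` whose
    lower cutoff is solved so the expected mean degree equals ``avg_degree``;
    community sizes follow a power law with exponent ``tau_size`` within the
    stated ranges.  ``mu1``/``mu2`` are each vertex's expected edge fractions
    toward different-macro and same-macro-different-micro vertices.
    """

    n: int = 1000
    avg_degree: float = 20.0
    max_degree: int = 50
    micro_size_range: tuple[int, int] = (10, 25)
    macro_size_range: tuple[int, int] = (50, 100)
    mu1: float = 0.2
    mu2: float = 0.3
    tau_degree: float = 2.0
    tau_size: float = 1.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.mu1 <= 1.0 and 0.0 <= self.mu2 <= 1.0):
            raise ValueError("mu1 and mu2 must lie in [0, 1]")
        if self.mu1 + self.mu2 > 1.0:
            raise ValueError("mu1 + mu2 must not exceed 1")
        lo, hi = self.micro_size_range
        Lo, Hi = self.macro_size_range
        if not (lo <= hi and Lo <= Hi and hi <= Hi):
            raise ValueError("micro size range must nest inside macro size range")


def _sample_sizes(
    total: int, lo: int, hi: int, tau: float, rng: np.random.Generator, tries: int = 2000
) -> list[int]:
    """Power-law sizes in [lo, hi] summing exactly to ``total`` (retry draws)."""
    support = np.arange(lo, hi + 1)
    weights = support.astype(float) ** (-tau)
    weights /= weights.sum()
    for _ in range(tries):
        sizes: list[int] = []
        acc = 0
        while acc < total:
            s = int(rng.choice(support, p=weights))
            if acc + s >= total:
                last = total - acc
                if lo <= last <= hi:
                    sizes.append(last)
                    acc = total
                else:
                    break  # infeasible tail; redraw the whole sequence
            else:
                sizes.append(s)
                acc += s
        if acc == total:
            return sizes
    raise ValueError(f"could not pack sizes in [{lo}, {hi}] summing to {total}")


def _degree_distribution(avg: float, tau: float, kmax: int):
    """Truncated power-law degree weights with mean exactly ``avg``.

    Finds the integer lower cutoff and a fractional weight on it so that the
    distribution's mean equals ``avg``.
    """
    from scipy.optimize import brentq

    def mean_from(klo: int, theta: float) -> float:
        ks = np.arange(klo, kmax + 1, dtype=float)
        w = ks ** (-tau)
        w[0] *= theta
        return float((ks * w).sum() / w.sum())

    klo = None
    for k in range(1, kmax):
        if mean_from(k, 1.0) <= avg < mean_from(k + 1, 1.0):
            klo = k
            break
    if klo is None:
        raise ValueError(f"mean degree {avg} unreachable with tau={tau}, kmax={kmax}")
    theta = brentq(lambda t: mean_from(klo, t) - avg, 1e-9, 1.0)
    ks = np.arange(klo, kmax + 1)
    w = ks.astype(float) ** (-tau)
    w[0] *= theta
    return ks, w / w.sum()


def _stochastic_round(x: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    lo = np.floor(x)
    return (lo + (rng.random(x.shape) < (x - lo))).astype(int)


def _match_stubs(
    stubs: list[int],
    group: np.ndarray,
    existing: set,
    rng: np.random.Generator,
    passes: int = 30,
) -> list[tuple[int, int]]:
    """Random stub matching forbidding self edges, multi-edges, and same-group
    pairs; unplaceable stubs are dropped after ``passes`` reshuffles."""
    edges: list[tuple[int, int]] = []
    pool = list(stubs)
    for _ in range(passes):
        if len(pool) < 2:
            break
        rng.shuffle(pool)
        leftover: list[int] = []
        for a, b in zip(pool[::2], pool[1::2]):
            if a == b or group[a] == group[b]:
                leftover.extend((a, b))
                continue
            key = (a, b) if a < b else (b, a)
            if key in existing:
                leftover.extend((a, b))
                continue
            existing.add(key)
            edges.append(key)
        if len(pool) % 2:
            leftover.append(pool[-1])
        if len(leftover) == len(pool):
            break
        pool = leftover
    return edges


def _havel_hakimi_random(
    members: np.ndarray, degs: np.ndarray, existing: set, rng: np.random.Generator
) -> list[tuple[int, int]]:
    """Randomized Havel-Hakimi realization of a degree sequence on ``members``.

    Residual stubs that cannot be placed are silently dropped (the sequence
    may be non-graphical after capping).
    """
    order = rng.permutation(len(members))
    residual = {int(members[i]): int(degs[i]) for i in order if degs[i] > 0}
    edges: list[tuple[int, int]] = []
    while len(residual) > 1:
        u = max(residual, key=residual.get)
        du = residual.pop(u)
        targets = sorted(residual, key=lambda v: (-residual[v], rng.random()))[:du]
        for v in targets:
            key = (u, v) if u < v else (v, u)
            if key in existing:
                continue
            existing.add(key)
            edges.append(key)
            residual[v] -= 1
            if residual[v] == 0:
                del residual[v]
    return edges


def heterogeneous_hierarchical_graph(
    params: HeteroParams = HeteroParams(), seed: int | None = None
) -> tuple[nx.Graph, HierarchySpec]:
    """Two nested levels of heterogeneous communities with power-law degrees.

    Each vertex's sampled degree is split into cross-macro (fraction mu1),
    same-macro-cross-micro (mu2) and within-micro stubs; within-micro stubs
    are realized by a randomized degree-faithful construction and the sparser
    scopes by random stub matching.  Stubs exceeding a scope's capacity are
    promoted one scope outward (unless that scope's fraction is zero, in which
    case they are dropped, so ``mu1 = 0`` keeps macro blocks disconnected).
    """
    rng = np.random.default_rng(seed)
    macro_sizes = _sample_sizes(
        params.n, *params.macro_size_range, params.tau_size, rng
    )
    micro_of = np.empty(params.n, dtype=int)
    macro_of = np.empty(params.n, dtype=int)
    micro_id = 0
    pos = 0
    micro_members: list[np.ndarray] = []
    macro_members: list[np.ndarray] = []
    for mac, msize in enumerate(macro_sizes):
        macro_members.append(np.arange(pos, pos + msize))
        for s in _sample_sizes(msize, *params.micro_size_range, params.tau_size, rng):
            micro_members.append(np.arange(pos, pos + s))
            micro_of[pos : pos + s] = micro_id
            macro_of[pos : pos + s] = mac
            micro_id += 1
            pos += s

    ks, w = _degree_distribution(params.avg_degree, params.tau_degree, params.max_degree)
    degree = rng.choice(ks, size=params.n, p=w)
    k_global = _stochastic_round(degree * params.mu1, rng)
    k_macro = _stochastic_round(degree * params.mu2, rng)
    k_micro = degree - k_global - k_macro
    k_micro = np.maximum(k_micro, 0)

    # capacity caps: promote excess stubs outward
    micro_cap = np.array([len(micro_members[micro_of[i]]) - 1 for i in range(params.n)])
    excess = np.maximum(k_micro - micro_cap, 0)
    k_micro -= excess
    if params.mu2 > 0.0 or params.mu1 > 0.0:
        k_macro += excess
    macro_cap = np.array(
        [
            len(macro_members[macro_of[i]]) - len(micro_members[micro_of[i]])
            for i in range(params.n)
        ]
    )
    excess = np.maximum(k_macro - macro_cap, 0)
    k_macro -= excess
    if params.mu1 > 0.0:
        k_global += excess

    existing: set = set()
    edges: list[tuple[int, int]] = []
    for members in micro_members:
        degs = k_micro[members].copy()
        if degs.sum() % 2:
            degs[int(np.argmax(degs))] -= 1
        edges.extend(_havel_hakimi_random(members, degs, existing, rng))
    for mac, members in enumerate(macro_members):
        stubs = [int(i) for i in members for _ in range(k_macro[i])]
        edges.extend(_match_stubs(stubs, micro_of, existing, rng))
    stubs = [i for i in range(params.n) for _ in range(k_global[i])]
    edges.extend(_match_stubs(stubs, macro_of, existing, rng))

    nodes = [f"v{i}" for i in range(params.n)]
    graph = nx.Graph()
    graph.add_nodes_from(nodes)
    graph.add_edges_from((nodes[u], nodes[v]) for u, v in edges)
    micro = {nodes[i]: int(micro_of[i]) for i in range(params.n)}
    macro = {nodes[i]: int(macro_of[i]) for i in range(params.n)}
    return graph, HierarchySpec([micro, macro], ["L1", "L2"])


@dataclass(frozen=True)
class RBLFRParams:
    """RB-LFR hierarchy parameters.

    An LFR seed graph of ``seed_n`` vertices is replicated ``replicas`` times
    per level over ``levels`` construction stages (default 3 levels = two
    replication stages, hence ``seed_n * (1 + replicas)**2`` vertices).  Each
    replica vertex gains one candidate connector edge to a uniformly random
    vertex of its stage's seed copy; connectors are removed independently with
    probability ``p_remove_l2`` (first stage) / ``p_remove_l3`` (second stage)
    in the extended variant.
    """

    seed_n: int = 128
    tau1: float = 2.5
    tau2: float = 1.5
    mu: float = 0.1
    avg_degree: float = 8.0
    max_degree: int = 24
    min_community: int = 12
    max_community: int = 48
    replicas: int = 2
    levels: int = 3
    p_remove_l2: float = 0.0
    p_remove_l3: float = 0.0

    def __post_init__(self) -> None:
        if self.levels != 3:
            raise ValueError("only the three-level construction is implemented")
        if self.replicas < 1:
            raise ValueError("need at least one replica per level")
        if not (0.0 <= self.p_remove_l2 <= 1.0 and 0.0 <= self.p_remove_l3 <= 1.0):
            raise ValueError("removal probabilities must lie in [0, 1]")


def _lfr_seed_graph(params: RBLFRParams, seed: int) -> tuple[nx.Graph, dict]:
    last_err: Exception | None = None
    for attempt in range(10):
        try:
            g = nx.LFR_benchmark_graph(
                params.seed_n,
                params.tau1,
                params.tau2,
                params.mu,
                average_degree=params.avg_degree,
                max_degree=params.max_degree,
                min_community=params.min_community,
                max_community=params.max_community,
                seed=(seed + 7919 * attempt) % 2**31,
            )
        except nx.ExceededMaxIterations as err:  # pragma: no cover - rare
            last_err = err
            continue
        g.remove_edges_from(nx.selfloop_edges(g))
        comms = {frozenset(g.nodes[v]["community"]) for v in g}
        part = {}
        for cid, comm in enumerate(sorted(comms, key=lambda c: min(c))):
            for v in comm:
                part[v] = cid
        return g, part
    raise RuntimeError(f"LFR seed generation failed after retries: {last_err}")


def rb_lfr_graph(
    params: RBLFRParams = RBLFRParams(), seed: int | None = None
) -> tuple[nx.Graph, HierarchySpec]:
    """Three-level RB-LFR hierarchy built from one LFR seed graph.

    Copies are indexed (u, v): u is the stage-2 unit, v the copy within the
    unit; copy (0, 0) is the overall seed and copy (u, 0) each unit's seed.
    Returns the graph plus hierarchy levels [per-copy communities, per copy,
    per unit] and the named ground truths "Flat", "S-R*2" and "R*2-S".
    """
    rng = np.random.default_rng(seed)
    base_seed = int(rng.integers(0, 2**31 - 1))
    seed_graph, seed_part = _lfr_seed_graph(params, base_seed)
    c = params.replicas
    n0 = params.seed_n

    def label(u: int, v: int, i: int) -> str:
        return f"u{u}r{v}_{i}"

    graph = nx.Graph()
    flat: dict = {}
    per_copy: dict = {}
    per_unit: dict = {}
    k_seed = len(set(seed_part.values()))
    for u in range(c + 1):
        for v in range(c + 1):
            copy_id = u * (c + 1) + v
            for i in seed_graph.nodes:
                node = label(u, v, i)
                graph.add_node(node)
                flat[node] = copy_id * k_seed + seed_part[i]
                per_copy[node] = copy_id
                per_unit[node] = u
            graph.add_edges_from(
                (label(u, v, a), label(u, v, b)) for a, b in seed_graph.edges
            )
    # stage 1: replica copies connect to their unit's seed copy
    for u in range(c + 1):
        for v in range(1, c + 1):
            targets = rng.integers(0, n0, size=n0)
            keep = rng.random(n0) >= params.p_remove_l2
            nodes0 = list(seed_graph.nodes)
            for i, node_i in enumerate(seed_graph.nodes):
                if keep[i]:
                    graph.add_edge(
                        label(u, v, node_i), label(u, 0, nodes0[targets[i]])
                    )
    # stage 2: replica units connect to the seed unit
    unit0 = [label(0, v, i) for v in range(c + 1) for i in seed_graph.nodes]
    for u in range(1, c + 1):
        for v in range(c + 1):
            targets = rng.integers(0, len(unit0), size=n0)
            keep = rng.random(n0) >= params.p_remove_l3
            for i, node_i in enumerate(seed_graph.nodes):
                if keep[i]:
                    graph.add_edge(label(u, v, node_i), unit0[targets[i]])
    named = {
        "Flat": flat,
        "S-R*2": {
            node: (("s", flat[node]) if per_copy[node] == 0 else ("r", per_copy[node]))
            for node in graph.nodes
        },
        "R*2-S": {
            node: (("r", flat[node]) if per_copy[node] != 0 else ("s", 0))
            for node in graph.nodes
        },
    }
    spec = HierarchySpec([flat, per_copy, per_unit], ["L1", "L2", "L3"], named)
    return graph, spec
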