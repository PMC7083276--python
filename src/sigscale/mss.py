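"""Multi-scale module-based disease-gene prioritization (MSS / RWR / MSS+).

MSS scores genes from multi-resolution module partitions of a protein
network: under each partition, a module's score is the proportion of known
(training) disease genes among its members, every member inherits it, and a
gene's final score combines the per-partition scores across the resolution
grid (mean by default).  RWR is the classical random walk with restart from
the training genes; MSS+ min-max normalizes both score vectors and combines
them linearly.  Performance is estimated by k-fold cross-validated AUC,
ranking held-out disease genes against genes never associated with the
disease.

:func:`synthetic_ppi` generates a planted-partition stand-in for the
integrated protein network, with disease genes concentrated in a few
designated modules, for parameter-recovery experiments.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import scipy.sparse as sp
from scipy.stats import rankdata

from .louvain import OptimizerSettings, optimize
from .quality import ResolutionConfig

__all__ = [
    "AssociationTable",
    "GeneScoreTable",
    "CVResult",
    "mss_scores",
    "rwr_scores",
    "combine_scores",
    "cross_validate",
    "auc_score",
    "multiscale_partitions",
    "synthetic_ppi",
]

DEFAULT_GAMMAS = tuple(np.geomspace(0.1, 1.0, 8))
DEFAULT_RESTART = 0.7
MIN_ASSOCIATED_GENES = 20


@dataclass
class AssociationTable:
    """Mapping disease -> set of associated gene labels present in a network.

    ``min_genes`` is the inclusion criterion: diseases with fewer associated
    genes are rejected at validation.
    """

    associations: dict[str, set]
    min_genes: int = MIN_ASSOCIATED_GENES

    def validate(self, graph: nx.Graph | None = None) -> None:
        for disease, genes in self.associations.items():
            present = genes & set(graph) if graph is not None else genes
            if len(present) < self.min_genes:
                raise ValueError(
                    f"disease {disease!r} has {len(present)} associated genes "
                    f"in the network; at least {self.min_genes} required"
                )

    def __getitem__(self, disease: str) -> set:
        return self.associations[disease]


@dataclass
class GeneScoreTable:
    """Per-gene real scores for one disease; higher means more disease-like."""

    scores: dict
    provenance: str
    gammas: tuple = ()

    def as_array(self, genes: Sequence) -> np.ndarray:
        return np.array([self.scores[g] for g in genes], dtype=float)


@dataclass
class CVResult:
    """Per-fold AUCs, their mean, and the seeded fold assignment."""

    fold_aucs: list[float]
    folds: list[list]
    method: str

    @property
    def mean_auc(self) -> float:
        return float(np.mean(self.fold_aucs))


def multiscale_partitions(
    graph: nx.Graph,
    gammas: Iterable[float] = DEFAULT_GAMMAS,
    measure: str = "significance",
    seed: int = 0,
) -> list[dict]:
    """Optimize the chosen measure at each resolution of the gamma grid."""
    parts = []
    for gamma in gammas:
        settings = OptimizerSettings(
            config=ResolutionConfig(gamma=float(gamma), measure=measure), seed=seed
        )
        parts.append(optimize(graph, settings))
    return parts


def mss_scores(
    graph: nx.Graph,
    partitions: Sequence[Mapping],
    train_genes: set,
    combine: str = "mean",
) -> GeneScoreTable:
    """Module-proportion scores across a list of partitions.

    Under each partition every gene inherits its module's score
    ``|module ∩ train| / |module|``; the final score is the mean (or max)
    over partitions.
    """
    if not partitions:
        raise ValueError("at least one partition required")
    if not train_genes:
        raise ValueError("empty training gene set")
    train = set(train_genes) & set(graph)
    if not train:
        raise ValueError("no training gene is present in the network")
    if combine not in ("mean", "max"):
        raise ValueError(f"unknown combination rule {combine!r}")
    acc = {g: [] for g in graph.nodes}
    for part in partitions:
        members: dict = {}
        hits: dict = {}
        for g in graph.nodes:
            c = part[g]
            members[c] = members.get(c, 0) + 1
            if g in train:
                hits[c] = hits.get(c, 0) + 1
        for g in graph.nodes:
            c = part[g]
            acc[g].append(hits.get(c, 0) / members[c])
    agg = max if combine == "max" else (lambda xs: sum(xs) / len(xs))
    return GeneScoreTable({g: float(agg(v)) for g, v in acc.items()}, "mss")


def rwr_scores(
    graph: nx.Graph,
    seeds: set,
    restart: float = DEFAULT_RESTART,
    tol: float = 1e-10,
    max_iter: int = 100000,
) -> GeneScoreTable:
    """Random walk with restart: stationary x of x = (1-c) W x + c e.

    W is the column-normalized adjacency matrix and e the uniform restart
    distribution over the seed genes; mass reaching degree-zero vertices is
    redirected to the restart distribution so scores always sum to 1.
    """
    if not 0.0 < restart <= 1.0:
        raise ValueError("restart probability must lie in (0, 1]")
    nodes = list(graph.nodes)
    index = {v: i for i, v in enumerate(nodes)}
    seed_idx = [index[s] for s in seeds if s in index]
    if not seed_idx:
        raise ValueError("no seed gene is present in the network")
    n = len(nodes)
    e = np.zeros(n)
    e[seed_idx] = 1.0 / len(seed_idx)
    if restart == 1.0:
        return GeneScoreTable({v: float(e[index[v]]) for v in nodes}, "rwr")
    adj = nx.to_scipy_sparse_array(graph, nodelist=nodes, format="csr", dtype=float)
    deg = np.asarray(adj.sum(axis=0)).ravel()
    dangling = deg == 0.0
    inv = np.where(dangling, 0.0, 1.0 / np.where(dangling, 1.0, deg))
    w = adj @ sp.diags(inv)
    x = e.copy()
    c = restart
    for _ in range(max_iter):
        leaked = float(x[dangling].sum())
        x_new = (1.0 - c) * (w @ x + leaked * e) + c * e
        if np.abs(x_new - x).sum() < tol:
            x = x_new
            break
        x = x_new
    return GeneScoreTable({v: float(x[index[v]]) for v in nodes}, "rwr")


def _minmax(values: np.ndarray) -> np.ndarray:
    lo, hi = values.min(), values.max()
    if hi == lo:
        return np.zeros_like(values)
    return (values - lo) / (hi - lo)


def combine_scores(
    a: GeneScoreTable, b: GeneScoreTable, weight: float = 0.5
) -> GeneScoreTable:
    """MSS+ style linear combination of two min-max normalized score tables."""
    if set(a.scores) != set(b.scores):
        raise ValueError("score tables cover different gene universes")
    if not 0.0 <= weight <= 1.0:
        raise ValueError("weight must lie in [0, 1]")
    genes = sorted(a.scores, key=str)
    va = _minmax(a.as_array(genes))
    vb = _minmax(b.as_array(genes))
    combined = weight * va + (1.0 - weight) * vb
    return GeneScoreTable(
        {g: float(s) for g, s in zip(genes, combined)},
        f"{a.provenance}+{b.provenance}",
    )


def auc_score(pos_scores: np.ndarray, neg_scores: np.ndarray) -> float:
    """Rank-based AUC (ties mid-ranked); equals the Mann-Whitney U statistic
    normalized by n_pos * n_neg."""
    pos = np.asarray(pos_scores, dtype=float)
    neg = np.asarray(neg_scores, dtype=float)
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("need at least one positive and one negative")
    ranks = rankdata(np.concatenate([pos, neg]))
    r_pos = ranks[: len(pos)].sum()
    return float((r_pos - len(pos) * (len(pos) + 1) / 2.0) / (len(pos) * len(neg)))


def cross_validate(
    graph: nx.Graph,
    disease_genes: set,
    method: str | Callable = "mss",
    k: int = 5,
    seed: int = 0,
    gammas: Iterable[float] = DEFAULT_GAMMAS,
    restart: float = DEFAULT_RESTART,
    partitions: Sequence[Mapping] | None = None,
    mss_weight: float = 0.5,
    exclude_train: bool = True,
) -> CVResult:
    """k-fold cross-validated AUC of a gene-scoring method for one disease.

    The disease gene set (restricted to network genes) is split into k
    near-equal seeded folds; each fold in turn is held out, the method is
    trained on the remainder, and the AUC ranks held-out genes against genes
    never associated with the disease.  ``method`` may be ``"mss"``,
    ``"rwr"``, ``"mss_plus"`` or a callable ``train_set -> {gene: score}``.
    Module partitions do not depend on the training genes, so they are
    computed once (or supplied) and reused across folds.
    """
    genes = sorted(set(disease_genes) & set(graph), key=str)
    if len(genes) < k:
        raise ValueError(f"need at least k={k} disease genes in the network")
    rng = np.random.default_rng(seed)
    order = [genes[i] for i in rng.permutation(len(genes))]
    folds = [list(order[i::k]) for i in range(k)]

    method_name = method if isinstance(method, str) else "custom"
    if method_name in ("mss", "mss_plus") and partitions is None:
        partitions = multiscale_partitions(graph, gammas, seed=seed)

    def scorer(train: set) -> Mapping:
        if callable(method):
            return method(train)
        if method == "mss":
            return mss_scores(graph, partitions, train).scores
        if method == "rwr":
            return rwr_scores(graph, train, restart).scores
        if method == "mss_plus":
            return combine_scores(
                mss_scores(graph, partitions, train),
                rwr_scores(graph, train, restart),
                mss_weight,
            ).scores
        raise ValueError(f"unknown method {method!r}")

    negatives = [g for g in graph.nodes if g not in set(genes)]
    aucs = []
    for fold in folds:
        train = set(genes) - set(fold)
        scores = scorer(train)
        # train genes never count as held-out positives; with
        # exclude_train=False they stay in the ranked candidate pool and
        # compete against the held-out genes
        pool_neg = negatives if exclude_train else negatives + sorted(train, key=str)
        pos = np.array([scores[g] for g in fold])
        neg = np.array([scores[g] for g in pool_neg])
        aucs.append(auc_score(pos, neg))
    return CVResult(aucs, folds, method_name)


def synthetic_ppi(
    module_sizes: Sequence[int] = (50,) * 20,
    p_in: float = 0.3,
    p_out: float = 0.01,
    n_disease_genes: int = 60,
    concentration: float = 0.8,
    n_disease_modules: int = 3,
    disease: str = "synthetic_disease",
    seed: int | None = None,
) -> tuple[nx.Graph, AssociationTable, dict, list[int]]:
    """Synthetic planted-partition protein network with planted disease genes.

    A stochastic block model (within-module density ``p_in``, between
    ``p_out``) stands in for the integrated protein network; a fraction
    ``concentration`` of the disease genes is sampled uniformly from
    ``n_disease_modules`` designated modules and the remainder uniformly from
    the other genes.  Returns (graph, association table, planted module
    partition, designated module ids).
    """
    if not 0.0 <= concentration <= 1.0:
        raise ValueError("concentration must lie in [0, 1]")
    if n_disease_genes < MIN_ASSOCIATED_GENES:
        raise ValueError(
            f"n_disease_genes must be >= {MIN_ASSOCIATED_GENES} "
            "(the association inclusion criterion)"
        )
    if n_disease_modules > len(module_sizes):
        raise ValueError("more disease modules than modules")
    rng = np.random.default_rng(seed)
    sbm_seed = int(rng.integers(0, 2**31 - 1))
    probs = [
        [p_in if i == j else p_out for j in range(len(module_sizes))]
        for i in range(len(module_sizes))
    ]
    raw = nx.stochastic_block_model(list(module_sizes), probs, seed=sbm_seed)
    mapping = {i: f"g{i}" for i in raw.nodes}
    graph = nx.relabel_nodes(raw, mapping)
    graph.graph.pop("partition", None)
    offsets = np.concatenate([[0], np.cumsum(module_sizes)])
    truth = {}
    for mod in range(len(module_sizes)):
        for i in range(int(offsets[mod]), int(offsets[mod + 1])):
            truth[f"g{i}"] = mod
    designated = list(rng.choice(len(module_sizes), n_disease_modules, replace=False))
    designated = [int(d) for d in designated]
    inside = [g for g, mod in truth.items() if mod in designated]
    outside = [g for g, mod in truth.items() if mod not in designated]
    n_inside = int(round(concentration * n_disease_genes))
    n_inside = min(n_inside, len(inside))
    picks = list(rng.choice(inside, n_inside, replace=False))
    picks += list(rng.choice(outside, n_disease_genes - n_inside, replace=False))
    assoc = AssociationTable({disease: set(picks)})
    assoc.validate(graph)
    return graph, assoc, truth, designated
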