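"""Plain-text file formats: edge lists, partitions, associations, score tables.

All formats are whitespace/tab-separated text.  Node labels are opaque
strings; community ids are renumbered to 0..Nd-1 by first appearance when
written.
"""
from __future__ import annotations

import logging

from typing import Mapping

import networkx as nx

log = logging.getLogger(__name__)

__all__ = [
    "read_edge_list",
    "write_edge_list",
    "read_partition",
    "write_partition",
    "read_associations",
    "write_scores",
]


def read_edge_list(path) -> nx.Graph:
    """Read a whitespace-separated edge list (two labels per line).

    Lines starting with ``#`` and blank lines are ignored; a third column
    (weight) is accepted and ignored.  Duplicate edges and self-loops are
    dropped with one counted warning each.
    """
    graph = nx.Graph()
    duplicates = 0
    self_loops = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 2:
                raise ValueError(f"{path}:{lineno}: expected two node labels, got {line!r}")
            u, v = fields[0], fields[1]
            if u == v:
                self_loops += 1
                graph.add_node(u)
                continue
            if graph.has_edge(u, v):
                duplicates += 1
                continue
            graph.add_edge(u, v)
    if duplicates:
        log.warning("%s: dropped %d duplicate edge(s)", path, duplicates)
    if self_loops:
        log.warning("%s: dropped %d self-loop(s)", path, self_loops)
    return graph


def write_edge_list(graph: nx.Graph, path) -> None:
    with open(path, "w") as fh:
        for u, v in graph.edges:
            fh.write(f"{u}\t{v}\n")


def _renumber(partition: Mapping) -> dict:
    labels: dict = {}
    out = {}
    for node in sorted(partition, key=str):
        c = partition[node]
        if c not in labels:
            labels[c] = len(labels)
        out[node] = labels[c]
    return out


def write_partition(partition: Mapping, path) -> None:
    """Write (node, community) TSV, communities renumbered by first appearance
    over the string-sorted node order (deterministic)."""
    renum = _renumber(partition)
    with open(path, "w") as fh:
        for node, c in renum.items():
            fh.write(f"{node}\t{c}\n")


def read_partition(path) -> dict:
    """Read a (node, community) TSV; duplicate node rows are an error."""
    partition: dict = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 2:
                raise ValueError(f"{path}:{lineno}: expected (node, community), got {line!r}")
            node, comm = fields[0], fields[1]
            if node in partition:
                raise ValueError(f"{path}:{lineno}: duplicate row for node {node!r}")
            partition[node] = comm
    return partition


def read_associations(path) -> dict[str, set]:
    """Read a (disease, gene) TSV into a disease -> gene-set mapping."""
    assoc: dict[str, set] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 2:
                raise ValueError(f"{path}:{lineno}: expected (disease, gene), got {line!r}")
            assoc.setdefault(fields[0], set()).add(fields[1])
    return assoc


def write_scores(tables: Mapping[str, Mapping], path) -> None:
    """Write per-gene score columns (one column per method) as TSV."""
    methods = list(tables)
    genes = sorted({g for t in tables.values() for g in t}, key=str)
    with open(path, "w") as fh:
        fh.write("gene\t" + "\t".join(methods) + "\n")
        for g in genes:
            row = "\t".join(f"{tables[m].get(g, float('nan')):.8g}" for m in methods)
            fh.write(f"{g}\t{row}\n")
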