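"""Partition comparison metrics: NMI, AMI, ARI, Fr, and community counting.

NMI uses the arithmetic-mean normalization; AMI is chance-adjusted under the
permutation (hypergeometric) model with max normalization; ARI is the
chance-adjusted Rand index.  ``Fr`` is the fraction of vertices whose
ground-truth community is not exactly reproduced (as a vertex set) in the
detected partition; unlike the three indices it is directional (truth first).
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
from sklearn.metrics import (
    adjusted_mutual_info_score,
    adjusted_rand_score,
    normalized_mutual_info_score,
)
from sklearn.metrics.cluster import contingency_matrix

__all__ = [
    "ConfusionTable",
    "confusion_table",
    "compare_partitions",
    "fraction_affected",
    "community_count",
]


@dataclass(frozen=True)
class ConfusionTable:
    """Vertex counts n_ij per (truth community i, detected community j)."""

    counts: np.ndarray
    truth_labels: list
    detected_labels: list

    @property
    def truth_marginals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def detected_marginals(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    @property
    def n(self) -> int:
        return int(self.counts.sum())


def _aligned_labels(truth: Mapping, detected: Mapping):
    if set(truth) != set(detected):
        raise ValueError("partitions cover different node sets")
    nodes = sorted(truth, key=str)
    enc_t: dict = {}
    enc_d: dict = {}
    a = np.empty(len(nodes), dtype=int)
    b = np.empty(len(nodes), dtype=int)
    for i, v in enumerate(nodes):
        a[i] = enc_t.setdefault(truth[v], len(enc_t))
        b[i] = enc_d.setdefault(detected[v], len(enc_d))
    return a, b, list(enc_t), list(enc_d)


def confusion_table(truth: Mapping, detected: Mapping) -> ConfusionTable:
    a, b, tl, dl = _aligned_labels(truth, detected)
    counts = contingency_matrix(a, b)
    return ConfusionTable(np.asarray(counts), tl, dl)


def compare_partitions(truth: Mapping, detected: Mapping) -> dict:
    """NMI / AMI / ARI between two partitions of the same node set.

    All three are symmetric, invariant under community relabeling, and equal
    1 on identical partitions; AMI and ARI are near 0 for independent random
    partitions, whereas NMI can stay substantially positive when both
    partitions have many groups.
    """
    a, b, _, _ = _aligned_labels(truth, detected)
    return {
        "nmi": float(normalized_mutual_info_score(a, b, average_method="arithmetic")),
        "ami": float(adjusted_mutual_info_score(a, b, average_method="max")),
        "ari": float(adjusted_rand_score(a, b)),
    }


def fraction_affected(
    truth: Mapping, detected: Mapping, merging_only: bool = False
) -> float:
    """Fraction Fr of vertices whose true community is not exactly recovered.

    A truth community counts as affected when its vertex set is not present
    verbatim among the detected communities; with ``merging_only=True`` only
    communities strictly contained in a larger detected community count
    (pure splits are then ignored).
    """
    if set(truth) != set(detected):
        raise ValueError("partitions cover different node sets")
    truth_comms: dict = {}
    det_comms: dict = {}
    for v, ct in truth.items():
        truth_comms.setdefault(ct, set()).add(v)
    for v, cd in detected.items():
        det_comms.setdefault(cd, set()).add(v)
    detected_sets = {frozenset(s) for s in det_comms.values()}
    affected = 0
    for comm in truth_comms.values():
        fs = frozenset(comm)
        if fs in detected_sets:
            continue
        if merging_only:
            rep = next(iter(comm))
            container = det_comms[detected[rep]]
            if not comm < container:
                continue
        affected += len(comm)
    return affected / len(truth)


def community_count(partition: Mapping) -> int:
    """Number of non-empty communities Nd."""
    return len(set(partition.values()))
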