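"""Weighted consensus networks over multiple inference methods.

Different inference algorithms (CMIMN, SparCC, SPIEC-EASI/glasso, SPRING,
...) routinely disagree on microbiome data.  A consensus network records,
for every taxon pair, how many of the M input methods report that edge — a
weight from 0 (no method) to M (all methods).  Thresholding the weight
trades off density against reliability: weight >= 1 keeps every candidate
association, weight = M keeps only edges confirmed unanimously.  All inputs
are binarised, unsigned networks; signed or weighted method outputs must be
thresholded upstream, since consensus edges are interpreted purely as
reproducible unsigned dependencies.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .abundance_io import UndirectedNetwork

__all__ = [
    "ConsensusNetwork",
    "build_consensus",
    "threshold_consensus",
    "edge_overlap_partition",
]


@dataclass
class ConsensusNetwork:
    """Symmetric integer edge weights = number of supporting methods."""

    node_ids: list[str]
    weights: np.ndarray  # (p, p) symmetric ints, zero diagonal
    method_names: list[str]

    @property
    def n_methods(self) -> int:
        return len(self.method_names)

    def weight_of(self, a: str, b: str) -> int:
        i, j = self.node_ids.index(a), self.node_ids.index(b)
        return int(self.weights[i, j])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.weights, index=self.node_ids, columns=self.node_ids, dtype=int
        )


def _check_inputs(
    networks: list[UndirectedNetwork], names: list[str] | None = None
) -> list[str]:
    if len(networks) < 2:
        raise ValueError("consensus needs at least 2 networks")
    ref = set(networks[0].node_ids)
    for k, net in enumerate(networks[1:], start=1):
        nodes = set(net.node_ids)
        if nodes != ref:
            diff = sorted(nodes.symmetric_difference(ref))
            raise ValueError(
                f"network {k} has a different node set; symmetric difference: {diff}"
            )
    if names is not None:
        if len(names) != len(networks):
            raise ValueError("one method name per network required")
        if len(set(names)) != len(names):
            raise ValueError(f"duplicate method names in {names}")
    return list(networks[0].node_ids)


def build_consensus(
    networks: list[UndirectedNetwork], method_names: list[str]
) -> ConsensusNetwork:
    """Simple voting: each pair's weight = number of networks containing it."""
    nodes = _check_inputs(networks, method_names)
    order = {n: i for i, n in enumerate(nodes)}
    w = np.zeros((len(nodes), len(nodes)), dtype=int)
    for net in networks:
        for a, b in net.edges:
            i, j = order[a], order[b]
            w[i, j] += 1
            w[j, i] += 1
    return ConsensusNetwork(nodes, w, list(method_names))


def threshold_consensus(cn: ConsensusNetwork, min_weight: int) -> UndirectedNetwork:
    """Binary network of pairs whose weight >= min_weight (1 <= w <= M)."""
    if not 1 <= min_weight <= cn.n_methods:
        raise ValueError(
            f"min_weight must be in [1, {cn.n_methods}], got {min_weight}"
        )
    edges = set()
    for i, j in zip(*np.nonzero(np.triu(cn.weights >= min_weight, 1))):
        edges.add((cn.node_ids[i], cn.node_ids[j]))
    return UndirectedNetwork(list(cn.node_ids), edges)


def edge_overlap_partition(
    networks: list[UndirectedNetwork], method_names: list[str] | None = None
) -> dict[frozenset[str], int]:
    """Venn-cell edge counts: edges present in exactly each method subset.

    Returns a map from every nonempty subset of method names to the number
    of edges appearing in exactly those methods; cells sum to the size of
    the union of all edge sets.
    """
    nodes = _check_inputs(networks, method_names)
    del nodes
    if method_names is None:
        method_names = [f"method_{k}" for k in range(len(networks))]
    membership: dict[tuple[str, str], set[str]] = {}
    for name, net in zip(method_names, networks):
        for e in net.edges:
            membership.setdefault(e, set()).add(name)
    cells = {
        frozenset(sub): 0
        for r in range(1, len(method_names) + 1)
        for sub in combinations(method_names, r)
    }
    for members in membership.values():
        cells[frozenset(members)] += 1
    return cells
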