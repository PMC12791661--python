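"""Network-topology-based selection of disease-associated taxa.

Two complementary strategies operate on condition-specific networks (one
inferred from healthy "clean" samples, one from diseased "scab" samples),
each constructed by several inference methods:

Strategy 1 — differential centrality.  For each method and each of five
centrality metrics (degree DE, eigenvector EV, PageRank PR, closeness CL,
betweenness BE), rank taxa by the absolute difference of their centrality
between the clean and scab networks; the top ceil(top_frac * p) taxa in any
metric are flagged for that method, and the final set is the intersection
across all methods.

Strategy 2 — composite topology score.  Within one network, each metric is
min-max scaled to [0, 1] across taxa and combined as

    score_i = w1*DE_i + w2*EV_i + w3*PR_i + w4*CL_i + w5*BE_i

with default weights (0.1, 0.1, 0.1, 0.2, 0.5): the path-based metrics
(betweenness, closeness) carry 0.7 of the weight because bridging taxa are
the usual keystone candidates, while the neighbour-based metrics (degree,
eigenvector, PageRank) share the rest.  Per condition, the consensus set is
the taxa in the top fraction for every method.

Scaling before weighting keeps the five metrics commensurate; raw
betweenness would otherwise dominate the sum regardless of the weights.
Ties at the top-fraction boundary are all included (deterministic and
label-independent), so the selected set can exceed ceil(top_frac * p).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from math import ceil

import networkx as nx
import numpy as np
import pandas as pd

from .abundance_io import UndirectedNetwork

__all__ = [
    "METRICS",
    "CentralityTable",
    "CompositeWeights",
    "SelectionReport",
    "centralities",
    "top_fraction",
    "strategy1_differential",
    "strategy2_composite",
    "strategy2_consensus",
    "finalize_selection",
]

METRICS = ("degree", "eigenvector", "pagerank", "closeness", "betweenness")


@dataclass
class CentralityTable:
    """Per-node values of the five centrality metrics in one network."""

    node_ids: list[str]
    metrics: pd.DataFrame  # index = node_ids, columns = METRICS
    network_label: str = ""
    method_label: str = ""


@dataclass
class CompositeWeights:
    """Weights for (DE, EV, PR, CL, BE) in the composite topology score."""

    degree: float = 0.1
    eigenvector: float = 0.1
    pagerank: float = 0.1
    closeness: float = 0.2
    betweenness: float = 0.5

    def as_array(self) -> np.ndarray:
        w = np.array(
            [self.degree, self.eigenvector, self.pagerank,
             self.closeness, self.betweenness]
        )
        if (w < 0).any():
            raise ValueError("composite weights must be nonnegative")
        return w


@dataclass
class SelectionReport:
    """Per-taxon selection flags across ML and network strategies."""

    taxa: list[str]
    ml_selected: set[str] = field(default_factory=set)
    strategy1_selected: set[str] = field(default_factory=set)
    strategy2_selected: set[str] = field(default_factory=set)
    final_selected: set[str] = field(default_factory=set)
    tiers: dict[str, set[str]] = field(default_factory=dict)
    details: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for t in self.taxa:
            rows.append(
                {
                    "taxon": t,
                    "ml": t in self.ml_selected,
                    "strategy1": t in self.strategy1_selected,
                    "strategy2": t in self.strategy2_selected,
                    "final": t in self.final_selected,
                }
            )
        return pd.DataFrame(rows).set_index("taxon")


def _to_graph(net: UndirectedNetwork) -> nx.Graph:
    g = nx.Graph()
    g.add_nodes_from(net.node_ids)
    g.add_edges_from(net.edges)
    return g


def centralities(net: UndirectedNetwork, network_label: str = "",
                 method_label: str = "") -> CentralityTable:
    """Compute the five centrality metrics, finite on disconnected graphs.

    degree: raw edge count per node.  eigenvector: principal eigenvector of
    the adjacency, computed per connected component (power iteration,
    tol 1e-10); isolated nodes get 0.  pagerank: damping 0.85 (sums to 1).
    closeness: harmonic closeness normalised by (n-1).  betweenness:
    shortest-path betweenness normalised by (n-1)(n-2)/2.
    """
    if not net.node_ids:
        raise ValueError("empty node set")
    g = _to_graph(net)
    n = g.number_of_nodes()
    degree = dict(g.degree())
    eigen = {v: 0.0 for v in g}
    for comp in nx.connected_components(g):
        if len(comp) < 2:
            continue
        sub = g.subgraph(comp)
        eigen.update(
            nx.eigenvector_centrality(sub, max_iter=10_000, tol=1e-10)
        )
    pagerank = nx.pagerank(g, alpha=0.85)
    harm = nx.harmonic_centrality(g)
    closeness = {v: (harm[v] / (n - 1) if n > 1 else 0.0) for v in g}
    betweenness = nx.betweenness_centrality(g, normalized=True)
    df = pd.DataFrame(
        {
            "degree": degree,
            "eigenvector": eigen,
            "pagerank": pagerank,
            "closeness": closeness,
            "betweenness": betweenness,
        }
    ).loc[list(net.node_ids), list(METRICS)]
    return CentralityTable(list(net.node_ids), df, network_label, method_label)


def top_fraction(scores: pd.Series, top_frac: float) -> set[str]:
    """Indices of the top ceil(top_frac * p) scores, expanding boundary ties."""
    if not 0 < top_frac <= 1:
        raise ValueError("top_frac must lie in (0, 1]")
    k = ceil(top_frac * len(scores))
    cutoff = scores.sort_values(ascending=False).iloc[k - 1]
    chosen = set(scores.index[scores >= cutoff])
    if len(chosen) > k:
        warnings.warn(
            f"tie at the top-{top_frac:.0%} boundary expanded the selection "
            f"from {k} to {len(chosen)} taxa",
            stacklevel=2,
        )
    return chosen


def _check_same_taxa(
    clean_nets: dict[str, UndirectedNetwork],
    scab_nets: dict[str, UndirectedNetwork],
) -> list[str]:
    if set(clean_nets) != set(scab_nets):
        raise ValueError("clean and scab conditions must share method keys")
    all_nets = list(clean_nets.values()) + list(scab_nets.values())
    taxa = set(all_nets[0].node_ids)
    for net in all_nets[1:]:
        if set(net.node_ids) != taxa:
            raise ValueError("all networks must share the same taxon set")
    return list(all_nets[0].node_ids)


def strategy1_differential(
    clean_nets: dict[str, UndirectedNetwork],
    scab_nets: dict[str, UndirectedNetwork],
    top_frac: float = 0.20,
) -> tuple[set[str], pd.DataFrame]:
    """Differential-centrality selection (Strategy 1).

    Returns the cross-method intersection of flagged taxa plus a per-taxon
    table with the methods and metrics responsible for each flag.
    """
    taxa = _check_same_taxa(clean_nets, scab_nets)
    per_method_flagged: dict[str, set[str]] = {}
    responsible: dict[str, set[str]] = {t: set() for t in taxa}
    for method in sorted(clean_nets):
        c_tab = centralities(clean_nets[method], "clean", method).metrics
        s_tab = centralities(scab_nets[method], "scab", method).metrics
        diff = (c_tab - s_tab).abs()
        flagged: set[str] = set()
        for metric in METRICS:
            col = diff[metric]
            if (col == 0).all():
                warnings.warn(
                    f"method {method}: all {metric} differences are zero "
                    "(identical networks?); selection degenerate for this metric",
                    stacklevel=2,
                )
            sel = top_fraction(col, top_frac)
            flagged |= sel
            for t in sel:
                responsible[t].add(f"{method}:{metric}")
        per_method_flagged[method] = flagged
    selected = set.intersection(*per_method_flagged.values())
    table = pd.DataFrame(
        {
            "selected": [t in selected for t in taxa],
            "features": [",".join(sorted(responsible[t])) for t in taxa],
        },
        index=taxa,
    )
    return selected, table


def _minmax(col: pd.Series) -> pd.Series:
    lo, hi = col.min(), col.max()
    # near-constant metrics (e.g. power-iteration noise on a symmetric graph)
    # would otherwise have pure numerical jitter blown up to the full [0, 1]
    if hi - lo <= 1e-9 * max(1.0, abs(hi)):
        warnings.warn(
            f"metric {col.name!r} is constant across nodes; it contributes 0 "
            "to the composite score",
            stacklevel=3,
        )
        return pd.Series(0.0, index=col.index)
    return (col - lo) / (hi - lo)


def strategy2_composite(
    net: UndirectedNetwork,
    weights: CompositeWeights | None = None,
    top_frac: float = 0.20,
) -> tuple[pd.Series, set[str]]:
    """Composite topology score per taxon and its top-fraction set."""
    weights = weights or CompositeWeights()
    tab = centralities(net).metrics
    scaled = tab.apply(_minmax, axis=0)
    scores = scaled @ weights.as_array()
    scores.name = "score"
    return scores, top_fraction(scores, top_frac)


def strategy2_consensus(
    clean_nets: dict[str, UndirectedNetwork],
    scab_nets: dict[str, UndirectedNetwork],
    weights: CompositeWeights | None = None,
    top_frac: float = 0.20,
) -> dict[str, set[str]]:
    """Per-condition cross-method consensus of composite-score top sets.

    Returns the clean-condition and scab-condition consensus sets (taxa in
    the top fraction for *every* method) plus their union and intersection.
    """
    _check_same_taxa(clean_nets, scab_nets)
    out: dict[str, set[str]] = {}
    for label, nets in (("clean", clean_nets), ("scab", scab_nets)):
        tops = [
            strategy2_composite(nets[m], weights, top_frac)[1]
            for m in sorted(nets)
        ]
        out[label] = set.intersection(*tops)
    out["union"] = out["clean"] | out["scab"]
    out["intersection"] = out["clean"] & out["scab"]
    return out


def finalize_selection(
    taxa: list[str],
    ml_selected: set[str],
    strategy1_selected: set[str],
    strategy2_selected: set[str],
    rule: str = "intersection_all",
) -> SelectionReport:
    """Combine ML and network selections into the final report with tiers.

    Tiers mirror the usual summary-table footnotes: "a" = in ML, Strategy 1
    and Strategy 2; "b" = ML and Strategy 1 only; "c" = ML and Strategy 2
    only; "d" = Strategy 1 and Strategy 2 only.  The final set is either the
    three-way intersection (``intersection_all``) or ML combined with at
    least one network strategy (``ml_and_any_network``).
    """
    universe = set(taxa)
    for name, s in (
        ("ml", ml_selected),
        ("strategy1", strategy1_selected),
        ("strategy2", strategy2_selected),
    ):
        if not s <= universe:
            raise ValueError(
                f"{name} selection contains taxa outside the shared universe: "
                f"{sorted(s - universe)}"
            )
    ml, s1, s2 = ml_selected, strategy1_selected, strategy2_selected
    tiers = {
        "a": ml & s1 & s2,
        "b": (ml & s1) - s2,
        "c": (ml & s2) - s1,
        "d": (s1 & s2) - ml,
    }
    if rule == "intersection_all":
        final = ml & s1 & s2
    elif rule == "ml_and_any_network":
        final = ml & (s1 | s2)
    else:
        raise ValueError(f"unknown rule {rule!r}")
    return SelectionReport(
        taxa=list(taxa),
        ml_selected=set(ml),
        strategy1_selected=set(s1),
        strategy2_selected=set(s2),
        final_selected=final,
        tiers=tiers,
    )
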