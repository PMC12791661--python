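"""CMIMN: conditional-mutual-information skeleton learning for microbiome data.

The algorithm recovers an undirected dependency skeleton among taxa in two
filtering stages with quantile-based (dynamic) thresholds:

  Step 0  start from the complete graph on all taxa;
  Step 1  compute Gaussian MI for every pair on the normalised data;
  Step 2  drop edges whose MI is strictly below the empirical q1 quantile of
          all pairwise MI values (default q1 = 0.70) -> S0;
  Step 3  for each surviving edge (X, Y), with candidate separators fixed
          once as the common neighbours of X and Y in S0, compute order-1
          CMI(X, Y | Z) for each single separator Z and keep the maximum;
  Step 4  drop edges whose maximum CMI is strictly below the q2 quantile of
          the max-CMI distribution (default q2 = 0.95) -> S1.

Quantile thresholds adapt to the scale of each dataset, unlike the fixed
cutoffs of classic constraint-based structure learners, and q1/q2 directly
control sparsity (higher quantiles, sparser skeletons).  Because separator
sets are frozen from S0 before any Step-4 removal, the result is invariant
to the order in which taxa are presented.  Edges with no common neighbour
in S0 have no conditioning evidence that could explain them away; they
bypass the CMI filter and are retained, and they do not contribute to the
q2 threshold distribution.  There is no randomness anywhere in inference.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .abundance_io import AbundanceTable, UndirectedNetwork, canonical_edge
from .gaussian_info import DEFAULT_CAP_NATS, cmi_from_cov, mi_from_cov
from .normalize import default_pipeline

__all__ = [
    "CmimnConfig",
    "CmimnTrace",
    "quantile_threshold",
    "infer",
    "permutation_invariance_check",
    "tune_q2_to_edge_count",
]

Edge = tuple[str, str]


@dataclass
class CmimnConfig:
    """Tuning knobs of the skeleton learner.

    q1, q2:
        quantile thresholds for the MI and CMI filtering stages, in (0, 1).
    quantitative:
        if True the input counts are log(count + pseudocount)-transformed
        before estimation; if False values pass through unchanged (supply
        pre-normalised data, e.g. CLR).
    """

    q1: float = 0.70
    q2: float = 0.95
    quantitative: bool = True
    pseudocount: float = 1.0
    cap_nats: float = DEFAULT_CAP_NATS

    def __post_init__(self) -> None:
        if not (0 < self.q1 < 1 and 0 < self.q2 < 1):
            raise ValueError("q1 and q2 must lie strictly inside (0, 1)")


@dataclass
class CmimnTrace:
    """Full intermediate state of one inference run.

    ``max_cmi`` maps each S0 edge to ``(value, separator)``; separator is
    None for edges with no common neighbour in S0 (value is None too, and
    the edge bypasses the CMI filter).
    """

    mi_values: dict[Edge, float]
    s0_edges: set[Edge]
    max_cmi: dict[Edge, tuple[float | None, str | None]]
    s1_edges: set[Edge]
    mi_threshold: float = float("nan")
    cmi_threshold: float = float("nan")
    dropped_constant_taxa: list[str] = field(default_factory=list)


def quantile_threshold(values, q: float) -> float:
    """Empirical q-quantile with linear interpolation between order statistics.

    Downstream filters remove items strictly below the returned value, so
    ties at the threshold survive.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("cannot take a quantile of an empty collection")
    if not 0 < q < 1:
        raise ValueError("q must lie strictly inside (0, 1)")
    return float(np.quantile(values, q, method="linear"))


def infer(
    table: AbundanceTable, config: CmimnConfig | None = None
) -> tuple[UndirectedNetwork, CmimnTrace]:
    """Run the two-stage skeleton learner; returns the network and its trace."""
    config = config or CmimnConfig()
    if table.n_samples < 3:
        raise ValueError("need at least 3 samples")
    norm = default_pipeline(table, config.quantitative, config.pseudocount)
    values = norm.values

    constant = np.ptp(values, axis=0) == 0
    dropped = [t for t, c in zip(norm.taxon_ids, constant) if c]
    if dropped:
        warnings.warn(
            f"dropping {len(dropped)} constant taxa before inference: {dropped}",
            stacklevel=2,
        )
        values = values[:, ~constant]
    taxa = [t for t, c in zip(norm.taxon_ids, constant) if not c]
    p = len(taxa)
    if p < 2:
        raise ValueError("fewer than 2 non-constant taxa; nothing to infer")

    cov = np.cov(values, rowvar=False, ddof=1)
    col = {t: k for k, t in enumerate(taxa)}

    # Steps 0-1: MI on the complete graph
    mi_values: dict[Edge, float] = {}
    for a in range(p):
        for b in range(a + 1, p):
            e = canonical_edge(taxa[a], taxa[b])
            mi_values[e] = mi_from_cov(cov, a, b, config.cap_nats)

    # Step 2: q1 quantile filter -> S0
    mi_threshold = quantile_threshold(list(mi_values.values()), config.q1)
    s0 = {e for e, v in mi_values.items() if v >= mi_threshold}

    # Step 3: order-1 CMI with separator sets frozen from S0
    neighbors: dict[str, set[str]] = {t: set() for t in taxa}
    for a, b in s0:
        neighbors[a].add(b)
        neighbors[b].add(a)
    max_cmi: dict[Edge, tuple[float | None, str | None]] = {}
    for e in s0:
        a, b = e
        separators = sorted(neighbors[a] & neighbors[b])
        if not separators:
            max_cmi[e] = (None, None)
            continue
        best_v, best_z = -np.inf, None
        for zname in separators:
            v = cmi_from_cov(cov, col[a], col[b], [col[zname]], config.cap_nats)
            if v > best_v:
                best_v, best_z = v, zname
        max_cmi[e] = (best_v, best_z)

    # Step 4: q2 quantile filter on edges that have conditioning evidence
    with_sep = [v for v, z in max_cmi.values() if z is not None]
    if with_sep:
        cmi_threshold = quantile_threshold(with_sep, config.q2)
        s1 = {
            e
            for e, (v, z) in max_cmi.items()
            if z is None or v >= cmi_threshold
        }
    else:
        cmi_threshold = float("nan")
        s1 = set(s0)

    net = UndirectedNetwork(taxa, s1)
    trace = CmimnTrace(
        mi_values=mi_values,
        s0_edges=s0,
        max_cmi=max_cmi,
        s1_edges=s1,
        mi_threshold=mi_threshold,
        cmi_threshold=cmi_threshold,
        dropped_constant_taxa=dropped,
    )
    return net, trace


def permutation_invariance_check(
    table: AbundanceTable,
    config: CmimnConfig | None = None,
    n_perms: int = 5,
    seed: int = 0,
) -> bool:
    """True iff the inferred edge set survives random taxon reorderings."""
    reference, _ = infer(table, config)
    rng = np.random.default_rng(seed)
    for _ in range(n_perms):
        order = rng.permutation(table.n_taxa)
        permuted = AbundanceTable(
            table.counts[:, order],
            [table.taxon_ids[k] for k in order],
            list(table.sample_ids),
            table.labels,
        )
        net, _ = infer(permuted, config)
        if net.edges != reference.edges:
            return False
    return True


def tune_q2_to_edge_count(
    table: AbundanceTable,
    target_edges: int,
    config: CmimnConfig | None = None,
    max_iter: int = 30,
) -> tuple[UndirectedNetwork, CmimnConfig]:
    """Binary-search q2 so that |S1| comes closest to ``target_edges``.

    Used when benchmarking against a known ground truth, where every method
    should produce a comparable number of edges.  |S1| is non-increasing in
    q2, so a simple bisection suffices; the achievable sizes are discrete,
    and the closest one wins (ties go to the sparser network).
    """
    config = config or CmimnConfig()
    lo, hi = 1e-6, 1 - 1e-6
    best: tuple[int, float, UndirectedNetwork, CmimnConfig] | None = None
    for _ in range(max_iter):
        mid = (lo + hi) / 2
        cand = CmimnConfig(
            config.q1, mid, config.quantitative, config.pseudocount, config.cap_nats
        )
        net, _ = infer(table, cand)
        gap = abs(net.n_edges - target_edges)
        if best is None or (gap, net.n_edges) < (best[0], best[2].n_edges):
            best = (gap, mid, net, cand)
        if net.n_edges > target_edges:
            lo = mid
        elif net.n_edges < target_edges:
            hi = mid
        else:
            break
    assert best is not None
    return best[2], best[3]
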