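"""Synthetic microbiome data with known ground-truth network structure.

Real microbial interaction networks are unknown, so algorithm benchmarking
uses simulated count data whose dependence structure is prescribed.  The
generator follows the standard graphical-model recipe:

1. a band graph on p taxa (edge iff 0 < |i - j| <= band_width) defines the
   ground-truth adjacency;
2. a precision (inverse covariance) matrix is built with +/-strength entries
   on the edges (random signs) and a diagonally dominant diagonal, so its
   support matches the adjacency exactly and it is positive definite;
3. counts are drawn by NorTA (normal-to-anything): a latent multivariate
   normal with the implied correlation is pushed through the normal CDF and
   then the inverse CDF of a zero-inflated negative binomial marginal.

The default marginal (mean 20, dispersion 0.5, zero probability 0.3) gives
zero-rich, strongly overdispersed counts of the kind 16S OTU tables show;
dispersion here is the negative-binomial size parameter, so variance =
mean + mean^2/dispersion and large dispersion approaches Poisson.

``two_class_dataset`` produces a healthy/diseased pair of ground truths
sharing a chosen fraction of edges (shared core plus class-specific
rewired edges), emulating disease-driven rewiring of the community.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy import stats

from .abundance_io import AbundanceTable, UndirectedNetwork, canonical_edge

__all__ = [
    "CountMarginal",
    "GroundTruth",
    "band_graph",
    "make_precision",
    "make_band_truth",
    "sample_counts",
    "two_class_dataset",
    "truth_network",
    "expected_random_f1",
]


@dataclass
class CountMarginal:
    """Zero-inflated negative binomial marginal for one taxon's counts.

    ``zero_prob = 0`` gives a plain negative binomial; ``dispersion`` is the
    NB size parameter (variance = mean + mean^2/dispersion).
    """

    mean: float = 20.0
    dispersion: float = 0.5
    zero_prob: float = 0.3

    def __post_init__(self) -> None:
        if self.mean <= 0 or self.dispersion <= 0:
            raise ValueError("mean and dispersion must be positive")
        if not 0 <= self.zero_prob < 1:
            raise ValueError("zero_prob must lie in [0, 1)")

    def ppf(self, q: np.ndarray) -> np.ndarray:
        r = self.dispersion
        prob = r / (r + self.mean)
        if self.zero_prob > 0:
            q = np.clip((q - self.zero_prob) / (1 - self.zero_prob), 0.0, 1.0)
        # scipy's discrete ppf maps q=0 to -1; such draws are structural zeros
        return np.maximum(stats.nbinom.ppf(q, r, prob), 0.0)


@dataclass
class GroundTruth:
    """Known adjacency + compatible precision matrix behind a simulation."""

    adjacency: np.ndarray
    precision: np.ndarray
    taxon_ids: list[str]
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        lam_min = float(np.linalg.eigvalsh(self.precision).min())
        if lam_min <= 0:
            raise ValueError(f"precision is not positive definite (min eig {lam_min})")
        off = (self.precision != 0) & ~np.eye(len(self.taxon_ids), dtype=bool)
        if not np.array_equal(off, self.adjacency.astype(bool)):
            raise ValueError("precision support does not match the adjacency")
        self.params.setdefault("min_eigenvalue", lam_min)

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum() // 2)


def band_graph(p: int, band_width: int) -> np.ndarray:
    """0/1 adjacency with an edge iff 0 < |i - j| <= band_width."""
    if p < 2:
        raise ValueError("need at least 2 nodes")
    if not 1 <= band_width < p:
        raise ValueError(f"band_width must lie in [1, {p - 1}], got {band_width}")
    idx = np.arange(p)
    dist = np.abs(idx[:, None] - idx[None, :])
    return ((dist > 0) & (dist <= band_width)).astype(int)


def _default_ids(p: int) -> list[str]:
    return [f"taxon_{k:03d}" for k in range(p)]


def make_precision(
    adjacency: np.ndarray, strength: float = 0.3, seed: int = 0
) -> np.ndarray:
    """Precision matrix with +/-strength on edges and a dominant diagonal.

    Signs are drawn at random (seeded); the diagonal is the absolute row sum
    of the off-diagonal entries plus 1, which guarantees strict diagonal
    dominance and hence positive definiteness.
    """
    adjacency = np.asarray(adjacency)
    p = adjacency.shape[0]
    rng = np.random.default_rng(seed)
    signs = np.triu(rng.choice((-1.0, 1.0), size=(p, p)), 1)
    off = signs * strength * np.triu(adjacency, 1)
    off = off + off.T
    prec = off + np.diag(np.abs(off).sum(axis=1) + 1.0)
    return prec


def sample_counts(
    truth: GroundTruth,
    n: int,
    marginal: CountMarginal | None = None,
    seed: int = 0,
) -> AbundanceTable:
    """Draw n samples by NorTA from the truth's implied latent correlation."""
    if n < 3:
        raise ValueError("need at least 3 samples")
    marginal = marginal or CountMarginal()
    cov = np.linalg.inv(truth.precision)
    d = np.sqrt(np.diag(cov))
    corr = cov / np.outer(d, d)
    rng = np.random.default_rng(seed)
    latent = rng.multivariate_normal(
        np.zeros(corr.shape[0]), corr, size=n, method="cholesky"
    )
    counts = marginal.ppf(stats.norm.cdf(latent))
    return AbundanceTable(counts, list(truth.taxon_ids), [f"s{k:04d}" for k in range(n)])


def truth_network(truth: GroundTruth) -> UndirectedNetwork:
    """The ground-truth adjacency as an UndirectedNetwork."""
    ids = truth.taxon_ids
    edges = {
        canonical_edge(ids[i], ids[j])
        for i, j in zip(*np.nonzero(np.triu(truth.adjacency, 1)))
    }
    return UndirectedNetwork(list(ids), edges)


def make_band_truth(
    p: int, band_width: int = 2, strength: float = 0.3, seed: int = 0
) -> GroundTruth:
    """Convenience: band-graph adjacency plus a compatible precision."""
    adj = band_graph(p, band_width)
    prec = make_precision(adj, strength, seed)
    return GroundTruth(
        adj,
        prec,
        _default_ids(p),
        params={"band_width": band_width, "strength": strength, "seed": seed},
    )


def two_class_dataset(
    p: int,
    n_per_class: int,
    shared_frac: float = 0.6,
    seed: int = 0,
    band_width: int = 2,
    strength: float = 0.3,
    marginal: CountMarginal | None = None,
) -> tuple[AbundanceTable, GroundTruth, GroundTruth]:
    """Healthy/diseased dataset whose class networks share ``shared_frac`` edges.

    Both class graphs have the edge count of the p/band_width band graph: a
    shared core of round(shared_frac * m) band edges plus class-specific
    edges rewired (seeded) to pairs outside the band, disjoint between the
    classes.  Labels are 0 for the first ``n_per_class`` samples (healthy)
    and 1 for the rest (diseased).
    """
    if not 0 <= shared_frac <= 1:
        raise ValueError("shared_frac must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    base = band_graph(p, band_width)
    band_edges = [tuple(e) for e in np.argwhere(np.triu(base, 1))]
    m = len(band_edges)
    n_core = round(shared_frac * m)
    n_specific = m - n_core
    non_band = [
        (i, j) for i, j in combinations(range(p), 2) if base[i, j] == 0
    ]
    if 2 * n_specific > len(non_band):
        raise ValueError(
            f"shared_frac={shared_frac} infeasible: needs {2 * n_specific} "
            f"rewired edges but only {len(non_band)} non-band pairs exist"
        )
    core_idx = rng.choice(m, size=n_core, replace=False)
    core = [band_edges[k] for k in sorted(core_idx)]
    rewire_idx = rng.choice(len(non_band), size=2 * n_specific, replace=False)
    spec_a = [non_band[k] for k in sorted(rewire_idx[:n_specific])]
    spec_b = [non_band[k] for k in sorted(rewire_idx[n_specific:])]

    def build(edges: list[tuple[int, int]], sub_seed: int) -> GroundTruth:
        adj = np.zeros((p, p), dtype=int)
        for i, j in edges:
            adj[i, j] = adj[j, i] = 1
        prec = make_precision(adj, strength, sub_seed)
        return GroundTruth(
            adj, prec, _default_ids(p),
            params={"shared_frac": shared_frac, "seed": sub_seed},
        )

    truth_clean = build(core + spec_a, seed + 1)
    truth_scab = build(core + spec_b, seed + 2)
    tab_clean = sample_counts(truth_clean, n_per_class, marginal, seed + 3)
    tab_scab = sample_counts(truth_scab, n_per_class, marginal, seed + 4)
    counts = np.vstack([tab_clean.counts, tab_scab.counts])
    sample_ids = [f"clean_{k:04d}" for k in range(n_per_class)] + [
        f"scab_{k:04d}" for k in range(n_per_class)
    ]
    labels = np.array([0] * n_per_class + [1] * n_per_class)
    table = AbundanceTable(counts, _default_ids(p), sample_ids, labels)
    return table, truth_clean, truth_scab


def expected_random_f1(n_true: int, n_test: int, n_pairs: int) -> float:
    """Expected F1 of a uniformly random test network against the truth.

    With k test edges drawn uniformly among N pairs and m true edges, the
    expected overlap is km/N, giving E[F1] ~= 2km / (N (m + k)).
    """
    if n_true == 0 or n_test == 0:
        return 0.0
    return 2 * n_true * n_test / (n_pairs * (n_true + n_test))
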