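"""Bootstrap reproducibility and network-agreement metrics.

Without a gold-standard microbiome network, an inference method is judged by
how stable its output is under resampling: the full-data network serves as
the reference, each of n_boot bootstrap replicates (rows resampled with
replacement, original sample size) is re-inferred independently, and every
replicate network is scored against the reference by F1 and Jaccard on edge
sets.  The replicate F1 distribution is summarised by its median, standard
deviation and 95% percentile confidence interval (theta*_0.025,
theta*_0.975).  These measure reproducibility, not biological accuracy.

Replicate r draws its resample from an independent RNG stream seeded with
seed + r, so different methods/normalisations can share identical resamples
for paired comparison.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .abundance_io import AbundanceTable, UndirectedNetwork

__all__ = [
    "AgreementScore",
    "BootstrapResult",
    "score_agreement",
    "bootstrap_resample",
    "bootstrap_stability",
    "pairwise_normalization_similarity",
    "compare_method_f1",
]

Inferrer = Callable[[AbundanceTable], UndirectedNetwork]


@dataclass
class AgreementScore:
    """Edge-set overlap between a reference and a test network."""

    precision: float
    recall: float
    f1: float
    jaccard: float
    reference_size: int
    test_size: int


@dataclass
class BootstrapResult:
    replicate_scores: list[AgreementScore]
    median_f1: float
    sd_f1: float
    ci_f1: tuple[float, float]

    @property
    def f1_values(self) -> np.ndarray:
        return np.array([s.f1 for s in self.replicate_scores])


def score_agreement(
    reference: UndirectedNetwork, test: UndirectedNetwork
) -> AgreementScore:
    """Precision/recall/F1 and Jaccard between two edge sets.

    Convention: two empty networks agree perfectly (all metrics 1); one
    empty and one not gives 0.
    """
    if set(reference.node_ids) != set(test.node_ids):
        raise ValueError("reference and test networks have different node sets")
    ref, tst = reference.edges, test.edges
    if not ref and not tst:
        return AgreementScore(1.0, 1.0, 1.0, 1.0, 0, 0)
    tp = len(ref & tst)
    precision = tp / len(tst) if tst else 0.0
    recall = tp / len(ref) if ref else 0.0
    f1 = (
        2 * precision * recall / (precision + recall)
        if precision + recall > 0
        else 0.0
    )
    jaccard = tp / len(ref | tst)
    return AgreementScore(precision, recall, f1, jaccard, len(ref), len(tst))


def bootstrap_resample(table: AbundanceTable, seed: int) -> AbundanceTable:
    """One bootstrap replicate: rows resampled with replacement, same n."""
    rng = np.random.default_rng(seed)
    rows = rng.integers(0, table.n_samples, size=table.n_samples)
    return table.subset_samples(rows)


def bootstrap_stability(
    table: AbundanceTable,
    inferrer: Inferrer,
    n_boot: int = 50,
    seed: int = 0,
) -> BootstrapResult:
    """Score n_boot re-inferred bootstrap networks against the full-data one."""
    if n_boot < 2:
        raise ValueError("n_boot must be >= 2")
    reference = inferrer(table)
    scores = []
    for r in range(n_boot):
        replicate = bootstrap_resample(table, seed + r)
        net = inferrer(replicate)
        # node sets can differ if the inferrer drops constant taxa on a
        # degenerate resample; score on the shared universe
        net = UndirectedNetwork(list(reference.node_ids), net.edges)
        scores.append(score_agreement(reference, net))
    f1 = np.array([s.f1 for s in scores])
    lo, hi = np.quantile(f1, [0.025, 0.975])
    return BootstrapResult(
        replicate_scores=scores,
        median_f1=float(np.median(f1)),
        sd_f1=float(np.std(f1, ddof=1)),
        ci_f1=(float(lo), float(hi)),
    )


def pairwise_normalization_similarity(
    table: AbundanceTable,
    inferrers: dict[str, Inferrer],
    n_boot: int = 50,
    seed: int = 0,
) -> dict[tuple[str, str], tuple[float, float]]:
    """Median and sd of per-replicate F1 between every pair of normalisations.

    ``inferrers`` maps a normalisation name to an inferrer that applies that
    normalisation internally.  The identical bootstrap resamples (streams
    seed+r) are reused for all methods so the comparison is paired: for each
    replicate, each method's network is inferred from the same resampled
    rows, and each method pair is scored on that replicate.
    """
    methods = list(inferrers)
    if len(methods) < 2:
        raise ValueError("need at least 2 normalization methods to compare")
    per_pair: dict[tuple[str, str], list[float]] = {
        (methods[i], methods[j]): []
        for i in range(len(methods))
        for j in range(i + 1, len(methods))
    }
    for r in range(n_boot):
        replicate = bootstrap_resample(table, seed + r)
        nets = {m: inferrers[m](replicate) for m in methods}
        for (a, b), acc in per_pair.items():
            na = UndirectedNetwork(list(nets[a].node_ids), nets[a].edges)
            nb = UndirectedNetwork(list(nets[a].node_ids), nets[b].edges)
            acc.append(score_agreement(na, nb).f1)
    return {
        pair: (float(np.median(v)), float(np.std(v, ddof=1)))
        for pair, v in per_pair.items()
    }


def compare_method_f1(
    distributions: dict[str, list[float]], adjust: str = "holm"
) -> dict[tuple[str, str], tuple[float, float]]:
    """Paired Wilcoxon signed-rank comparison of per-method F1 distributions.

    Returns, per method pair, (median(A) - median(B), adjusted two-sided
    p-value).  The Holm adjustment is the default; identical paired lists
    (all differences zero) get p = 1 by convention.
    """
    names = list(distributions)
    lengths = {len(v) for v in distributions.values()}
    if len(lengths) != 1:
        raise ValueError("all F1 score lists must have the same length (paired)")
    pairs, raw_p, med_diff = [], [], []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            a = np.asarray(distributions[names[i]], dtype=float)
            b = np.asarray(distributions[names[j]], dtype=float)
            pairs.append((names[i], names[j]))
            med_diff.append(float(np.median(a) - np.median(b)))
            if np.all(a == b):
                raw_p.append(1.0)
            else:
                raw_p.append(float(stats.wilcoxon(a, b).pvalue))
    if len(raw_p) > 1:
        adj = multipletests(raw_p, method=adjust)[1]
    else:
        adj = raw_p
    return {
        pair: (d, float(p)) for pair, d, p in zip(pairs, med_diff, adj)
    }
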