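"""Sample-wise normalisation transforms for count tables.

Four transforms commonly applied to microbiome counts before network
inference or learning: elementwise log, centred log-ratio (CLR), total sum
scaling (TSS), and GMPR (geometric mean of pairwise ratios) size-factor
scaling.  Raw counts without transformation produce unstable MI/CMI
estimates, so inference defaults to the log transform; CLR additionally
addresses compositionality, TSS converts to relative abundances, and GMPR
is a zero-robust alternative to library-size scaling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .abundance_io import AbundanceTable

__all__ = [
    "NormalizedTable",
    "NORMALIZATION_METHODS",
    "normalize",
    "default_pipeline",
    "gmpr_size_factors",
]

NORMALIZATION_METHODS = ("log", "clr", "tss", "gmpr", "none")


@dataclass
class NormalizedTable:
    """Transformed samples x taxa matrix, keeping the source identifiers."""

    values: np.ndarray
    taxon_ids: list[str]
    sample_ids: list[str]
    method: str
    pseudocount: float = 1.0
    labels: np.ndarray | None = None

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_taxa(self) -> int:
        return self.values.shape[1]


def gmpr_size_factors(counts: np.ndarray) -> np.ndarray:
    """GMPR size factor per sample.

    For sample i, take the median of pairwise count ratios c_ik/c_jk against
    each other sample j, restricted to taxa nonzero in both; the size factor
    is the geometric mean of these medians over all partners j != i.  A
    sample sharing no nonzero taxon with any other sample has no defined
    factor and raises.
    """
    counts = np.asarray(counts, dtype=float)
    n = counts.shape[0]
    if n < 2:
        raise ValueError("GMPR needs at least two samples")
    factors = np.empty(n)
    nz = counts > 0
    for i in range(n):
        log_medians = []
        for j in range(n):
            if j == i:
                continue
            shared = nz[i] & nz[j]
            if not shared.any():
                continue
            log_medians.append(
                np.median(np.log(counts[i, shared]) - np.log(counts[j, shared]))
            )
        if not log_medians:
            raise ValueError(
                f"GMPR undefined: sample index {i} shares no nonzero taxon "
                "with any other sample"
            )
        factors[i] = np.exp(np.mean(log_medians))
    return factors


def normalize(
    table: AbundanceTable, method: str, pseudocount: float = 1.0
) -> NormalizedTable:
    """Apply one of the supported transforms sample-wise.

    log:  log(count + pseudocount)
    clr:  log(count + pseudocount) minus its per-sample mean
    tss:  counts divided by the sample total (rows sum to 1)
    gmpr: counts divided by the sample's GMPR size factor
    none: passthrough
    """
    if method not in NORMALIZATION_METHODS:
        raise ValueError(f"unknown normalization method {method!r}")
    c = table.counts
    if method in ("log", "clr"):
        if pseudocount <= 0 and (c == 0).any():
            raise ValueError(f"{method} needs a positive pseudocount when zeros present")
        logs = np.log(c + pseudocount)
        values = logs if method == "log" else logs - logs.mean(axis=1, keepdims=True)
    elif method == "tss":
        totals = c.sum(axis=1)
        if (totals == 0).any():
            i = int(np.argwhere(totals == 0)[0][0])
            raise ValueError(f"TSS undefined for all-zero sample {table.sample_ids[i]!r}")
        values = c / totals[:, None]
    elif method == "gmpr":
        values = c / gmpr_size_factors(c)[:, None]
    else:  # none
        values = c.copy()
    return NormalizedTable(
        values,
        list(table.taxon_ids),
        list(table.sample_ids),
        method,
        pseudocount,
        table.labels,
    )


def default_pipeline(table: AbundanceTable, quantitative: bool = True,
                     pseudocount: float = 1.0) -> NormalizedTable:
    """Default preprocessing in front of network inference.

    With ``quantitative=True`` counts are log-transformed (the inference
    default); with ``quantitative=False`` the values pass through unchanged,
    for callers supplying externally normalised data (e.g. CLR).
    """
    if quantitative:
        return normalize(table, "log", pseudocount)
    return normalize(table, "none", pseudocount)
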