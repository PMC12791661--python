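"""Reading, validating, filtering, and writing abundance tables and networks.

Abundance tables are delimited text (TSV/CSV by extension) with a header row
and identifiers in the first column.  Networks are exchanged either as
two-column edge lists or as labelled, symmetric 0/1 adjacency matrices; the
adjacency form is the entry point for binarised exports of external inference
tools (SparCC, SPIEC-EASI, SPRING) fed into consensus building.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "AbundanceTable",
    "UndirectedNetwork",
    "canonical_edge",
    "read_abundance",
    "filter_prevalence",
    "write_network",
    "read_network",
    "read_adjacency",
]


def canonical_edge(a: str, b: str) -> tuple[str, str]:
    """Canonical (lexicographically sorted) key for an undirected edge.

    Every module stores and compares edges under this key so that edge sets
    from different sources are directly comparable.
    """
    if a == b:
        raise ValueError(f"self-loop edge ({a!r}, {a!r}) is not allowed")
    return (a, b) if a < b else (b, a)


def _check_unique(ids, what: str) -> None:
    seen: dict[str, int] = {}
    for i, x in enumerate(ids):
        if x in seen:
            raise ValueError(f"duplicate {what} id {x!r} (positions {seen[x]} and {i})")
        seen[x] = i


@dataclass
class AbundanceTable:
    """Samples x taxa count matrix with identifiers and optional 0/1 labels.

    ``counts`` holds nonnegative numbers (raw read counts in the typical
    case); ``labels``, when present, marks each sample as healthy (0) or
    diseased (1).
    """

    counts: np.ndarray
    taxon_ids: list[str]
    sample_ids: list[str]
    labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        self.taxon_ids = [str(t) for t in self.taxon_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        if self.counts.ndim != 2:
            raise ValueError("counts must be a 2-D matrix (samples x taxa)")
        n, p = self.counts.shape
        if n != len(self.sample_ids) or p != len(self.taxon_ids):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.taxon_ids)} taxa"
            )
        _check_unique(self.taxon_ids, "taxon")
        _check_unique(self.sample_ids, "sample")
        if not np.all(np.isfinite(self.counts)):
            raise ValueError("counts contain non-finite entries")
        if np.any(self.counts < 0):
            i, j = np.argwhere(self.counts < 0)[0]
            raise ValueError(
                f"negative count at sample {self.sample_ids[i]!r}, "
                f"taxon {self.taxon_ids[j]!r}"
            )
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=int)
            if self.labels.shape != (n,):
                raise ValueError("labels length must equal the number of samples")
            if not np.all(np.isin(self.labels, (0, 1))):
                raise ValueError("labels must be 0 (healthy) or 1 (diseased)")

    @property
    def n_samples(self) -> int:
        return self.counts.shape[0]

    @property
    def n_taxa(self) -> int:
        return self.counts.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.sample_ids, columns=self.taxon_ids)

    def subset_taxa(self, taxa: list[str]) -> "AbundanceTable":
        idx = [self.taxon_ids.index(t) for t in taxa]
        return AbundanceTable(
            self.counts[:, idx], list(taxa), list(self.sample_ids), self.labels
        )

    def subset_samples(self, rows: np.ndarray) -> "AbundanceTable":
        """Row subset/resample; duplicate rows get suffixed sample ids."""
        rows = np.asarray(rows, dtype=int)
        ids, seen = [], {}
        for r in rows:
            base = self.sample_ids[r]
            k = seen.get(base, 0)
            seen[base] = k + 1
            ids.append(base if k == 0 else f"{base}.{k}")
        labels = None if self.labels is None else self.labels[rows]
        return AbundanceTable(self.counts[rows], list(self.taxon_ids), ids, labels)


@dataclass
class UndirectedNetwork:
    """Node set plus a symmetric, unsigned binary edge relation.

    This is the "skeleton" output of every inference method in the package:
    no self-loops, no orientation, edges stored under :func:`canonical_edge`.
    """

    node_ids: list[str]
    edges: set[tuple[str, str]] = field(default_factory=set)

    def __post_init__(self) -> None:
        self.node_ids = [str(n) for n in self.node_ids]
        _check_unique(self.node_ids, "node")
        nodes = set(self.node_ids)
        canon = set()
        for a, b in self.edges:
            e = canonical_edge(a, b)
            if e[0] not in nodes or e[1] not in nodes:
                raise ValueError(f"edge {e} has endpoint outside the node set")
            canon.add(e)
        self.edges = canon

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def has_edge(self, a: str, b: str) -> bool:
        return canonical_edge(a, b) in self.edges

    def adjacency(self) -> pd.DataFrame:
        a = pd.DataFrame(
            0, index=self.node_ids, columns=self.node_ids, dtype=int
        )
        for i, j in self.edges:
            a.loc[i, j] = 1
            a.loc[j, i] = 1
        return a


def _read_delimited(path: str) -> pd.DataFrame:
    sep = "," if str(path).lower().endswith(".csv") else "\t"
    with open(path) as fh:
        header = fh.readline().rstrip("\r\n").split(sep)[1:]
    _check_unique(header, "header column")  # pandas silently mangles duplicates
    return pd.read_csv(path, sep=sep, index_col=0)


def read_abundance(path: str, orientation: str = "samples_as_rows") -> AbundanceTable:
    """Read a delimited abundance table, normalising to samples x taxa.

    Parameters
    ----------
    path:
        TSV (default) or CSV file; header row, first column = identifiers.
    orientation:
        ``"samples_as_rows"`` or ``"taxa_as_rows"``; the latter is transposed
        on read so downstream code always sees samples as rows.
    """
    if orientation not in ("samples_as_rows", "taxa_as_rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    df = _read_delimited(path)
    if orientation == "taxa_as_rows":
        df = df.T
    # locate non-numeric cells before coercing so the error can name them
    numeric = df.apply(pd.to_numeric, errors="coerce")
    if numeric.isna().any().any():
        bad = np.argwhere(numeric.isna().to_numpy())[0]
        raise ValueError(
            f"non-numeric value at row {df.index[bad[0]]!r}, "
            f"column {df.columns[bad[1]]!r} in {path}"
        )
    return AbundanceTable(
        numeric.to_numpy(dtype=float),
        taxon_ids=[str(c) for c in df.columns],
        sample_ids=[str(r) for r in df.index],
    )


def filter_prevalence(table: AbundanceTable, min_samples: int = 15) -> AbundanceTable:
    """Keep taxa with a nonzero count in at least ``min_samples`` samples.

    "Appearing" in a sample means count > 0.  The default of 15 samples is
    the prevalence floor used for the soil OTU tables this package targets;
    it removes rare taxa that carry little statistical signal.
    """
    if min_samples < 1:
        raise ValueError("min_samples must be >= 1")
    prevalence = (table.counts > 0).sum(axis=0)
    keep = prevalence >= min_samples
    if not keep.any():
        raise ValueError(
            f"no taxon appears in >= {min_samples} samples; lower the threshold"
        )
    taxa = [t for t, k in zip(table.taxon_ids, keep) if k]
    return AbundanceTable(
        table.counts[:, keep], taxa, list(table.sample_ids), table.labels
    )


def write_network(net: UndirectedNetwork, path: str, format: str = "edge_list") -> None:
    """Write a network as an edge-list TSV or a labelled 0/1 adjacency TSV."""
    if format == "edge_list":
        rows = sorted(net.edges)
        pd.DataFrame(rows, columns=["node_a", "node_b"]).to_csv(
            path, sep="\t", index=False
        )
    elif format == "adjacency_matrix":
        net.adjacency().to_csv(path, sep="\t")
    else:
        raise ValueError(f"unknown network format {format!r}")


def read_network(path: str, node_ids: list[str] | None = None) -> UndirectedNetwork:
    """Read an edge-list TSV (columns node_a, node_b[, weight])."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"edge list {path} needs at least two columns")
    edges = {canonical_edge(a, b) for a, b in zip(df.iloc[:, 0], df.iloc[:, 1])}
    if node_ids is None:
        node_ids = sorted({n for e in edges for n in e})
    return UndirectedNetwork(node_ids, edges)


def read_adjacency(path: str) -> UndirectedNetwork:
    """Read a labelled adjacency matrix; nonzero off-diagonal entries are edges.

    Asymmetric input is symmetrised by logical OR with a warning — all edges
    in this package are undirected and unsigned.  The diagonal is ignored.
    """
    df = _read_delimited(path)
    if df.shape[0] != df.shape[1]:
        raise ValueError(f"adjacency in {path} is not square: {df.shape}")
    rows = [str(r) for r in df.index]
    cols = [str(c) for c in df.columns]
    if rows != cols:
        raise ValueError(f"adjacency row labels do not match column labels in {path}")
    a = df.to_numpy(dtype=float) != 0
    np.fill_diagonal(a, False)
    if not np.array_equal(a, a.T):
        warnings.warn(
            f"asymmetric adjacency in {path}; symmetrising by logical OR",
            stacklevel=2,
        )
        a = a | a.T
    edges = {
        canonical_edge(rows[i], rows[j]) for i, j in zip(*np.nonzero(np.triu(a, 1)))
    }
    return UndirectedNetwork(rows, edges)
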