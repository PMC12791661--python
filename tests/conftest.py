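import numpy as np
import pytest

from micronet import AbundanceTable, UndirectedNetwork, canonical_edge


def random_network(node_ids, density, rng) -> UndirectedNetwork:
    """Erdos-Renyi network on the given nodes."""
    edges = set()
    for i in range(len(node_ids)):
        for j in range(i + 1, len(node_ids)):
            if rng.random() < density:
                edges.add(canonical_edge(node_ids[i], node_ids[j]))
    return UndirectedNetwork(list(node_ids), edges)


def random_table(n, p, seed, zero_frac=0.3) -> AbundanceTable:
    """Overdispersed zero-rich count table with no built-in structure."""
    rng = np.random.default_rng(seed)
    counts = rng.negative_binomial(1, 0.05, size=(n, p)).astype(float)
    counts[rng.random((n, p)) < zero_frac] = 0
    # guard against constant columns, which inference drops
    counts[0] += np.arange(p) + 1
    return AbundanceTable(
        counts, [f"t{j:02d}" for j in range(p)], [f"s{i:03d}" for i in range(n)]
    )


@pytest.fixture
def small_table():
    return random_table(60, 8, seed=42)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
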