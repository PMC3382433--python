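from __future__ import annotations

import numpy as np
import networkx as nx
import pytest

try:
    from hypothesis import settings

    settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
    settings.load_profile("ci")
except ImportError:  # pragma: no cover
    pass


def random_graph(n: int, p: float, seed: int) -> nx.Graph:
    """Erdos-Renyi graph with string vertex labels (zero-padded for a
    stable lexicographic order)."""
    rng = np.random.default_rng(seed)
    labels = [f"v{i:02d}" for i in range(n)]
    g = nx.Graph()
    g.add_nodes_from(labels)
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < p:
                g.add_edge(labels[i], labels[j])
    return g


def random_partition(genes: list[str], n_parts: int, rng) -> list[frozenset[str]]:
    labels = rng.integers(0, n_parts, size=len(genes))
    groups: dict[int, set[str]] = {}
    for g, lab in zip(genes, labels):
        groups.setdefault(int(lab), set()).add(g)
    return [frozenset(v) for _, v in sorted(groups.items())]


@pytest.fixture(scope="session")
def worked_fixture():
    from cliqueclust.synthetic import small_worked_fixture

    return small_worked_fixture()
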