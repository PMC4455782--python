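import sys
from pathlib import Path

import networkx as nx
import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from hicdecon.contacts import ContactGraph
from hicdecon.contigs_io import Contig


def make_contig(cid: str, length: int = 10_000, sites=(), sequence=None) -> Contig:
    return Contig(id=cid, length=length, site_positions=tuple(sites), sequence=sequence)


def make_graph(edges, lengths=None, site_counts=None) -> ContactGraph:
    """Build a ContactGraph from (u, v, weight[, raw]) tuples."""
    g = nx.Graph()
    nodes = {n for e in edges for n in e[:2]}
    for n in sorted(nodes):
        g.add_node(n,
                   length=(lengths or {}).get(n, 10_000),
                   site_count=(site_counts or {}).get(n, 1))
    for e in edges:
        u, v, w = e[0], e[1], e[2]
        raw = e[3] if len(e) > 3 else max(1, int(round(w)))
        g.add_edge(u, v, weight=float(w), raw_links=int(raw))
    return ContactGraph(graph=g)


def random_weighted_graph(rng: np.random.Generator, max_nodes: int = 30) -> ContactGraph:
    n = int(rng.integers(4, max_nodes + 1))
    p = rng.uniform(0.15, 0.6)
    edges = []
    names = [f"n{i:02d}" for i in range(n)]
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < p:
                edges.append((names[i], names[j], float(rng.uniform(0.05, 1.0)),
                              int(rng.integers(1, 20))))
    if not edges:  # ensure at least one edge
        edges.append((names[0], names[1], 0.5, 1))
    return make_graph(edges)


@pytest.fixture
def rng():
    return np.random.default_rng(20240501)
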