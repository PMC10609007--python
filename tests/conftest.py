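"""Shared fixtures and independent oracles for the test suite.

The oracles here deliberately use naive exhaustive algorithms (BFS path
enumeration for betweenness, full set-partition search for modularity) so
they share no code path with the implementations they check.
"""

from __future__ import annotations

import itertools
import warnings

import networkx as nx
import numpy as np
import pytest

import sparccnet as sn


@pytest.fixture(autouse=True)
def _quiet_small_n_warnings():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        warnings.simplefilter("ignore", RuntimeWarning)
        yield


@pytest.fixture
def tiny_table():
    """2 taxa x 2 samples with counts [[1, 2], [3, 4]]."""
    return sn.CountTable(
        taxa=[sn.TaxonLabel.parse("f_A; g_a"), sn.TaxonLabel.parse("f_B; g_b")],
        samples=["s1", "s2"],
        counts=np.array([[1, 2], [3, 4]]),
    )


# ---------------------------------------------------------------- oracles
def brute_betweenness(g: nx.Graph) -> dict:
    """Exhaustive shortest-path enumeration betweenness (unordered pairs)."""

    def all_shortest_paths(s, t):
        # BFS distances from s, then enumerate paths along the distance DAG
        dist = {s: 0}
        frontier = [s]
        while frontier:
            nxt = []
            for u in frontier:
                for v in g.neighbors(u):
                    if v not in dist:
                        dist[v] = dist[u] + 1
                        nxt.append(v)
            frontier = nxt
        if t not in dist:
            return []
        paths = []

        def extend(path):
            u = path[-1]
            if u == t:
                paths.append(list(path))
                return
            for v in g.neighbors(u):
                if dist.get(v) == dist[u] + 1 and dist[v] <= dist[t]:
                    extend(path + [v])

        extend([s])
        return [p for p in paths if len(p) - 1 == dist[t]]

    b = {v: 0.0 for v in g.nodes}
    nodes = list(g.nodes)
    for i, s in enumerate(nodes):
        for t in nodes[i + 1:]:
            paths = all_shortest_paths(s, t)
            if not paths:
                continue
            for p in paths:
                for v in p[1:-1]:
                    b[v] += 1.0 / len(paths)
    return b


def modularity_q(g: nx.Graph, partition: list[set]) -> float:
    """Q = (1/2m) sum_ij [A_ij − k_i k_j / 2m] delta(c_i, c_j), unweighted."""
    m = g.number_of_edges()
    if m == 0:
        return 0.0
    deg = dict(g.degree())
    q = 0.0
    for comm in partition:
        inside = sum(1 for a, b in g.edges if a in comm and b in comm)
        dc = sum(deg[v] for v in comm)
        q += inside / m - (dc / (2 * m)) ** 2
    return q


def set_partitions(items: list):
    """All partitions of ``items`` (restricted growth strings)."""
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in set_partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [[first] + part[i]] + part[i + 1:]
        yield [[first]] + part


def brute_max_modularity(g: nx.Graph) -> tuple[float, list[list], bool]:
    """Exhaustive modularity maximum; also reports whether it is unique."""
    best_q, best_p, n_best = -np.inf, None, 0
    for part in set_partitions(list(g.nodes)):
        q = modularity_q(g, [set(c) for c in part])
        if q > best_q + 1e-12:
            best_q, best_p, n_best = q, part, 1
        elif abs(q - best_q) <= 1e-12:
            n_best += 1
    return best_q, best_p, n_best == 1


def random_graph(rng: np.random.Generator, n_max: int = 7) -> nx.Graph:
    """A random connected-ish small graph with string node labels."""
    n = int(rng.integers(3, n_max + 1))
    p = float(rng.uniform(0.3, 0.8))
    g = nx.Graph()
    g.add_nodes_from(f"n{i}" for i in range(n))
    for i, j in itertools.combinations(range(n), 2):
        if rng.random() < p:
            g.add_edge(f"n{i}", f"n{j}")
    return g
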