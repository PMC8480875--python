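"""Shared fixtures and independent oracles for the test suite."""

import networkx as nx
import numpy as np
import pytest

import methylnet as mn


@pytest.fixture
def chain():
    return nx.DiGraph([("a", "b"), ("b", "c")])


@pytest.fixture
def out_star():
    return nx.DiGraph([("hub", f"leaf{k}") for k in range(5)])


@pytest.fixture
def cycle():
    return nx.DiGraph([(k, (k + 1) % 5) for k in range(5)])


@pytest.fixture(scope="session")
def small_cohort():
    """A modest synthetic cohort reused by several slower tests."""
    return mn.generate_cohort(20, 200, edge_density=0.08, seed=3)


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def reach_by_boolean_powers(graph: nx.DiGraph, m: int) -> dict:
    """m-reach via boolean adjacency-matrix powers (brute force)."""
    nodes = list(graph.nodes)
    n = len(nodes)
    A = nx.to_numpy_array(graph, nodelist=nodes, dtype=bool)
    reach = np.zeros((n, n), dtype=bool)
    P = np.eye(n, dtype=bool)
    for _ in range(m):
        P = P @ A
        reach |= P
    np.fill_diagonal(reach, False)
    return {v: reach[k].sum() / (n - 1) for k, v in enumerate(nodes)}


def grc_by_boolean_powers(graph: nx.DiGraph, m: int) -> float:
    r = np.array(list(reach_by_boolean_powers(graph, m).values()))
    return float(np.sum(r.max() - r) / (len(r) - 1))


def max_matching_by_enumeration(edges) -> int:
    """Maximum matching size of a directed link set, by exhaustive search.

    Link u->v occupies the out-copy of u and the in-copy of v; a matching is a
    link subset where no two links share an out-copy or an in-copy.
    """
    edges = list(edges)

    def best(idx, used_out, used_in):
        if idx == len(edges):
            return 0
        u, v = edges[idx]
        score = best(idx + 1, used_out, used_in)      # skip this link
        if u not in used_out and v not in used_in:
            score = max(score, 1 + best(idx + 1, used_out | {u}, used_in | {v}))
        return score

    return best(0, frozenset(), frozenset())


def control_centrality_by_enumeration(graph: nx.DiGraph, node) -> int:
    reachable = {node} | nx.descendants(graph, node)
    edges = [(u, v) for u, v in graph.edges if u in reachable and v in reachable]
    edges.append(("__src__", node))
    return max_matching_by_enumeration(edges)


def effective_beta_by_walks(network: mn.SignedNetwork, source, l_max) -> dict:
    """Walk sums by explicit recursive enumeration of all walks."""
    out_links = {}
    for _, row in network.to_edgelist().iterrows():
        out_links.setdefault(row["source"], []).append((row["target"],
                                                        row["beta"]))
    acc = {v: 0.0 for v in network.nodes}

    def walk(node, product, length):
        if length == l_max:
            return
        for nxt, b in out_links.get(node, ()):
            acc[nxt] += product * b
            walk(nxt, product * b, length + 1)

    walk(str(source), 1.0, 0)
    return acc


def random_digraph(rng, n_max=8, p=0.3) -> nx.DiGraph:
    n = int(rng.integers(2, n_max + 1))
    g = nx.DiGraph()
    g.add_nodes_from(range(n))
    for i in range(n):
        for j in range(n):
            if i != j and rng.random() < p:
                g.add_edge(i, j)
    return g
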