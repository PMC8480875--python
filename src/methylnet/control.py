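"""Structural-control analysis via maximum matching on reachable subgraphs.

The control centrality ``C(i)`` of node ``i`` is the maximum number of nodes a
single external signal injected at ``i`` can drive.  Following structural
controllability, link weights are irrelevant (all non-zero weights are treated
as 1) and ``C(i)`` is combinatorial: take the subgraph reachable from ``i``,
attach an external source ``s -> i``, map links to a bipartite graph
(out-copies vs in-copies) and count the links of a maximum matching.  The
external link is matchable, so ``C(i) >= 1`` — every node at least controls
itself.  Relative control centrality is ``c(i) = C(i) / N`` with ``N`` the full
network size, and the threshold-sweep average ``<c>(i)`` ranks nodes across an
ensemble of sparsifications rather than a single graph.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.sparse.csgraph import maximum_bipartite_matching

from .network import SignedNetwork, _as_digraph

__all__ = [
    "reachable_subgraph",
    "control_centrality",
    "all_control_centralities",
    "control_analysis",
    "sweep_averaged_control",
    "ControlResult",
]


def reachable_subgraph(graph, i) -> nx.DiGraph:
    """Induced subgraph on ``i`` and everything reachable from it."""
    g = _as_digraph(graph)
    if i not in g:
        raise KeyError(f"node {i!r} not in graph")
    nodes = {i} | nx.descendants(g, i)
    return g.subgraph(nodes).copy()


def _matching_size(edges, nodes) -> int:
    """Maximum bipartite matching size of the directed link set (Hopcroft-Karp
    complexity class via scipy's augmenting-path matcher)."""
    pos = {v: k for k, v in enumerate(nodes)}
    rows = [pos[u] for u, v in edges]
    cols = [pos[v] for u, v in edges]
    n = len(nodes)
    biadj = sp.csr_matrix((np.ones(len(edges)), (rows, cols)), shape=(n, n))
    match = maximum_bipartite_matching(biadj, perm_type="column")
    return int(np.sum(match >= 0))


def control_centrality(graph, i, *, include_external: bool = True) -> int:
    """Number of nodes drivable by an external signal at ``i``.

    With ``include_external=True`` (default) the auxiliary link ``s -> i``
    participates in the matching, so an isolated node scores 1 (it controls
    itself) and a chain head scores the full chain length.  The exclusive
    variant matches on the reachable subgraph alone.
    """
    sub = reachable_subgraph(graph, i)
    edges = list(sub.edges())
    nodes = list(sub.nodes())
    if include_external:
        source = ("__external_source__", i)
        edges.append((source, i))
        nodes.append(source)
    return _matching_size(edges, nodes)


def all_control_centralities(graph, *, include_external: bool = True) -> pd.Series:
    g = _as_digraph(graph)
    return pd.Series(
        {v: control_centrality(g, v, include_external=include_external)
         for v in g.nodes}, dtype=int)


@dataclass
class ControlResult:
    """Absolute, relative and sweep-averaged control centralities."""

    control_centrality: pd.Series          # C(i), counts
    relative: pd.Series                    # c(i) = C(i)/N
    averaged: pd.Series | None = None      # <c>(i) over the threshold sweep
    sweep_thresholds: np.ndarray | None = None

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame({"C": self.control_centrality, "c": self.relative})
        if self.averaged is not None:
            df["c_avg"] = self.averaged
        return df


def control_analysis(graph, *, n_total: int | None = None,
                     include_external: bool = True) -> ControlResult:
    """Absolute and relative control centrality of every node of one graph.

    ``n_total`` is the N used for normalisation (defaults to the graph size);
    the full-network N should be passed when analysing a thresholded graph.
    """
    c_abs = all_control_centralities(graph, include_external=include_external)
    n = n_total if n_total is not None else len(c_abs)
    return ControlResult(c_abs, c_abs.astype(float) / n)


def sweep_averaged_control(network: SignedNetwork, w_lo: float = 0.04,
                           w_hi: float = 0.1, n_thresholds: int = 60,
                           *, include_external: bool = True):
    """Average relative control centrality over a weight-threshold sweep.

    ``n_thresholds`` evenly spaced thresholds in ``[w_lo, w_hi]`` are applied
    to the (unthresholded) network; ``<c>(i)`` is the mean of ``c(i)`` across
    the resulting graphs.  All N nodes stay in every thresholded graph, so a
    node isolated by some threshold contributes ``c = 1/N`` there (it controls
    only itself).  Returns ``(averaged, thresholds)``.
    """
    if n_thresholds < 1:
        raise ValueError("need at least one threshold")
    if n_thresholds > 1 and not w_lo < w_hi:
        raise ValueError("need w_lo < w_hi")
    thresholds = (np.array([float(w_lo)]) if n_thresholds == 1
                  else np.linspace(w_lo, w_hi, n_thresholds))
    n = network.n_nodes
    acc = pd.Series(0.0, index=pd.Index(network.nodes))
    any_links = False
    for w_star in thresholds:
        sub = network.thresholded(float(w_star))
        any_links = any_links or sub.n_links > 0
        c_abs = all_control_centralities(sub.to_networkx(),
                                         include_external=include_external)
        acc += c_abs.astype(float) / n
    if not any_links:
        raise ValueError("every threshold in the sweep empties the network")
    return acc / len(thresholds), thresholds
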