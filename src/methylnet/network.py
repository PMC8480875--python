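"""Signed methylation-network inference and efficiency-based sparsification.

Each CpG's methylation level is modelled as a sparse linear combination of all
other CpGs, ``m_j = sum_{i != j} beta_ji m_i + beta_0``, fitted per response
node by cross-validated Lasso regression.  Non-zero coefficients define a
directed link ``i -> j`` with sign ``beta_ji`` and weight ``w_ij = |beta_ji|``.
The dense raw graph is sparsified by a weight threshold ``w*`` chosen to
maximise the efficiency quality function ``J = (E_g + E_l) / rho_L``, where
``E_g`` / ``E_l`` are global and local network efficiency and ``rho_L`` is the
link density.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.linear_model import LassoCV
from sklearn.model_selection import KFold

from .io_clock import MethylationMatrix

__all__ = [
    "SignedNetwork",
    "ThresholdScan",
    "fit_node_lasso",
    "build_network",
    "global_efficiency",
    "local_efficiency",
    "quality_J",
    "scan_thresholds",
    "make_fold_assignment",
]


class SignedNetwork:
    """Directed graph of signed regression coefficients between CpGs.

    ``beta`` is an (N, N) sparse matrix with ``beta[j, i]`` the coefficient of
    predictor ``i`` in the model for response ``j`` (link ``i -> j``).  Link
    weights are ``w_ij = |beta_ji]``; the diagonal is structurally zero (no
    self-links).
    """

    def __init__(self, nodes, beta, intercepts=None, threshold_applied=None):
        self.nodes = list(map(str, nodes))
        n = len(self.nodes)
        beta = sp.csr_matrix(beta, shape=(n, n), dtype=float)
        if beta.diagonal().any():
            raise ValueError("self-links are not allowed (non-zero diagonal)")
        beta.eliminate_zeros()
        self.beta = beta
        self.intercepts = (np.zeros(n) if intercepts is None
                           else np.asarray(intercepts, dtype=float))
        self.threshold_applied = threshold_applied
        if threshold_applied is not None and self.n_links:
            if np.abs(self.beta.data).min() < threshold_applied:
                raise ValueError("stored link weaker than threshold_applied")

    # -- basic quantities --------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_links(self) -> int:
        return int(self.beta.nnz)

    @property
    def link_density(self) -> float:
        n = self.n_nodes
        return self.n_links / (n * (n - 1)) if n > 1 else 0.0

    @property
    def mean_total_degree(self) -> float:
        """Mean in+out degree, <k> = 2 L / N."""
        return 2.0 * self.n_links / self.n_nodes if self.n_nodes else 0.0

    @property
    def weights(self) -> np.ndarray:
        """Link weights |beta| in CSR data order."""
        return np.abs(self.beta.data)

    def thresholded(self, w_star: float) -> "SignedNetwork":
        """Keep links with ``|beta| >= w_star``; signs are retained."""
        beta = self.beta.copy()
        beta.data[np.abs(beta.data) < w_star] = 0.0
        beta.eliminate_zeros()
        return SignedNetwork(self.nodes, beta, self.intercepts, w_star)

    def to_networkx(self) -> nx.DiGraph:
        """Directed graph with all N nodes; edge attrs ``beta`` and ``weight``."""
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        coo = self.beta.tocoo()
        for j, i, b in zip(coo.row, coo.col, coo.data):
            g.add_edge(self.nodes[i], self.nodes[j], beta=float(b),
                       weight=abs(float(b)))
        return g

    def to_edgelist(self) -> pd.DataFrame:
        coo = self.beta.tocoo()
        return pd.DataFrame({
            "source": [self.nodes[i] for i in coo.col],
            "target": [self.nodes[j] for j in coo.row],
            "beta": coo.data,
            "weight": np.abs(coo.data),
        }).sort_values(["source", "target"], ignore_index=True)

    @classmethod
    def from_edgelist(cls, df: pd.DataFrame, nodes=None,
                      threshold_applied=None) -> "SignedNetwork":
        if nodes is None:
            nodes = sorted(set(df["source"]).union(df["target"]))
        nodes = list(map(str, nodes))
        pos = {n: k for k, n in enumerate(nodes)}
        rows = [pos[str(t)] for t in df["target"]]
        cols = [pos[str(s)] for s in df["source"]]
        beta = sp.coo_matrix((df["beta"].to_numpy(float), (rows, cols)),
                             shape=(len(nodes), len(nodes)))
        return cls(nodes, beta, threshold_applied=threshold_applied)

    def write_edgelist(self, path, *, sidecar: bool = True) -> None:
        """Write edges as TSV; a JSON sidecar (``<path>.meta.json``) keeps the
        full node universe (isolated nodes included) and the threshold."""
        self.to_edgelist().to_csv(path, sep="\t", index=False,
                                  float_format="%.17g")
        if sidecar:
            import json

            meta = {"nodes": self.nodes,
                    "threshold_applied": self.threshold_applied}
            with open(f"{path}.meta.json", "wt", encoding="utf-8") as fh:
                json.dump(meta, fh)

    @classmethod
    def read_edgelist(cls, path, nodes=None) -> "SignedNetwork":
        import json
        import os

        threshold = None
        meta_path = f"{path}.meta.json"
        if os.path.exists(meta_path):
            with open(meta_path, "rt", encoding="utf-8") as fh:
                meta = json.load(fh)
            if nodes is None:
                nodes = meta.get("nodes")
            threshold = meta.get("threshold_applied")
        return cls.from_edgelist(
            pd.read_csv(path, sep="\t", float_precision="round_trip"),
            nodes=nodes, threshold_applied=threshold)

    def __repr__(self):
        thr = (f", w*={self.threshold_applied:g}"
               if self.threshold_applied is not None else "")
        return f"<SignedNetwork N={self.n_nodes} L={self.n_links}{thr}>"


# ---------------------------------------------------------------------------
# per-node Lasso regression
# ---------------------------------------------------------------------------

def make_fold_assignment(n_samples: int, n_folds: int, seed: int) -> np.ndarray:
    """Seeded per-sample fold labels (a shuffled balanced K-fold split)."""
    rng = np.random.default_rng(seed)
    folds = np.repeat(np.arange(n_folds), -(-n_samples // n_folds))[:n_samples]
    rng.shuffle(folds)
    return folds


def _cv_splits(fold_assignment):
    labels = np.unique(fold_assignment)
    idx = np.arange(len(fold_assignment))
    return [(idx[fold_assignment != f], idx[fold_assignment == f]) for f in labels]


def fit_node_lasso(response: str, matrix: MethylationMatrix, n_folds: int = 10,
                   seed: int = 0, *, fold_assignment=None, standardize=False,
                   eps: float = 1e-3, n_alphas: int = 100,
                   max_iter: int = 5000):
    """Cross-validated Lasso of one CpG on all the others.

    Returns ``(coefficients, intercept)`` where ``coefficients`` is a Series
    over the other CpG ids (most exactly zero for sparse truths).  The L1
    penalty is picked on a log-spaced grid spanning three decades below the
    data-driven maximum; folds come from ``fold_assignment`` (a per-sample
    label array) or a seeded shuffled K-fold split.
    """
    if response not in matrix.cpg_ids:
        raise KeyError(f"response CpG {response!r} not in matrix")
    if n_folds < 2:
        raise ValueError("need at least 2 folds")
    if matrix.n_samples < n_folds:
        raise ValueError(f"{matrix.n_samples} samples < {n_folds} folds")
    others = [c for c in matrix.cpg_ids if c != response]
    idx = pd.Index(matrix.cpg_ids)
    y = matrix.values[idx.get_loc(response)]
    X = matrix.values[idx.get_indexer(others)].T
    if np.std(y) == 0.0:
        warnings.warn(f"response {response!r} is constant; all coefficients zero")
        return pd.Series(0.0, index=others), float(y[0])
    if fold_assignment is None:
        fold_assignment = make_fold_assignment(matrix.n_samples, n_folds, seed)
    # an integer `alphas` requests a log grid of that many points spanning
    # `eps` decades below the data-driven alpha_max
    model = LassoCV(eps=eps, alphas=n_alphas, fit_intercept=True,
                    max_iter=max_iter, cv=_cv_splits(fold_assignment))
    if standardize:
        mu, sd = X.mean(axis=0), X.std(axis=0)
        sd[sd == 0] = 1.0
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model.fit((X - mu) / sd, y)
        coefs = model.coef_ / sd
        intercept = float(model.intercept_ - np.dot(coefs, mu))
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model.fit(X, y)
        coefs = model.coef_
        intercept = float(model.intercept_)
    return pd.Series(coefs, index=others), intercept


def build_network(matrix: MethylationMatrix, n_folds: int = 10, seed: int = 0,
                  *, standardize=False, progress=False) -> SignedNetwork:
    """Assemble the unthresholded signed network, one Lasso fit per response.

    A link ``i -> j`` is stored iff the fitted ``beta_ji`` is non-zero.  The
    CV fold assignment is drawn once from ``seed`` and shared across responses
    so the whole build is reproducible and sample-permutation invariant.
    """
    nodes = list(matrix.cpg_ids)
    pos = {c: k for k, c in enumerate(nodes)}
    folds = make_fold_assignment(matrix.n_samples, n_folds, seed)
    rows, cols, data = [], [], []
    intercepts = np.zeros(len(nodes))
    iterator = enumerate(nodes)
    if progress:
        from tqdm import tqdm  # pragma: no cover - cosmetic
        iterator = tqdm(list(iterator), desc="lasso")
    for j, response in iterator:
        coefs, b0 = fit_node_lasso(response, matrix, n_folds, seed,
                                   fold_assignment=folds, standardize=standardize)
        intercepts[j] = b0
        nz = coefs[coefs != 0.0]
        rows.extend([j] * len(nz))
        cols.extend(pos[c] for c in nz.index)
        data.extend(nz.to_numpy())
    beta = sp.coo_matrix((data, (rows, cols)), shape=(len(nodes), len(nodes)))
    return SignedNetwork(nodes, beta, intercepts)


# ---------------------------------------------------------------------------
# efficiency and threshold selection
# ---------------------------------------------------------------------------

def _as_digraph(graph) -> nx.DiGraph:
    if isinstance(graph, SignedNetwork):
        return graph.to_networkx()
    return graph


def global_efficiency(graph) -> float:
    """Mean inverse directed shortest-path length over ordered node pairs.

    Unreachable pairs contribute 0 (``1/inf``); paths are unweighted.
    """
    g = _as_digraph(graph)
    n = g.number_of_nodes()
    if n < 2:
        raise ValueError("global efficiency needs at least 2 nodes")
    total = 0.0
    for _, lengths in nx.all_pairs_shortest_path_length(g):
        total += sum(1.0 / d for d in lengths.values() if d > 0)
    return total / (n * (n - 1))


def local_efficiency(graph, *, neighbourhood: str = "all") -> float:
    """Mean over nodes of the global efficiency of each neighbour subgraph.

    The neighbour set of ``i`` is the union of in- and out-neighbours
    (``neighbourhood="out"`` restricts to successors); ``i`` itself is removed
    and subgraphs with fewer than 2 nodes contribute 0.
    """
    g = _as_digraph(graph)
    n = g.number_of_nodes()
    if n == 0:
        return 0.0
    total = 0.0
    for node in g:
        if neighbourhood == "all":
            nbrs = (set(g.predecessors(node)) | set(g.successors(node))) - {node}
        elif neighbourhood == "out":
            nbrs = set(g.successors(node)) - {node}
        else:
            raise ValueError(f"unknown neighbourhood mode {neighbourhood!r}")
        if len(nbrs) >= 2:
            total += global_efficiency(g.subgraph(nbrs))
    return total / n


def quality_J(graph) -> float:
    """Efficiency quality function ``J = (E_g + E_l) / rho_L``."""
    g = _as_digraph(graph)
    n, l = g.number_of_nodes(), g.number_of_edges()
    if n < 2:
        raise ValueError("quality function needs at least 2 nodes")
    rho = l / (n * (n - 1))
    if rho == 0:
        raise ValueError("threshold removed all links (rho_L = 0)")
    return (global_efficiency(g) + local_efficiency(g)) / rho


@dataclass
class ThresholdScan:
    """Efficiency scan over candidate weight thresholds ``w*``.

    ``J`` is NaN for candidates that empty the graph; the argmax is taken over
    the remaining candidates, ties broken toward the smaller (denser) ``w*``.
    """

    thresholds: np.ndarray
    J: np.ndarray
    E_g: np.ndarray
    E_l: np.ndarray
    rho_L: np.ndarray
    w_opt: float

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({"w_star": self.thresholds, "J": self.J,
                             "E_g": self.E_g, "E_l": self.E_l,
                             "rho_L": self.rho_L})

    def plot(self, ax=None):
        """J as a function of w*, with the optimum marked."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.thresholds, self.J, "-", lw=1.5)
        ax.axvline(self.w_opt, color="crimson", ls="--",
                   label=f"w* = {self.w_opt:.3g}")
        ax.set_xlabel("weight threshold w*")
        ax.set_ylabel("J = (E_g + E_l) / rho_L")
        ax.legend()
        return ax


def scan_thresholds(network: SignedNetwork, grid=None, *,
                    n_points: int = 200) -> ThresholdScan:
    """Scan candidate thresholds and locate the efficiency optimum.

    The default grid is ``n_points`` evenly spaced values between the smallest
    and largest observed link weight of the (unthresholded) network.
    """
    if network.n_links == 0:
        raise ValueError("cannot scan thresholds of an empty network")
    if grid is None:
        w = network.weights
        grid = np.linspace(w.min(), w.max(), n_points)
    grid = np.asarray(grid, dtype=float)
    if np.any(np.diff(grid) < 0):
        raise ValueError("threshold grid must be sorted ascending")
    J = np.full(len(grid), np.nan)
    Eg = np.full(len(grid), np.nan)
    El = np.full(len(grid), np.nan)
    rho = np.zeros(len(grid))
    for k, w_star in enumerate(grid):
        sub = network.thresholded(w_star)
        rho[k] = sub.link_density
        if sub.n_links == 0:
            continue
        g = sub.to_networkx()
        Eg[k] = global_efficiency(g)
        El[k] = local_efficiency(g)
        J[k] = (Eg[k] + El[k]) / rho[k]
    if np.all(np.isnan(J)):
        raise ValueError("every candidate threshold empties the network")
    best = int(np.nanargmax(J))  # first max -> smallest w* on ties
    return ThresholdScan(grid, J, Eg, El, rho, float(grid[best]))
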