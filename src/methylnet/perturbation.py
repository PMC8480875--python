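"""Propagation of single-CpG perturbations and their effect on clock age.

A change ``delta_m`` at CpG ``i`` propagates along the signed links: the first
neighbours shift by ``beta_ji * delta_m``, second neighbours by products of two
coefficients, and so on up to chains of length ``l_max``.  Collecting walk
terms yields an *effective* coefficient ``sum_{l=1}^{l_max} (B^l)_{ji}``, and
in the linear (adult) branch of the clock the age response is::

    da/dm_i = (a_t + 1) * [H_i + sum_j H_j * effective_beta_ji]
    delta_a = da/dm_i * delta_m,   delta_m = 2 <sigma(m)>

where ``<sigma(m)>`` is the mean per-CpG standard deviation of the cohort.
The displacement of a sample in methylation space and its angle with the clock
vector ``H`` characterize how well a propagated perturbation aligns with the
cohort's natural direction of ageing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .io_clock import ClockModel, MethylationMatrix, mean_cpg_std
from .network import SignedNetwork

__all__ = [
    "effective_beta",
    "age_derivative",
    "delta_a",
    "perturb_all",
    "project_cloud",
    "displacement_geometry",
    "PerturbationResult",
    "ProjectionResult",
    "DisplacementResult",
]


def _node_index(network: SignedNetwork, i) -> int:
    try:
        return network.nodes.index(str(i))
    except ValueError:
        raise KeyError(f"node {i!r} not in network") from None


def effective_beta(network: SignedNetwork, i, l_max: int, *,
                   mode: str = "walks") -> pd.Series:
    """Effective influence coefficients of node ``i`` on every node ``j``.

    ``mode="walks"`` (default) sums products of signed coefficients over all
    walks of length 1..l_max, computed by repeated sparse matrix-vector
    products (``sum_l (B^l)_{ji}``); ``mode="simple-paths"`` restricts the sum
    to paths without repeated nodes, for sensitivity analysis.
    """
    if l_max < 1:
        raise ValueError("l_max must be >= 1 (use age_derivative for l_max=0)")
    k = _node_index(network, i)
    n = network.n_nodes
    if mode == "walks":
        B = network.beta.tocsr()
        v = np.zeros(n)
        v[k] = 1.0
        acc = np.zeros(n)
        for _ in range(l_max):
            v = B @ v
            acc += v
    elif mode == "simple-paths":
        coo = network.beta.tocoo()
        out_links: dict[int, list[tuple[int, float]]] = {}
        for j, s, b in zip(coo.row, coo.col, coo.data):
            out_links.setdefault(s, []).append((j, b))
        acc = np.zeros(n)

        def walk(node, product, depth, visited):
            for nxt, b in out_links.get(node, ()):
                if nxt in visited:
                    continue
                acc[nxt] += product * b
                if depth + 1 < l_max:
                    walk(nxt, product * b, depth + 1, visited | {nxt})

        walk(k, 1.0, 0, {k})
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return pd.Series(acc, index=pd.Index(network.nodes))


def age_derivative(network: SignedNetwork, clock: ClockModel, i,
                   l_max: int, *, mode: str = "walks") -> float:
    """Derivative of the clock age w.r.t. the methylation level of node ``i``.

    ``da/dm_i = (a_t + 1) * (H_i + sum_j H_j * effective_beta_ji)``; at
    ``l_max = 0`` this is the isolated-CpG response ``(a_t + 1) * H_i``.
    Assumes the linear (adult) branch of the clock.
    """
    h = clock.vector(network.nodes)
    k = _node_index(network, i)
    base = h[k]
    if l_max >= 1:
        eff = effective_beta(network, i, l_max, mode=mode).to_numpy()
        base = base + float(h @ eff)
    return (clock.adult_threshold + 1.0) * base


@dataclass
class PerturbationResult:
    """Age response of a single-CpG perturbation propagated to depth l_max."""

    node: str
    l_max: int
    derivative: float          # years per unit methylation
    delta_m: float             # applied perturbation, 2<sigma(m)>
    delta_a: float             # signed age change for +delta_m, years
    effective_beta: pd.Series | None = None

    @property
    def delta_a_abs(self) -> float:
        return abs(self.delta_a)

    @property
    def age_reducing_sign(self) -> float:
        """Sign of delta_m that decreases the estimated age."""
        return -float(np.sign(self.derivative)) if self.derivative else 0.0


def delta_a(network: SignedNetwork, clock: ClockModel,
            matrix: MethylationMatrix, i, l_max: int, *,
            mode: str = "walks") -> PerturbationResult:
    """Expected age change when node ``i`` shifts by ``2<sigma(m)>``."""
    dm = 2.0 * mean_cpg_std(matrix)
    deriv = age_derivative(network, clock, i, l_max, mode=mode)
    eff = (effective_beta(network, i, l_max, mode=mode) if l_max >= 1 else None)
    return PerturbationResult(str(i), l_max, deriv, dm, deriv * dm, eff)


def perturb_all(network: SignedNetwork, clock: ClockModel,
                matrix: MethylationMatrix, l_max: int = 4, *,
                mode: str = "walks") -> pd.DataFrame:
    """Perturbation summary for every node.

    Columns: derivative, delta_a (signed), delta_a_abs, plus the displacement
    angles with H at l_max = 0 and at the requested l_max.
    """
    dm = 2.0 * mean_cpg_std(matrix)
    h = clock.vector(network.nodes)
    a_t1 = clock.adult_threshold + 1.0
    rows = {}
    for k, node in enumerate(network.nodes):
        eff = (effective_beta(network, node, l_max).to_numpy()
               if l_max >= 1 else np.zeros(network.n_nodes))
        deriv = a_t1 * (h[k] + float(h @ eff))
        disp = eff * dm
        disp[k] += dm
        disp0 = np.zeros_like(disp)
        disp0[k] = dm
        rows[node] = {
            "derivative": deriv,
            "delta_a": deriv * dm,
            "delta_a_abs": abs(deriv * dm),
            "angle_l0": _angle_with(disp0, h),
            f"angle_l{l_max}": _angle_with(disp, h),
        }
    return pd.DataFrame.from_dict(rows, orient="index")


# ---------------------------------------------------------------------------
# methylation-space geometry
# ---------------------------------------------------------------------------

@dataclass
class ProjectionResult:
    """Sample cloud coordinates relative to the clock direction ``H``.

    ``along`` is the component of each sample vector along ``H/|H|``;
    ``perp_distance`` is the distance of its perpendicular part from the centre
    of mass of all perpendicular parts.
    """

    along: pd.Series
    perp_distance: pd.Series
    h_unit: np.ndarray
    cpg_ids: list

    def plot(self, ages=None, ax=None):
        """Scatter of the sample cloud (along-H vs perpendicular distance)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        sc = ax.scatter(self.along, self.perp_distance, c=ages, s=12,
                        cmap="viridis")
        if ages is not None:
            plt.colorbar(sc, ax=ax, label="age [years]")
        ax.set_xlabel("component along H")
        ax.set_ylabel("perpendicular distance d(q)")
        return ax


def project_cloud(matrix: MethylationMatrix, clock: ClockModel) -> ProjectionResult:
    """Project every sample onto the clock direction and its orthogonal plane."""
    h = clock.vector(matrix.cpg_ids)
    norm = np.linalg.norm(h)
    if norm == 0:
        raise ValueError("clock vector H is zero")
    h_unit = h / norm
    m = matrix.values  # (n_cpgs, n_samples)
    along = h_unit @ m
    perp = m - np.outer(h_unit, along)
    centre = perp.mean(axis=1, keepdims=True)
    d = np.linalg.norm(perp - centre, axis=0)
    return ProjectionResult(pd.Series(along, index=matrix.sample_ids),
                            pd.Series(d, index=matrix.sample_ids),
                            h_unit, list(matrix.cpg_ids))


def _angle_with(vec: np.ndarray, h: np.ndarray) -> float:
    nv, nh = np.linalg.norm(vec), np.linalg.norm(h)
    if nv == 0 or nh == 0:
        return np.nan
    cos = np.clip(vec @ h / (nv * nh), -1.0, 1.0)
    return float(np.arccos(cos))


@dataclass
class DisplacementResult:
    """Methylation-space displacement of a propagated perturbation."""

    node: str
    l_max: int
    vector: pd.Series
    length: float
    angle: float               # radians with H; NaN if displacement is zero
    degenerate: bool

    def __repr__(self):
        a = "undefined" if self.degenerate else f"{np.degrees(self.angle):.1f} deg"
        return (f"<DisplacementResult {self.node} l_max={self.l_max} "
                f"|d|={self.length:.3g} angle={a}>")


def displacement_geometry(network: SignedNetwork, clock: ClockModel,
                          matrix: MethylationMatrix, i, l_max: int, *,
                          mode: str = "walks") -> DisplacementResult:
    """Displacement vector of a perturbation at ``i`` and its angle with H.

    The vector holds ``delta_m`` at coordinate ``i`` plus
    ``effective_beta_ji * delta_m`` at every downstream ``j`` (only coordinate
    ``i`` at ``l_max = 0``).
    """
    dm = 2.0 * mean_cpg_std(matrix)
    k = _node_index(network, i)
    disp = np.zeros(network.n_nodes)
    if l_max >= 1:
        disp = effective_beta(network, i, l_max, mode=mode).to_numpy() * dm
    disp[k] += dm
    h = clock.vector(network.nodes)
    length = float(np.linalg.norm(disp))
    angle = _angle_with(disp, h)
    degenerate = length == 0.0
    if degenerate:
        warnings.warn(f"zero displacement for node {i!r}; angle undefined")
    return DisplacementResult(str(i), l_max,
                              pd.Series(disp, index=pd.Index(network.nodes)),
                              length, angle, degenerate)
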