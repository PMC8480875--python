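"""Model/Results facade tying the analysis stages together.

:class:`MethylationNetworkModel` is built from a cohort (a beta matrix plus,
optionally, a clock) and ``fit()`` performs the per-node Lasso-CV network
inference and efficiency-based sparsification.  The returned
:class:`MethylationNetworkResults` carries the inferred signed network and
threshold scan, and exposes the downstream analyses — hierarchy, structural
control, perturbation propagation and the top-k ranking — as methods, plus a
``summary()`` table.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import control as _control
from . import hierarchy as _hierarchy
from . import network as _network
from . import perturbation as _perturbation
from .io_clock import ClockModel, MethylationMatrix

__all__ = ["MethylationNetworkModel", "MethylationNetworkResults"]


class MethylationNetworkModel:
    """Methylation-network model of a CpG cohort.

    Parameters
    ----------
    matrix : MethylationMatrix
        Beta values, CpGs by samples.
    clock : ClockModel, optional
        Clock coefficients; required only for the perturbation analyses.
    """

    def __init__(self, matrix: MethylationMatrix, clock: ClockModel | None = None):
        self.matrix = matrix
        self.clock = clock

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, ages=None,
                       clock: ClockModel | None = None):
        return cls(MethylationMatrix.from_dataframe(df, ages), clock)

    def fit(self, folds: int = 10, seed: int = 0, threshold="auto", *,
            grid=None, grid_points: int = 200,
            standardize: bool = False) -> "MethylationNetworkResults":
        """Infer the signed network and sparsify it.

        ``threshold`` is ``"auto"`` (efficiency-optimal ``w*`` from a grid
        scan), a number (fixed ``w*``), or ``None`` (no sparsification).
        """
        full = _network.build_network(self.matrix, folds, seed,
                                      standardize=standardize)
        scan = None
        if threshold == "auto":
            if full.n_links == 0:
                import warnings

                warnings.warn("inferred network is empty; skipping the "
                              "threshold scan")
                w_star = None
            else:
                scan = _network.scan_thresholds(full, grid, n_points=grid_points)
                w_star = scan.w_opt
        elif threshold is None:
            w_star = None
        else:
            w_star = float(threshold)
        net = full if w_star is None else full.thresholded(w_star)
        return MethylationNetworkResults(self, full, net, w_star, scan,
                                         folds=folds, seed=seed)


class MethylationNetworkResults:
    """Fitted methylation network with the downstream analyses attached."""

    def __init__(self, model, network_full, network, w_star, scan, *,
                 folds, seed):
        self.model = model
        self.network_full = network_full     # pre-threshold
        self.network = network               # post-threshold (working graph)
        self.w_star = w_star
        self.scan = scan
        self.folds = folds
        self.seed = seed

    # -- analyses ----------------------------------------------------------
    def hierarchy(self, m: int = 3, *, null_samples: int = 0,
                  swaps_per_link: int = 10, seed: int = 0):
        """m-reach, GRC, levels and (optionally) the randomized null."""
        return _hierarchy.hierarchy_analysis(
            self.network, m, null_samples=null_samples,
            swaps_per_link=swaps_per_link, seed=seed)

    def control(self, *, sweep=(0.04, 0.1, 60), include_external=True):
        """Control centrality on the thresholded network, plus sweep average."""
        res = _control.control_analysis(
            self.network.to_networkx(), n_total=self.network.n_nodes,
            include_external=include_external)
        if sweep is not None:
            w_lo, w_hi, n_thr = sweep
            res.averaged, res.sweep_thresholds = _control.sweep_averaged_control(
                self.network_full, w_lo, w_hi, n_thr,
                include_external=include_external)
        return res

    def perturbation(self, l_max: int = 4) -> pd.DataFrame:
        """Per-node age derivatives, delta_a and displacement angles."""
        if self.model.clock is None:
            raise ValueError("perturbation analysis needs a clock")
        return _perturbation.perturb_all(self.network, self.model.clock,
                                         self.model.matrix, l_max)

    def ranking(self, k: int = 20, *, m: int = 3, sweep=(0.04, 0.1, 60),
                l_max: int = 4):
        """Top-k ranking table by |delta_a|, m-reach and averaged control."""
        from .pipeline import ranking_table

        pert = self.perturbation(l_max)
        reach = _hierarchy.all_reaches(self.network.to_networkx(), m)
        ctrl = self.control(sweep=sweep)
        c_avg = ctrl.averaged if ctrl.averaged is not None else ctrl.relative
        return ranking_table(pert["delta_a_abs"], reach, c_avg, k)

    # -- presentation ------------------------------------------------------
    def summary(self) -> str:
        full, net = self.network_full, self.network
        lines = [
            "Methylation network results",
            "=" * 43,
            f"{'CpGs (nodes)':<30}{full.n_nodes:>13}",
            f"{'Samples':<30}{self.model.matrix.n_samples:>13}",
            f"{'CV folds / seed':<30}{f'{self.folds} / {self.seed}':>13}",
            f"{'Links before threshold':<30}{full.n_links:>13}",
            f"{'Mean total degree <k>':<30}{full.mean_total_degree:>13.2f}",
        ]
        if self.w_star is not None:
            lines += [
                f"{'Weight threshold w*':<30}{self.w_star:>13.4g}",
                f"{'Links after threshold':<30}{net.n_links:>13}",
                f"{'Link density rho_L':<30}{net.link_density:>13.4g}",
            ]
        if self.scan is not None:
            j_best = float(np.nanmax(self.scan.J))
            lines.append(f"{'Efficiency J at optimum':<30}{j_best:>13.4g}")
        lines.append("=" * 43)
        return "\n".join(lines)

    def __repr__(self):
        return (f"<MethylationNetworkResults N={self.network.n_nodes} "
                f"L={self.network.n_links} w*={self.w_star}>")
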