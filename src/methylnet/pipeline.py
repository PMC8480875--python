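"""End-to-end orchestration: full runs, top-k ranking, mixed-hierarchy test.

``run_full`` executes infer -> threshold -> hierarchy (+null) -> control
(+sweep) -> perturbation -> ranking on a cohort and returns (and optionally
writes) every stage's output plus a summary, including the Pearson correlation
between sweep-averaged control centrality and m-reach.  The mixed-hierarchy
experiment checks how well the hierarchy position of a set of seed CpGs is
conserved when they are embedded in networks built with randomly drawn
companion CpGs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from . import hierarchy as _hierarchy
from .io_clock import ClockModel, MethylationMatrix
from .model import MethylationNetworkModel

__all__ = [
    "ranking_table",
    "RankingTable",
    "run_full",
    "mixed_hierarchy_experiment",
    "MixedHierarchyResult",
]


@dataclass
class RankingTable:
    """Top-k lists by |delta_a|, m-reach and averaged control centrality."""

    table: pd.DataFrame            # all nodes, scores + top-k membership flags
    k: int
    top: dict                      # criterion -> list of node ids (len k)
    overlaps: dict                 # (criterion, criterion) -> overlap count

    def union_table(self) -> pd.DataFrame:
        """Rows restricted to nodes in any top-k list, sorted by |delta_a|."""
        mask = self.table[[c for c in self.table.columns
                           if c.startswith("top_")]].any(axis=1)
        return (self.table[mask]
                .sort_values("delta_a_abs", ascending=False))


def _top_k(scores: pd.Series, k: int) -> list:
    """Top-k ids, descending score, ties broken by ascending id."""
    df = pd.DataFrame({"score": scores})
    df["id"] = df.index.astype(str)
    df = df.sort_values(["score", "id"], ascending=[False, True],
                        kind="stable")
    return list(df.index[:k])


def ranking_table(delta_a_abs, reach, c_avg, k: int) -> RankingTable:
    """Rank nodes by the three criteria and count pairwise top-k overlaps."""
    scores = {
        "delta_a_abs": pd.Series(delta_a_abs, dtype=float),
        "reach": pd.Series(reach, dtype=float),
        "c_avg": pd.Series(c_avg, dtype=float),
    }
    base = set(scores["delta_a_abs"].index)
    for name, s in scores.items():
        if set(s.index) != base:
            raise ValueError(f"node set of {name!r} differs from |delta_a|'s")
    if k > len(base):
        raise ValueError(f"k={k} exceeds the {len(base)} available nodes")
    index = scores["delta_a_abs"].index
    table = pd.DataFrame({n: s.reindex(index) for n, s in scores.items()})
    top = {name: _top_k(s, k) for name, s in scores.items()}
    for name, ids in top.items():
        table[f"top_{name}"] = table.index.isin(ids)
    names = list(scores)
    overlaps = {(a, b): len(set(top[a]) & set(top[b]))
                for i, a in enumerate(names) for b in names[i + 1:]}
    return RankingTable(table, k, top, overlaps)


def run_full(matrix: MethylationMatrix, clock: ClockModel | None = None, *,
             folds: int = 10, seed: int = 0, threshold="auto",
             grid_points: int = 200, m: int = 3, null_samples: int = 1000,
             swaps_per_link: int = 10, sweep=(0.04, 0.1, 60), l_max: int = 4,
             top_k: int = 20, outdir=None) -> dict:
    """Run the complete analysis and collect every stage's output.

    Returns a bundle with the fitted results object, hierarchy, control,
    perturbation table, ranking and a JSON-serialisable ``summary`` (which
    includes the Pearson correlation between ``<c>`` and ``r_m``).  When
    ``outdir`` is given all tables are written as TSV and the summary and
    manifest as JSON.
    """
    results = MethylationNetworkModel(matrix, clock).fit(
        folds=folds, seed=seed, threshold=threshold, grid_points=grid_points)
    # a near-empty graph cannot be link-randomized; report hierarchy without null
    null_n = null_samples if results.network.n_links >= 2 else 0
    hier = results.hierarchy(m, null_samples=null_n,
                             swaps_per_link=swaps_per_link, seed=seed)
    try:
        ctrl = results.control(sweep=sweep)
    except ValueError:          # every sweep threshold empties the network
        ctrl = results.control(sweep=None)
    c_for_rank = ctrl.averaged if ctrl.averaged is not None else ctrl.relative
    pert = results.perturbation(l_max) if clock is not None else None

    with np.errstate(all="ignore"):
        import warnings as _warnings

        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore")
            try:
                r_cr = stats.pearsonr(c_for_rank.reindex(hier.reach.index),
                                      hier.reach)
                pearson_cr = float(r_cr.statistic)
            except Exception:
                pearson_cr = float("nan")
    summary = {
        "n_cpgs": matrix.n_cpgs,
        "n_samples": matrix.n_samples,
        "links_pre_threshold": results.network_full.n_links,
        "mean_total_degree_pre": results.network_full.mean_total_degree,
        "w_star": results.w_star,
        "links_post_threshold": results.network.n_links,
        "m": m,
        "grc": hier.grc,
        "grc_null_mean": None if hier.null is None else hier.null.mean,
        "grc_null_sd": None if hier.null is None else hier.null.sd,
        "grc_z": None if hier.null is None else hier.null.z_score,
        "grc_p": None if hier.null is None else hier.null.p_value,
        "pearson_c_avg_reach": pearson_cr,
        "l_max": l_max,
    }
    ranking = None
    if pert is not None:
        # mean |delta_a| at l_max and at 0 (the latter from the clock alone)
        from .io_clock import mean_cpg_std

        dm = 2.0 * mean_cpg_std(matrix)
        h = clock.vector(results.network.nodes)
        summary["mean_abs_delta_a_l0"] = float(
            np.mean(np.abs((clock.adult_threshold + 1.0) * h * dm)))
        summary["mean_abs_delta_a_lmax"] = float(pert["delta_a_abs"].mean())
        summary["max_abs_delta_a_lmax"] = float(pert["delta_a_abs"].max())
        angle_cols = [c for c in pert.columns if c.startswith("angle_l")
                      and c != "angle_l0"]
        if angle_cols and l_max > 0:
            better = pert[angle_cols[0]] < pert["angle_l0"]
            summary["angle_improved_fraction"] = float(better.mean())
            summary["angle_improved_count"] = int(better.sum())
        ranking = ranking_table(pert["delta_a_abs"], hier.reach,
                                c_for_rank, min(top_k, matrix.n_cpgs))
        summary["top_k"] = ranking.k
        summary["overlap_reach_c_avg"] = ranking.overlaps[("reach", "c_avg")]
        summary["overlap_delta_a_reach"] = ranking.overlaps[("delta_a_abs", "reach")]
        summary["overlap_delta_a_c_avg"] = ranking.overlaps[("delta_a_abs", "c_avg")]

    bundle = {"results": results, "hierarchy": hier, "control": ctrl,
              "perturbation": pert, "ranking": ranking, "summary": summary}

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        results.network_full.write_edgelist(outdir / "network_full.tsv")
        results.network.write_edgelist(outdir / "network_thresholded.tsv")
        if results.scan is not None:
            results.scan.to_dataframe().to_csv(outdir / "threshold_scan.tsv",
                                               sep="\t", index=False)
        hier.to_dataframe().to_csv(outdir / "hierarchy.tsv", sep="\t",
                                   index_label="cpg_id")
        ctrl.to_dataframe().to_csv(outdir / "control.tsv", sep="\t",
                                   index_label="cpg_id")
        if pert is not None:
            pert.to_csv(outdir / "perturbation.tsv", sep="\t",
                        index_label="cpg_id")
        if ranking is not None:
            ranking.table.to_csv(outdir / "ranking.tsv", sep="\t",
                                 index_label="cpg_id")
        manifest = {"folds": folds, "seed": seed, "threshold": str(threshold),
                    "grid_points": grid_points, "m": m,
                    "null_samples": null_samples,
                    "swaps_per_link": swaps_per_link,
                    "sweep": list(sweep) if sweep is not None else None,
                    "l_max": l_max, "top_k": top_k}
        (outdir / "manifest.json").write_text(
            json.dumps(manifest, sort_keys=True, indent=2))
        (outdir / "summary.json").write_text(
            json.dumps(summary, sort_keys=True, indent=2))
    return bundle


# ---------------------------------------------------------------------------
# mixed-hierarchy conservation experiment
# ---------------------------------------------------------------------------

@dataclass
class MixedHierarchyResult:
    """Positions of seed CpGs across hierarchies of mixed networks."""

    records: pd.DataFrame    # replicate, cpg_id, is_seed, reach, level, reach_percentile
    n_networks: int

    @property
    def seed_median_percentile(self) -> float:
        return float(self.records.loc[self.records["is_seed"],
                                      "reach_percentile"].median())

    def level_densities(self) -> pd.DataFrame:
        """Density of hierarchy levels for seed nodes vs all nodes."""
        out = {}
        for label, sub in (("all", self.records),
                           ("seed", self.records[self.records["is_seed"]])):
            counts = sub["level"].value_counts(normalize=True).sort_index()
            out[label] = counts
        return pd.DataFrame(out).fillna(0.0)


def mixed_hierarchy_experiment(seed_ids, pool_matrix: MethylationMatrix,
                               n_networks: int = 50,
                               network_size: int | None = None, *,
                               m: int = 3, folds: int = 10,
                               threshold="auto", grid_points: int = 50,
                               seed: int = 0) -> MixedHierarchyResult:
    """Re-embed seed CpGs among random companions and track their positions.

    For each replicate, ``network_size - len(seed_ids)`` CpGs are drawn without
    replacement from the pool (independently across replicates), the network is
    inferred and thresholded on the mixed set, and every node's reach, level
    and within-replicate reach percentile are recorded.
    """
    seed_ids = [str(s) for s in seed_ids]
    if network_size is None:
        network_size = pool_matrix.n_cpgs
    if network_size < len(seed_ids):
        raise ValueError("network_size smaller than the seed set")
    candidates = [c for c in pool_matrix.cpg_ids if c not in seed_ids]
    n_extra = network_size - len(seed_ids)
    if n_extra > len(candidates):
        raise ValueError(f"pool has only {len(candidates)} non-seed CpGs, "
                         f"need {n_extra}")
    rng = np.random.default_rng(seed)
    records = []
    for rep in range(n_networks):
        extra = list(rng.choice(candidates, size=n_extra, replace=False))
        sub = pool_matrix.subset_cpgs(seed_ids + extra)
        results = MethylationNetworkModel(sub).fit(
            folds=folds, seed=int(rng.integers(2**31)), threshold=threshold,
            grid_points=grid_points)
        hier = results.hierarchy(m)
        pct = hier.reach.rank(pct=True, method="average")
        for cpg in sub.cpg_ids:
            records.append({
                "replicate": rep, "cpg_id": cpg,
                "is_seed": cpg in seed_ids,
                "reach": float(hier.reach[cpg]),
                "level": int(hier.levels[cpg]),
                "reach_percentile": float(pct[cpg]),
            })
    return MixedHierarchyResult(pd.DataFrame.from_records(records), n_networks)
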