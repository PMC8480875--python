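"""Per-node Lasso inference, efficiency measures and threshold selection."""

import networkx as nx
import numpy as np
import pytest
import scipy.sparse as sp

import methylnet as mn
from methylnet.network import make_fold_assignment


def _matrix_from_values(values, prefix="cg"):
    n_cpgs, n_samples = values.shape
    return mn.MethylationMatrix(values, [f"{prefix}{k}" for k in range(n_cpgs)],
                                [f"s{q}" for q in range(n_samples)])


class TestFitNodeLasso:
    def test_single_true_predictor_recovered(self):
        rng = np.random.default_rng(5)
        n = 400
        x = rng.uniform(0.1, 0.9, n)
        noise = _matrix_from_values(rng.uniform(0.2, 0.8, (4, n)))
        y = 0.5 * x + 0.2 + rng.normal(0, 0.005, n)
        values = np.vstack([x, y, noise.values])
        matrix = _matrix_from_values(values)
        coefs, intercept = mn.fit_node_lasso("cg1", matrix, 10, seed=0)
        # oracle: OLS on the true single predictor gives ~0.5
        assert coefs["cg0"] == pytest.approx(0.5, abs=0.05)
        assert (coefs.drop("cg0").abs() < 0.01).all()

    def test_pure_noise_response_stays_near_empty(self):
        # null simulation: worst spurious coefficient across 20 seeds at
        # n = 600 is ~0.058 (CV picks a prediction-optimal, not a
        # selection-optimal penalty); frozen with a small margin
        worst = 0.0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            matrix = _matrix_from_values(rng.uniform(0.2, 0.8, (8, 600)))
            coefs, _ = mn.fit_node_lasso("cg0", matrix, 10, seed=seed)
            worst = max(worst, coefs.abs().max())
        assert worst < 0.06

    def test_sample_permutation_invariance_with_fixed_folds(self):
        rng = np.random.default_rng(2)
        matrix = _matrix_from_values(rng.uniform(0.2, 0.8, (6, 60)))
        folds = make_fold_assignment(60, 5, seed=0)
        ref, ref_b0 = mn.fit_node_lasso("cg0", matrix, 5,
                                        fold_assignment=folds)
        perm = rng.permutation(60)
        permuted = mn.MethylationMatrix(matrix.values[:, perm],
                                        matrix.cpg_ids,
                                        [matrix.sample_ids[p] for p in perm])
        got, got_b0 = mn.fit_node_lasso("cg0", permuted, 5,
                                        fold_assignment=folds[perm])
        assert np.allclose(ref.to_numpy(), got.to_numpy(), atol=1e-10)
        assert ref_b0 == pytest.approx(got_b0, abs=1e-10)

    def test_constant_response_warns_and_zeroes(self):
        rng = np.random.default_rng(3)
        values = rng.uniform(0.2, 0.8, (4, 40))
        values[2] = 0.5
        matrix = _matrix_from_values(values)
        with pytest.warns(UserWarning, match="constant"):
            coefs, b0 = mn.fit_node_lasso("cg2", matrix, 5)
        assert (coefs == 0).all()
        assert b0 == 0.5

    def test_unknown_response_rejected(self):
        matrix = _matrix_from_values(np.random.default_rng(0)
                                     .uniform(0.2, 0.8, (3, 30)))
        with pytest.raises(KeyError):
            mn.fit_node_lasso("cg99", matrix, 5)


class TestBuildNetwork:
    def test_independent_noise_gives_near_empty_network(self):
        rng = np.random.default_rng(11)
        matrix = _matrix_from_values(rng.uniform(0.2, 0.8, (3, 600)))
        net = mn.build_network(matrix, 10, seed=0)
        assert net.n_links == 0 or (net.weights < 0.05).all()

    def test_self_links_never_stored(self, small_cohort):
        net = mn.build_network(small_cohort.matrix, 5, seed=0)
        assert not net.beta.diagonal().any()
        assert net.nodes == small_cohort.matrix.cpg_ids

    def test_edgelist_round_trip(self, small_cohort, tmp_path):
        net = mn.build_network(small_cohort.matrix, 5, seed=0)
        path = tmp_path / "edges.tsv"
        net.write_edgelist(path)
        back = mn.SignedNetwork.read_edgelist(path, nodes=net.nodes)
        assert (back.beta != net.beta).nnz == 0


class TestEfficiency:
    def test_complete_digraph_has_unit_efficiencies_and_J_two(self):
        K = nx.complete_graph(5, nx.DiGraph)
        assert mn.global_efficiency(K) == 1.0
        assert mn.local_efficiency(K) == 1.0
        assert mn.quality_J(K) == 2.0

    def test_single_link_pair(self):
        g = nx.DiGraph([("a", "b")])
        assert mn.global_efficiency(g) == 0.5
        assert mn.quality_J(g) == pytest.approx(1.0)

    def test_empty_graph(self):
        g = nx.empty_graph(4, nx.DiGraph)
        assert mn.global_efficiency(g) == 0.0
        assert mn.local_efficiency(g) == 0.0
        with pytest.raises(ValueError, match="links"):
            mn.quality_J(g)

    def test_directed_triangle_local_efficiency_one(self):
        g = nx.complete_graph(3, nx.DiGraph)
        assert mn.local_efficiency(g) == 1.0

    def test_out_star_local_efficiency_zero(self, out_star):
        assert mn.local_efficiency(out_star) == 0.0

    def test_single_node_rejected(self):
        g = nx.empty_graph(1, nx.DiGraph)
        with pytest.raises(ValueError):
            mn.global_efficiency(g)


def _planted_toy_network():
    """4 strongly interconnected core nodes plus 8 weakly attached satellites."""
    core = [f"c{k}" for k in range(4)]
    sats = [f"s{k}" for k in range(8)]
    rows, cols, data = [], [], []
    nodes = core + sats
    pos = {n: k for k, n in enumerate(nodes)}
    for a in core:
        for b in core:
            if a != b:
                rows.append(pos[b]); cols.append(pos[a]); data.append(0.9)
    for k, s in enumerate(sats):
        src = core[k // 2]
        rows.append(pos[s]); cols.append(pos[src]); data.append(0.05)
    beta = sp.coo_matrix((data, (rows, cols)), shape=(12, 12))
    return mn.SignedNetwork(nodes, beta)


class TestThresholdScan:
    def test_noise_links_pruned_at_argmax(self):
        net = _planted_toy_network()
        scan = mn.scan_thresholds(net, grid=[0.01, 0.5])
        assert scan.w_opt == 0.5
        # hand values: thresholded graph = K4 core + 8 isolated satellites;
        # E_g = 12/132, each core's neighbour subgraph is the complete K3 so
        # E_l = 4/12, rho = 12/132 -> J = 1 + 11/3 = 14/3
        assert scan.J[1] == pytest.approx(14 / 3)
        # unthresholded: E_g = 32/132, E_l = 4*0.3/12, rho = 20/132
        assert scan.J[0] == pytest.approx((32 / 132 + 0.1) / (20 / 132))

    def test_single_candidate_is_argmax(self):
        net = _planted_toy_network()
        scan = mn.scan_thresholds(net, grid=[0.01])
        assert scan.w_opt == 0.01

    def test_emptying_grid_rejected(self):
        net = _planted_toy_network()
        with pytest.raises(ValueError, match="empt"):
            mn.scan_thresholds(net, grid=[5.0])

    def test_thresholding_is_monotone(self, small_cohort):
        net = mn.build_network(small_cohort.matrix, 5, seed=1)
        w = np.quantile(net.weights, [0.3, 0.7])
        links_lo = set(map(tuple, net.thresholded(w[0]).to_edgelist()
                           [["source", "target"]].itertuples(index=False)))
        links_hi = set(map(tuple, net.thresholded(w[1]).to_edgelist()
                           [["source", "target"]].itertuples(index=False)))
        assert links_hi <= links_lo

    def test_efficiencies_bounded(self, small_cohort):
        net = mn.build_network(small_cohort.matrix, 5, seed=1)
        scan = mn.scan_thresholds(net, n_points=25)
        ok = ~np.isnan(scan.J)
        assert ((scan.E_g[ok] >= 0) & (scan.E_g[ok] <= 1)).all()
        assert ((scan.E_l[ok] >= 0) & (scan.E_l[ok] <= 1)).all()
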