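"""Walk-sum propagation, age derivatives and methylation-space geometry."""

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

import methylnet as mn
from methylnet.perturbation import (age_derivative, delta_a,
                                    displacement_geometry, effective_beta,
                                    perturb_all, project_cloud)

from conftest import effective_beta_by_walks


def _net(nodes, links):
    pos = {n: k for k, n in enumerate(nodes)}
    rows = [pos[t] for _, t, _ in links]
    cols = [pos[s] for s, _, _ in links]
    data = [b for *_, b in links]
    return mn.SignedNetwork(nodes, sp.coo_matrix((data, (rows, cols)),
                                                 shape=(len(nodes),) * 2))


class TestEffectiveBeta:
    def test_single_link_only_one_walk(self):
        net = _net(["i", "j"], [("i", "j", 0.5)])
        eff = effective_beta(net, "i", 4)
        assert eff.to_dict() == {"i": 0.0, "j": 0.5}

    def test_chain_walks_multiply(self):
        net = _net(["i", "k", "j"], [("i", "k", 0.4), ("k", "j", 0.5)])
        eff = effective_beta(net, "i", 2)
        assert eff["k"] == pytest.approx(0.4)
        assert eff["j"] == pytest.approx(0.2)

    def test_two_cycle_accumulates_odd_walks(self):
        net = _net(["i", "j"], [("i", "j", 0.5), ("j", "i", 0.5)])
        eff = effective_beta(net, "i", 4)
        assert eff["j"] == pytest.approx(0.5 + 0.125)       # lengths 1 and 3
        assert eff["i"] == pytest.approx(0.25 + 0.0625)     # lengths 2 and 4

    def test_simple_path_mode_excludes_revisits(self):
        net = _net(["i", "j"], [("i", "j", 0.5), ("j", "i", 0.5)])
        eff = effective_beta(net, "i", 4, mode="simple-paths")
        assert eff["j"] == pytest.approx(0.5)
        assert eff["i"] == 0.0

    def test_modes_agree_on_dags(self):
        net = _net(["a", "b", "c", "d"],
                   [("a", "b", 0.3), ("b", "c", -0.5), ("a", "c", 0.2),
                    ("c", "d", 0.4)])
        walks = effective_beta(net, "a", 4)
        paths = effective_beta(net, "a", 4, mode="simple-paths")
        assert np.allclose(walks, paths)

    def test_lmax_zero_rejected(self):
        net = _net(["i", "j"], [("i", "j", 0.5)])
        with pytest.raises(ValueError):
            effective_beta(net, "i", 0)

    def test_matches_walk_enumeration_oracle(self):
        rng = np.random.default_rng(9)
        for _ in range(40):
            n = int(rng.integers(2, 7))
            nodes = [f"n{k}" for k in range(n)]
            links = [(nodes[i], nodes[j], float(rng.normal(0, 0.5)))
                     for i in range(n) for j in range(n)
                     if i != j and rng.random() < 0.35]
            if not links:
                continue
            net = _net(nodes, links)
            src = nodes[int(rng.integers(n))]
            l_max = int(rng.integers(1, 5))
            expected = effective_beta_by_walks(net, src, l_max)
            got = effective_beta(net, src, l_max)
            for v in nodes:
                assert got[v] == pytest.approx(expected[v], abs=1e-12)


class TestAgeDerivative:
    def test_empty_network_reduces_to_clock_coefficient(self):
        net = mn.SignedNetwork(["i", "j"], sp.csr_matrix((2, 2)))
        clock = mn.ClockModel({"i": 0.1, "j": 0.2}, 20.0)
        assert age_derivative(net, clock, "i", 0) == pytest.approx(2.1)
        assert age_derivative(net, clock, "i", 4) == pytest.approx(2.1)

    def test_first_neighbour_hand_value(self):
        net = _net(["i", "j"], [("i", "j", 0.5)])
        clock = mn.ClockModel({"i": 0.1, "j": 0.2}, 20.0)
        assert age_derivative(net, clock, "i", 1) == pytest.approx(4.2)

    def test_depth_one_dag_saturates(self):
        net = _net(["i", "j", "k"], [("i", "j", 0.5), ("i", "k", -0.2)])
        clock = mn.ClockModel({"i": 0.1, "j": 0.2, "k": 0.4}, 20.0)
        assert age_derivative(net, clock, "i", 1) == \
            pytest.approx(age_derivative(net, clock, "i", 4))

    def test_truncation_adds_exactly_the_next_walk_order(self):
        rng = np.random.default_rng(10)
        nodes = [f"n{k}" for k in range(5)]
        links = [(nodes[i], nodes[j], float(rng.normal(0, 0.4)))
                 for i in range(5) for j in range(5)
                 if i != j and rng.random() < 0.5]
        net = _net(nodes, links)
        clock = mn.ClockModel(dict(zip(nodes, rng.normal(0, 1, 5))), 20.0)
        B = net.beta.toarray()
        h = clock.vector(nodes)
        for l in range(1, 5):
            step = (age_derivative(net, clock, "n0", l)
                    - age_derivative(net, clock, "n0", l - 1))
            order_term = 21.0 * h @ np.linalg.matrix_power(B, l)[:, 0]
            assert step == pytest.approx(order_term, abs=1e-10)

    def test_missing_clock_coefficient_rejected(self):
        net = _net(["i", "j"], [("i", "j", 0.5)])
        clock = mn.ClockModel({"i": 0.1}, 20.0)
        with pytest.raises(KeyError, match="j"):
            age_derivative(net, clock, "i", 1)


class TestDeltaA:
    def _matrix(self, values):
        values = np.asarray(values, dtype=float)
        return mn.MethylationMatrix(values,
                                    ["i", "j"][: values.shape[0]],
                                    [f"s{q}" for q in range(values.shape[1])])

    def test_zero_variance_cohort_gives_zero_delta(self):
        net = _net(["i", "j"], [("i", "j", 0.5)])
        clock = mn.ClockModel({"i": 0.1, "j": 0.2}, 20.0)
        matrix = self._matrix(np.full((2, 4), 0.5))
        res = delta_a(net, clock, matrix, "i", 4)
        assert res.delta_a == 0.0

    def test_isolated_node_arithmetic(self):
        net = mn.SignedNetwork(["i", "j"], sp.csr_matrix((2, 2)))
        clock = mn.ClockModel({"i": 0.1, "j": 0.0001}, 20.0)
        matrix = self._matrix([[0.4, 0.5], [0.45, 0.55]])
        res = delta_a(net, clock, matrix, "i", 0)
        expected = 2.1 * 2.0 * mn.mean_cpg_std(matrix)
        assert res.delta_a_abs == pytest.approx(expected)

    def test_delta_a_linear_in_delta_m(self):
        net = _net(["i", "j"], [("i", "j", -0.7)])
        clock = mn.ClockModel({"i": 0.3, "j": 0.2}, 20.0)
        matrix = self._matrix([[0.4, 0.6], [0.2, 0.4]])
        res = delta_a(net, clock, matrix, "i", 3)
        assert res.delta_a == res.derivative * res.delta_m  # exact identity


class TestGeometry:
    def test_projection_hand_geometry(self):
        # H along the first axis; points (0.3, 0.4) and (0.3, 0.0)
        matrix = mn.MethylationMatrix([[0.3, 0.3], [0.4, 0.0]],
                                      ["a", "b"], ["s1", "s2"])
        clock = mn.ClockModel({"a": 1.0, "b": 0.0}, 20.0)
        pc = project_cloud(matrix, clock)
        assert np.allclose(pc.along, [0.3, 0.3])
        assert np.allclose(pc.perp_distance, [0.2, 0.2])

    def test_single_sample_is_its_own_centre(self):
        matrix = mn.MethylationMatrix([[0.3], [0.4]], ["a", "b"], ["s1"])
        clock = mn.ClockModel({"a": 1.0, "b": 2.0}, 20.0)
        pc = project_cloud(matrix, clock)
        assert pc.perp_distance["s1"] == 0.0

    def test_along_component_recovers_linear_branch_age(self, small_cohort):
        pc = project_cloud(small_cohort.matrix, small_cohort.clock)
        h_norm = np.linalg.norm(
            small_cohort.clock.vector(small_cohort.matrix.cpg_ids))
        ages = mn.horvath_ages(small_cohort.matrix, small_cohort.clock)
        linear = pc.along.to_numpy() * h_norm * 21.0 + 20.0
        adult = linear >= 20.0   # identity holds on the linear branch
        assert np.allclose(linear[adult], ages[adult])

    def test_aligned_perturbation_angle_zero(self):
        net = mn.SignedNetwork(["i", "j"], sp.csr_matrix((2, 2)))
        clock = mn.ClockModel({"i": 1.0, "j": 0.0}, 20.0)
        matrix = mn.MethylationMatrix([[0.4, 0.6], [0.2, 0.4]],
                                      ["i", "j"], ["s1", "s2"])
        res = displacement_geometry(net, clock, matrix, "i", 0)
        assert res.angle == pytest.approx(0.0)

    def test_orthogonal_perturbation_angle_right(self):
        net = mn.SignedNetwork(["i", "j"], sp.csr_matrix((2, 2)))
        clock = mn.ClockModel({"i": 0.0, "j": 1.0}, 20.0)
        matrix = mn.MethylationMatrix([[0.4, 0.6], [0.2, 0.4]],
                                      ["i", "j"], ["s1", "s2"])
        res = displacement_geometry(net, clock, matrix, "i", 0)
        assert res.angle == pytest.approx(np.pi / 2)

    def test_zero_displacement_flagged(self):
        net = mn.SignedNetwork(["i", "j"], sp.csr_matrix((2, 2)))
        clock = mn.ClockModel({"i": 1.0, "j": 0.0}, 20.0)
        matrix = mn.MethylationMatrix(np.full((2, 3), 0.5),
                                      ["i", "j"], ["s1", "s2", "s3"])
        with pytest.warns(UserWarning, match="zero displacement"):
            res = displacement_geometry(net, clock, matrix, "i", 0)
        assert res.degenerate and np.isnan(res.angle)


class TestPerturbAll:
    def test_table_consistent_with_single_node_calls(self):
        rng = np.random.default_rng(12)
        nodes = [f"n{k}" for k in range(4)]
        links = [("n0", "n1", 0.5), ("n1", "n2", -0.4), ("n2", "n3", 0.3)]
        net = _net(nodes, links)
        clock = mn.ClockModel(dict(zip(nodes, rng.normal(0, 0.5, 4))), 20.0)
        matrix = mn.MethylationMatrix(rng.uniform(0.2, 0.8, (4, 10)), nodes,
                                      [f"s{q}" for q in range(10)])
        table = perturb_all(net, clock, matrix, l_max=3)
        for node in nodes:
            single = delta_a(net, clock, matrix, node, 3)
            assert table.loc[node, "delta_a"] == pytest.approx(single.delta_a)
            geo = displacement_geometry(net, clock, matrix, node, 3)
            assert table.loc[node, "angle_l3"] == pytest.approx(geo.angle)
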