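import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import net_from_edges
from netpharm.synthetic_data import random_graph, scale_free_graph
from netpharm.topology import (average_clustering, betweenness,
                               bottleneck_scores, characteristic_path_length,
                               clustering_coefficient, degree_histogram,
                               fit_power_law, harmonic_closeness, summarize)
from oracles import (betweenness_oracle, bottleneck_oracle, clustering_oracle,
                     harmonic_closeness_oracle, ols_loglog_oracle,
                     path_length_oracle)


class TestDegreeHistogram:
    def test_triangle(self, triangle):
        assert degree_histogram(triangle) == [(2, 3)]

    def test_star(self, star5):
        assert degree_histogram(star5) == [(1, 4), (4, 1)]

    def test_matches_brute_force_tally_on_scale_free_graph(self):
        net = scale_free_graph(200, 2, seed=7)
        tally = {}
        for n in net.nodes:
            k = len(net.neighbors(n))
            if k:
                tally[k] = tally.get(k, 0) + 1
        assert degree_histogram(net) == sorted(tally.items())

    def test_total_count_is_non_isolated_nodes(self):
        net = random_graph(40, 0.1, seed=1)
        isolated = sum(1 for n in net.nodes if not net.neighbors(n))
        assert sum(c for _, c in degree_histogram(net)) == 40 - isolated


class TestPowerLawFit:
    def test_recovers_published_constants_from_noiseless_curve(self):
        pts = [(k, 258.52 * k ** -1.171) for k in range(1, 21)]
        fit = fit_power_law(pts)
        assert fit.exponent_b == pytest.approx(-1.171, abs=1e-6)
        assert fit.coefficient_a == pytest.approx(258.52, abs=1e-6)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-6)

    def test_constant_counts_fit_zero_slope(self):
        fit = fit_power_law([(k, 5.0) for k in range(1, 11)])
        assert fit.exponent_b == pytest.approx(0.0, abs=1e-12)
        assert fit.r_squared == 1.0  # horizontal data: perfect flat fit

    def test_matches_normal_equations_on_noisy_points(self):
        rng = np.random.default_rng(42)
        pts = [(k, float(10.0 * k ** -0.8 * math.exp(rng.normal(0, 0.2))))
               for k in range(1, 30)]
        fit = fit_power_law(pts)
        slope, intercept = ols_loglog_oracle(pts)
        assert fit.exponent_b == pytest.approx(slope, rel=1e-10)
        assert fit.coefficient_a == pytest.approx(10 ** intercept, rel=1e-10)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(a=st.floats(0.01, 1e4), b=st.floats(-3.0, 0.0))
    def test_noiseless_power_law_recovered_exactly(self, a, b):
        pts = [(k, a * k ** b) for k in (1, 2, 3, 5, 8, 13, 21)]
        fit = fit_power_law(pts)
        assert fit.exponent_b == pytest.approx(b, abs=1e-6)
        assert fit.coefficient_a == pytest.approx(a, rel=1e-6)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-6)

    def test_rejects_degenerate_inputs(self):
        with pytest.raises(ValueError):
            fit_power_law([(1, 5.0)])
        with pytest.raises(ValueError):
            fit_power_law([(1, 5.0), (1, 6.0)])

    def test_scale_free_fits_better_than_random_null(self):
        sf = scale_free_graph(600, 2, seed=9)
        fit_sf = fit_power_law(degree_histogram(sf))
        er = random_graph(600, 2 * sf.n_edges / (600 * 599), seed=9)
        fit_er = fit_power_law(degree_histogram(er))
        assert fit_sf.exponent_b < 0
        assert fit_sf.r_squared > fit_er.r_squared


class TestClustering:
    def test_triangle_vertices_fully_clustered(self, triangle):
        assert clustering_coefficient(triangle, "A") == 1.0
        assert average_clustering(triangle) == 1.0

    def test_star_centre_unclustered(self, star5):
        assert clustering_coefficient(star5, "Z") == 0.0

    def test_matches_neighbour_pair_enumeration(self):
        net = random_graph(30, 0.3, seed=1)
        oracle = clustering_oracle(net.nodes, net.edges)
        for v in net.nodes:
            assert clustering_coefficient(net, v) == pytest.approx(oracle[v])


class TestPathLength:
    def test_three_node_path(self, path_abc):
        assert characteristic_path_length(path_abc) == pytest.approx(4 / 3)

    @pytest.mark.parametrize("n", [2, 3, 5, 8])
    def test_complete_graph_is_one(self, n):
        net = net_from_edges([(f"N{i}", f"N{j}")
                              for i in range(n) for j in range(i + 1, n)])
        assert characteristic_path_length(net) == 1.0

    def test_matches_floyd_warshall_on_random_graph(self):
        net = random_graph(25, 0.15, seed=8)
        assert characteristic_path_length(net) == pytest.approx(
            path_length_oracle(net.nodes, net.edges))

    def test_disconnected_pairs_are_excluded(self):
        net = net_from_edges([("A", "B")], extra_nodes=["C"])
        assert characteristic_path_length(net) == 1.0

    def test_no_connected_pair_is_an_error(self):
        with pytest.raises(ValueError):
            characteristic_path_length(net_from_edges([], extra_nodes=["A", "B"]))


class TestBetweenness:
    def test_path_middle_carries_one_pair(self, path_abc):
        assert betweenness(path_abc) == {"A": 0.0, "B": 1.0, "C": 0.0}

    def test_star_centre_carries_all_leaf_pairs(self, star5):
        assert betweenness(star5)["Z"] == 6.0

    def test_matches_path_enumeration_on_random_graph(self):
        net = random_graph(10, 0.35, seed=4)
        oracle = betweenness_oracle(net.nodes, net.edges)
        got = betweenness(net)
        for v in net.nodes:
            assert got[v] == pytest.approx(oracle[v], abs=1e-9)


class TestHarmonicCloseness:
    def test_star_centre(self):
        net = net_from_edges([("Z", l) for l in "ABC"])
        assert harmonic_closeness(net)["Z"] == 3.0

    def test_path_end(self, path_abc):
        assert harmonic_closeness(path_abc)["A"] == pytest.approx(1.5)

    def test_matches_bfs_reciprocal_sums(self):
        net = random_graph(20, 0.2, seed=6)
        oracle = harmonic_closeness_oracle(net.nodes, net.edges)
        got = harmonic_closeness(net)
        for v in net.nodes:
            assert got[v] == pytest.approx(oracle[v])


class TestBottleneck:
    def test_isolated_nodes_score_zero(self):
        net = net_from_edges([], extra_nodes=["A", "B"])
        assert bottleneck_scores(net) == {"A": 0, "B": 0}

    def test_star_centre_counted_from_each_leaf_root(self, star5):
        # from each of the 4 leaf roots the centre's subtree holds 4 of the
        # 5 tree nodes (> 5/4); leaves only ever hold themselves
        scores = bottleneck_scores(star5)
        assert scores["Z"] == 4
        assert all(scores[l] == 0 for l in "ABCD")

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_independent_tree_walk_on_random_graphs(self, seed):
        net = random_graph(9, 0.3, seed=seed)
        assert bottleneck_scores(net) == bottleneck_oracle(net.nodes, net.edges)


class TestSummarize:
    def test_complete_graph_k4(self):
        net = net_from_edges([(a, b) for a in "ABCD" for b in "ABCD" if a < b])
        s = summarize(net)
        assert (s.n_nodes, s.n_edges) == (4, 6)
        assert s.average_degree == 3.0
        assert s.average_clustering == 1.0
        assert s.characteristic_path_length == 1.0

    def test_path_graph(self, path_abc):
        s = summarize(path_abc)
        assert s.average_clustering == 0.0
        assert s.characteristic_path_length == pytest.approx(4 / 3)

    def test_degree_sum_is_twice_edge_count(self):
        net = random_graph(50, 0.1, seed=3)
        assert sum(net.degree(v) for v in net.nodes) == 2 * net.n_edges
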