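"""Network summary statistics: analytic cases, oracle agreement, monotonicity."""

import math

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import oracles
from mitosocial.netstats import (
    UndefinedStatisticError,
    diameter,
    efficiency,
    mean_betweenness,
    mean_degree,
    n_components,
    summarize_network,
    summarize_series,
)
from mitosocial.network import EncounterNetwork, build_network, network_series
from mitosocial.simulate import SimulationConfig, simulate_cell


def graph_of(n, edges):
    g = nx.Graph()
    g.add_nodes_from(range(n))
    g.add_edges_from(edges)
    return g


class TestAnalyticCases:
    @pytest.mark.parametrize("n", range(2, 11))
    def test_complete_graph_efficiency_one(self, n):
        assert efficiency(nx.complete_graph(n)) == pytest.approx(1.0, abs=1e-12)

    def test_path3_efficiency_five_sixths(self):
        # pairs at hop distance (1, 1, 2): mean reciprocal = 5/6
        assert efficiency(nx.path_graph(3)) == pytest.approx(5.0 / 6.0, abs=1e-12)

    @pytest.mark.parametrize("k", [2, 3, 5, 9])
    def test_path_diameter(self, k):
        assert diameter(nx.path_graph(k)) == k - 1

    def test_complete_graph_diameter_one(self):
        assert diameter(nx.complete_graph(6)) == 1

    def test_complete_graph_mean_degree(self):
        assert mean_degree(nx.complete_graph(5)) == pytest.approx(4.0)

    def test_path3_mean_degree(self):
        assert mean_degree(nx.path_graph(3)) == pytest.approx(4.0 / 3.0)

    def test_star_mean_betweenness_unnormalized(self):
        # 4 leaves: C(4,2)=6 leaf pairs all route via the hub -> mean 6/5
        g = nx.star_graph(4)
        assert mean_betweenness(g, normalized=False) == pytest.approx(1.2, abs=1e-12)

    def test_complete_graph_betweenness_zero(self):
        assert mean_betweenness(nx.complete_graph(7)) == pytest.approx(0.0, abs=1e-12)

    def test_two_triangles_components_and_diameter(self):
        g = graph_of(6, [(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5)])
        assert n_components(g) == 2
        assert diameter(g) == 1  # largest-component convention

    def test_isolated_nodes_count_as_components(self):
        g = graph_of(7, [(0, 1), (1, 2), (2, 3), (0, 3)])  # K4-ish + 3 isolated
        assert n_components(g) == 4

    def test_mean_degree_isolated_node_modes(self):
        g = graph_of(3, [(0, 1)])
        assert mean_degree(g, include_isolated=True) == pytest.approx(2.0 / 3.0)
        assert mean_degree(g, include_isolated=False) == pytest.approx(1.0)


class TestUndefinedSignals:
    def test_empty_graph(self):
        with pytest.raises(UndefinedStatisticError):
            mean_degree(nx.Graph())
        assert n_components(nx.Graph()) == 0

    def test_single_node_efficiency_undefined(self):
        with pytest.raises(UndefinedStatisticError):
            efficiency(graph_of(1, []))

    def test_edgeless_diameter_undefined(self):
        with pytest.raises(UndefinedStatisticError):
            diameter(graph_of(4, []))

    def test_small_graph_betweenness_zero(self):
        assert mean_betweenness(graph_of(2, [(0, 1)])) == 0.0

    def test_summary_turns_undefined_into_nan(self):
        net = EncounterNetwork(graph_of(3, []), window=(0, 9), threshold_um=1.6)
        s = summarize_network(net)
        assert math.isnan(s.efficiency) or s.efficiency == 0.0  # edgeless: eff 0 defined
        assert math.isnan(s.diameter)
        assert s.n_components == 3
        assert s.mean_degree == 0.0


@settings(max_examples=60, deadline=None, derandomize=True)
@given(seed=st.integers(0, 10_000))
def test_all_statistics_match_brute_force_oracles(seed):
    """Property: the five statistics agree with Floyd–Warshall / path-count
    oracles on random graphs of up to 50 nodes."""
    rng = np.random.default_rng(seed)
    n, edges = oracles.random_graph(rng, max_nodes=50)
    g = graph_of(n, edges)

    assert mean_degree(g) == pytest.approx(oracles.oracle_mean_degree(n, edges), abs=1e-12)
    assert efficiency(g) == pytest.approx(oracles.oracle_efficiency(n, edges), abs=1e-12)
    assert n_components(g) == oracles.oracle_n_components(n, edges)

    want_diam = oracles.oracle_diameter_largest_component(n, edges)
    if math.isnan(want_diam):
        with pytest.raises(UndefinedStatisticError):
            diameter(g)
    else:
        assert diameter(g) == int(want_diam)

    want_bc = oracles.oracle_betweenness(n, edges)
    assert mean_betweenness(g) == pytest.approx(float(want_bc.mean()), abs=1e-9)


@settings(max_examples=40, deadline=None, derandomize=True)
@given(seed=st.integers(0, 10_000))
def test_edge_addition_monotonicity(seed):
    """Adding one edge with the node set fixed never decreases efficiency or
    mean degree, and never increases the component count."""
    rng = np.random.default_rng(seed)
    n, edges = oracles.random_graph(rng, max_nodes=25)
    g = graph_of(n, edges)
    missing = [
        (i, j) for i in range(n) for j in range(i + 1, n) if not g.has_edge(i, j)
    ]
    if not missing or n < 2:
        return
    extra = missing[int(rng.integers(len(missing)))]
    g2 = g.copy()
    g2.add_edge(*extra)

    assert efficiency(g2) >= efficiency(g) - 1e-12
    assert mean_degree(g2) >= mean_degree(g)
    assert n_components(g2) <= n_components(g)


class TestSeries:
    def test_nested_networks_efficiency_nondecreasing_with_fixed_nodes(self):
        # force a fixed node set by using a simulated cell where every track
        # spans all frames; only edges accumulate over checkpoints
        for seed in range(20):
            sim = simulate_cell(SimulationConfig(n_mito=20, n_frames=40, seed=seed))
            series = network_series(sim.cell.mito, 1.6, checkpoints=(9, 19, 29, 39))
            assert len({net.n_nodes for net in series}) == 1
            summaries = summarize_series(series)
            effs = [s.efficiency for s in summaries]
            degs = [s.mean_degree for s in summaries]
            assert all(b >= a - 1e-12 for a, b in zip(effs, effs[1:]))
            assert all(b >= a for a, b in zip(degs, degs[1:]))

    def test_single_and_empty_series(self):
        sim = simulate_cell(SimulationConfig(n_mito=10, n_frames=10, seed=2))
        one = summarize_series(network_series(sim.cell.mito, 1.6, checkpoints=(9,)))
        assert len(one) == 1
        assert one[0].window_end_frame == 9
        assert summarize_series([]) == []

    def test_summary_bookkeeping_consistent(self):
        sim = simulate_cell(SimulationConfig(n_mito=30, n_frames=30, seed=8))
        net = build_network(sim.cell.mito, 1.6)
        s = summarize_network(net)
        assert s.n_nodes == net.n_nodes and s.n_edges == net.n_edges
        assert s.mean_degree == pytest.approx(2 * s.n_edges / s.n_nodes)
        assert 0.0 <= s.efficiency <= 1.0
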