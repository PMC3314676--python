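import math

import numpy as np
import pytest

from conftest import directed_chain, directed_cycle, out_star
from oracles import (
    local_reach_directed_oracle,
    local_reach_undirected_oracle,
    local_reach_weighted_oracle,
    random_digraph,
    random_undirected_graph,
    random_weighted_digraph,
)

from hiernet.errors import LookupNodeError, UsageError
from hiernet.graph_core import Network, read_edge_list
from hiernet.reaching import (
    local_reach_directed,
    local_reach_undirected,
    local_reach_weighted,
    reach_distribution,
    reach_profile,
)


class TestLocalReachDirected:
    def test_chain_interior_node(self):
        net = directed_chain(5)
        assert local_reach_directed(net, "v1") == 0.75  # 3 of 4 nodes downstream

    def test_isolated_node_reaches_nothing(self):
        net = Network(nodes=("a", "b", "z"), edges={("a", "b"): 1.0}, directed=True)
        assert local_reach_directed(net, "z") == 0.0

    def test_star_center_reaches_all(self):
        assert local_reach_directed(out_star(10), "c") == 1.0

    def test_unknown_node_raises(self):
        with pytest.raises(LookupNodeError):
            local_reach_directed(directed_chain(3), "nope")

    def test_single_node_convention(self):
        net = Network(nodes=("a",), edges={}, directed=True)
        assert local_reach_directed(net, "a") == 0.0


class TestLocalReachWeighted:
    def test_max_weight_shortest_path_rule(self):
        # two hop-2 routes to j; the heavier one (via a) must be used
        net = Network.from_edges(
            [("i", "a", 1.0), ("i", "b", 0.1), ("a", "j", 1.0), ("b", "j", 0.1)]
        )
        assert math.isclose(local_reach_weighted(net, "i"), 0.7)

    def test_single_weighted_edge(self):
        net = Network.from_edges([("i", "j", 0.5)])
        assert local_reach_weighted(net, "i") == 0.5

    @pytest.mark.parametrize("seed", range(10))
    def test_unit_weights_recover_unweighted(self, seed):
        net = random_digraph(np.random.default_rng(seed))
        for node in net.nodes:
            assert local_reach_weighted(net, node) == local_reach_directed(net, node)

    def test_requires_directed(self):
        und = read_edge_list("a b", directed=False)
        with pytest.raises(UsageError):
            local_reach_weighted(und, "a")


class TestLocalReachUndirected:
    def test_path_endpoint(self):
        net = read_edge_list("a b\nb c", directed=False)
        assert local_reach_undirected(net, "a") == 0.75  # (1 + 1/2) / 2

    def test_complete_graph(self):
        labels = [f"v{i}" for i in range(5)]
        net = Network.from_edges(
            [(u, v) for i, u in enumerate(labels) for v in labels[i + 1 :]],
            directed=False,
        )
        assert all(local_reach_undirected(net, n) == 1.0 for n in labels)

    def test_disconnected_node_contributes_zero(self):
        net = Network(nodes=("a", "b", "z"), edges={("a", "b"): 1.0}, directed=False)
        assert local_reach_undirected(net, "z") == 0.0

    def test_requires_undirected(self):
        with pytest.raises(UsageError):
            local_reach_undirected(read_edge_list("a b"), "a")


class TestOracleAgreement:
    """Dual-route checks against brute-force computations."""

    @pytest.mark.parametrize("seed", range(30))
    def test_directed_matches_matrix_powering(self, seed):
        net = random_digraph(np.random.default_rng(seed))
        prof = reach_profile(net, "directed")
        for node in net.nodes:
            assert math.isclose(prof.values[node], local_reach_directed_oracle(net, node))
            assert math.isclose(local_reach_directed(net, node), prof.values[node])

    @pytest.mark.parametrize("seed", range(30))
    def test_weighted_matches_path_enumeration(self, seed):
        net = random_weighted_digraph(np.random.default_rng(seed))
        for node in net.nodes:
            assert math.isclose(
                local_reach_weighted(net, node), local_reach_weighted_oracle(net, node)
            )

    @pytest.mark.parametrize("seed", range(30))
    def test_undirected_matches_bfs_harmonic(self, seed):
        net = random_undirected_graph(np.random.default_rng(seed))
        prof = reach_profile(net, "undirected")
        for node in net.nodes:
            assert math.isclose(prof.values[node], local_reach_undirected_oracle(net, node))


class TestReachProfile:
    def test_out_star_grc_is_one(self):
        assert reach_profile(out_star(10), "directed").grc == 1.0

    def test_directed_cycle_grc_is_zero(self):
        assert reach_profile(directed_cycle(10), "directed").grc == 0.0

    def test_chain_values_and_grc(self):
        prof = reach_profile(directed_chain(5), "directed")
        assert sorted(prof.values.values()) == [0.0, 0.25, 0.5, 0.75, 1.0]
        assert prof.grc == 0.625
        assert prof.c_max == 1.0

    @pytest.mark.parametrize("n", range(3, 21))
    def test_chain_closed_form(self, n):
        assert math.isclose(reach_profile(directed_chain(n)).grc, n / (2 * (n - 1)))

    def test_relabeling_invariance(self):
        rng = np.random.default_rng(42)
        net = random_digraph(rng)
        perm = {n: f"x{k}" for k, n in enumerate(rng.permutation(net.nodes))}
        relabeled = Network.from_edges(
            [(perm[u], perm[v]) for u, v in net.edges],
            extra_nodes=[perm[n] for n in net.nodes],
        )
        assert math.isclose(reach_profile(net).grc, reach_profile(relabeled).grc)

    def test_undirected_input_bidirected_for_directed_variant(self):
        und = read_edge_list("a b\nb c", directed=False)
        prof = reach_profile(und, "directed")
        assert prof.grc == 0.0  # everyone reaches everyone after bidirection

    def test_single_node_grc_zero(self):
        net = Network(nodes=("a",), edges={}, directed=True)
        assert reach_profile(net).grc == 0.0

    def test_weighted_on_undirected_is_usage_error(self):
        with pytest.raises(UsageError):
            reach_profile(read_edge_list("a b", directed=False), "weighted")


class TestReachDistribution:
    def test_out_star_mass_split(self):
        centers, freqs = reach_distribution(reach_profile(out_star(10)), bins=10)
        assert math.isclose(freqs.sum(), 1.0)
        assert math.isclose(freqs[0], 10 / 11)  # leaves at 0
        assert math.isclose(freqs[-1], 1 / 11)  # center at 1

    def test_cycle_all_mass_at_one(self):
        _, freqs = reach_distribution(reach_profile(directed_cycle(8)), bins=50)
        assert math.isclose(freqs[-1], 1.0)

    def test_tree_distribution_is_bottom_heavy(self):
        from hiernet.generators import random_arborescence

        freq_sum = np.zeros(50)
        for seed in range(50):
            prof = reach_profile(random_arborescence(200, 5, seed=seed).net)
            _, freqs = reach_distribution(prof, bins=50)
            freq_sum += freqs
        freq_mean = freq_sum / 50
        # heavy-tailed near zero: the lowest bin dominates every other bin
        assert freq_mean[0] > 0.5
        assert freq_mean[0] > freq_mean[1:].max()
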