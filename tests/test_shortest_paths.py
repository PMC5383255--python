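"""Seed-pair shortest paths and the inner-node betweenness count."""

import itertools

import networkx as nx
import numpy as np
import pytest

import netprio as npr
from netprio.errors import ValidationError
from netprio.shortest_paths import (ALL_TIES, SINGLE, betweenness,
                                    betweenness_counts,
                                    seed_pair_shortest_paths, sp_candidates)

from conftest import random_weighted_records


def brute_force_min_paths(net, a, b):
    """Exhaustive enumeration of all simple a-b paths; returns (min weight, tied paths)."""
    best, ties = None, []
    for path in nx.all_simple_paths(net.graph, a, b):
        w = sum(net.weight(u, v) for u, v in zip(path, path[1:]))
        if best is None or w < best:
            best, ties = w, [tuple(path)]
        elif w == best:
            ties.append(tuple(path))
    return best, sorted(ties)


def _random_sp_case(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(4, 11))
    recs, names = random_weighted_records(rng, n, 0.4)
    net = npr.build_network(recs, mode="transformed")
    k = int(rng.integers(2, min(4, n) + 1))
    seeds = npr.SeedSet(tuple(sorted(rng.choice(names, size=k, replace=False))))
    return net, seeds


class TestSeedPairShortestPaths:
    def test_adjacent_seeds_have_empty_inner_nodes(self):
        net = npr.build_network([npr.InteractionRecord("s1", "s2", 900)],
                                mode="transformed")
        paths = seed_pair_shortest_paths(net, npr.SeedSet(("s1", "s2")))
        assert len(paths) == 1
        assert paths[0].inner_nodes == () and paths[0].total_weight == 100

    def test_four_cycle_tie_modes(self):
        # a-b-c-d-a with equal weights; seeds a and c sit opposite
        recs = [npr.InteractionRecord(u, v, 500)
                for u, v in [("a", "b"), ("b", "c"), ("c", "d"), ("d", "a")]]
        net = npr.build_network(recs, mode="transformed")
        seeds = npr.SeedSet(("a", "c"))
        all_ties = seed_pair_shortest_paths(net, seeds, ALL_TIES)
        single = seed_pair_shortest_paths(net, seeds, SINGLE)
        assert len(all_ties) == 2 and len(single) == 1
        # deterministic tie-break: lexicographically smallest node sequence
        assert single[0].inner_nodes == ("b",)

    def test_disconnected_pairs_are_skipped_not_fatal(self):
        recs = [npr.InteractionRecord("a", "b", 500),
                npr.InteractionRecord("c", "d", 500)]
        net = npr.build_network(recs, mode="transformed")
        paths = seed_pair_shortest_paths(net, npr.SeedSet(("a", "c")))
        assert paths == []

    def test_raw_mode_network_rejected(self, path_network):
        with pytest.raises(ValidationError):
            seed_pair_shortest_paths(path_network, npr.SeedSet(("a", "c")))

    @pytest.mark.parametrize("case_seed", range(10))
    def test_matches_exhaustive_enumeration(self, case_seed):
        net, seeds = _random_sp_case(case_seed)
        paths = seed_pair_shortest_paths(net, seeds, ALL_TIES)
        by_pair = {}
        for p in paths:
            by_pair.setdefault((p.seed_a, p.seed_b), []).append(p)
        for a, b in itertools.combinations(sorted(seeds.ids), 2):
            best, ties = brute_force_min_paths(net, a, b)
            got = by_pair.get((a, b), [])
            assert sorted((a,) + p.inner_nodes + (b,) for p in got) == ties
            for p in got:
                assert p.total_weight == best

    @pytest.mark.parametrize("case_seed", range(10))
    def test_dijkstra_distances_match_bellman_ford(self, case_seed):
        net, seeds = _random_sp_case(case_seed + 100)
        g = net.graph
        for a, b in itertools.combinations(sorted(seeds.ids), 2):
            try:
                d_dij = nx.dijkstra_path_length(g, a, b, weight="weight")
            except nx.NetworkXNoPath:
                continue
            d_bf = nx.bellman_ford_path_length(g, a, b, weight="weight")
            assert d_dij == d_bf


class TestBetweenness:
    def test_star_hub_counts_all_seed_pairs(self, star_network):
        seeds = npr.SeedSet(tuple(f"leaf{i}" for i in range(4)))
        paths = seed_pair_shortest_paths(star_network, seeds)
        table = betweenness(paths, seeds)
        assert table == {"hub": 6}  # C(4, 2)

    def test_adjacent_seed_pair_yields_empty_table(self):
        net = npr.build_network([npr.InteractionRecord("s1", "s2", 900)],
                                mode="transformed")
        seeds = npr.SeedSet(("s1", "s2"))
        assert betweenness(seed_pair_shortest_paths(net, seeds), seeds) == {}

    @pytest.mark.parametrize("case_seed", range(8))
    def test_seed_genes_never_enter_the_table(self, case_seed):
        net, seeds = _random_sp_case(case_seed + 50)
        table = betweenness(seed_pair_shortest_paths(net, seeds), seeds)
        assert not set(table) & seeds.as_set()

    @pytest.mark.parametrize("case_seed", range(8))
    def test_total_count_conservation(self, case_seed):
        # sum of betweenness equals total non-seed inner-node slots over paths
        net, seeds = _random_sp_case(case_seed + 200)
        paths = seed_pair_shortest_paths(net, seeds)
        table = betweenness(paths, seeds)
        slots = sum(
            sum(1 for n in p.inner_nodes if n not in seeds.as_set()) for p in paths
        )
        assert sum(table.values()) == slots

    @pytest.mark.parametrize("case_seed", range(12))
    def test_sigma_counting_matches_path_enumeration(self, case_seed):
        # independent route: Dijkstra multiplicity counting vs explicit paths
        net, seeds = _random_sp_case(case_seed + 300)
        via_paths = betweenness(seed_pair_shortest_paths(net, seeds, ALL_TIES), seeds)
        via_counts = betweenness_counts(net, seeds)
        assert via_paths == via_counts

    def test_relabeling_invariance_in_all_ties_mode(self):
        net, seeds = _random_sp_case(77)
        rename = {n: f"zz_{n}" for n in net.node_order}
        recs = [npr.InteractionRecord(rename[u], rename[v], s) for u, v, s in net.edges()]
        net2 = npr.build_network(recs, mode="transformed")
        seeds2 = npr.SeedSet(tuple(sorted(rename[s] for s in seeds.ids)))
        t1 = betweenness_counts(net, seeds)
        t2 = betweenness_counts(net2, seeds2)
        assert {rename[g]: c for g, c in t1.items()} == t2


class TestSpCandidates:
    def test_single_entry_table(self):
        cands = sp_candidates({"hub": 6})
        assert len(cands) == 1
        assert cands[0].gene == "hub" and cands[0].statistic == 6.0

    def test_empty_table(self):
        assert sp_candidates({}) == []

    def test_record_carries_full_reporting_schema(self):
        # the result-table layout: statistic, p-value, MIS, MFS and flags
        rec = sp_candidates({"g": 3})[0]
        for field in ("gene", "statistic", "p_value", "mis", "mfs"):
            assert hasattr(rec, field)

    def test_sorted_by_count_then_id(self):
        cands = sp_candidates({"b": 2, "a": 2, "c": 9})
        assert [c.gene for c in cands] == ["c", "a", "b"]
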