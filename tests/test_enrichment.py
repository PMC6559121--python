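from __future__ import annotations

import itertools

import networkx as nx
import numpy as np
import pytest

from netbridge import enrichment as en
from netbridge import synthetic_data as sd

from conftest import random_connected_graph
from oracles import hypergeom_tail_enumeration, hypergeom_tail_oracle


def ten_node_case() -> nx.Graph:
    """Candidate 'c' with degree 3 in a 10-node connected graph."""
    g = nx.Graph()
    others = [f"o{i}" for i in range(9)]
    g.add_edges_from(zip(others, others[1:]))
    g.add_edges_from([("c", "o0"), ("c", "o1"), ("c", "o5")])
    return g


class TestNeighborEnrichmentP:
    def test_zero_overlap_gives_p_one(self, toy_graph):
        rec = en.neighbor_enrichment_p(toy_graph, "2", {"6", "7"})
        assert rec.overlap == 0 and rec.p == 1.0

    def test_worked_ten_node_example(self):
        # degree 3, set of 4 non-candidate members, overlap 2:
        # p = [C(4,2)C(5,1)+C(4,3)C(5,0)]/C(9,3) = 34/84
        g = ten_node_case()
        members = {"o0", "o1", "o2", "o3"}
        rec = en.neighbor_enrichment_p(g, "c", members)
        assert rec.degree == 3 and rec.overlap == 2
        assert rec.p == pytest.approx(34 / 84, abs=1e-12)

    def test_perfect_overlap_is_single_term_minimum(self):
        # neighbors exactly equal the set: p = 1/C(N-1, k)
        g = nx.Graph()
        others = [f"o{i}" for i in range(7)]
        g.add_edges_from(zip(others, others[1:]))
        g.add_edges_from([("c", "o0"), ("c", "o1"), ("c", "o2")])
        rec = en.neighbor_enrichment_p(g, "c", {"o0", "o1", "o2"})
        from math import comb

        assert rec.p == pytest.approx(1 / comb(7, 3), rel=1e-12)

    def test_candidate_excluded_from_set_and_universe(self):
        g = ten_node_case()
        with_self = en.neighbor_enrichment_p(g, "c", {"c", "o0", "o1"})
        without = en.neighbor_enrichment_p(g, "c", {"o0", "o1"})
        assert with_self == without

    def test_matches_exhaustive_enumeration_small_populations(self, rng):
        # every (population<=12, successes, draws, overlap) case realisable
        # on a star-augmented graph, against literal subset enumeration
        for n_nodes in (6, 9, 12):
            g = random_connected_graph(n_nodes, 3 * n_nodes, rng)
            nodes = sorted(g.nodes)
            for _ in range(20):
                cand = nodes[int(rng.integers(len(nodes)))]
                k = int(rng.integers(1, n_nodes - 1))
                members = set(rng.choice([n for n in nodes if n != cand], size=k, replace=False))
                rec = en.neighbor_enrichment_p(g, cand, members)
                expect = hypergeom_tail_enumeration(
                    [n for n in nodes if n != cand], members, rec.degree, rec.overlap
                )
                assert rec.p == pytest.approx(expect, rel=1e-9)

    def test_p_nonincreasing_in_overlap(self):
        # fixed degree and set size, varying overlap via the closed form
        pops = [
            hypergeom_tail_oracle(30, 8, 6, k) for k in range(0, 7)
        ]
        assert all(a >= b for a, b in zip(pops, pops[1:]))

    def test_isolated_candidate_rejected(self):
        g = nx.Graph()
        g.add_node("c")
        g.add_edge("a", "b")
        with pytest.raises(ValueError):
            en.neighbor_enrichment_p(g, "c", {"a"})


class TestSelection:
    def make_planted(self, seed: int):
        spec = sd.NetworkSpec(
            n_nodes=150,
            n_edges=350,
            anchor="CFTR",
            sets=(
                sd.PlantedSetSpec("s1", size=12, frac_distance1=0.5),
                sd.PlantedSetSpec("s2", size=12, frac_distance1=0.5),
            ),
        )
        net, truth = sd.generate_network(spec, seed=seed)
        return net, truth

    def plant_hub(self, net, truth):
        """A node adjacent to every member of both sets and nothing else."""
        hub = "HUB"
        net.add_node(hub)
        for label in ("s1", "s2"):
            for m in truth.set_members[label]:
                net.add_edge(hub, m)
        return hub

    def test_planted_hub_selected_with_top_rank(self):
        hits = 0
        for seed in range(20):
            net, truth = self.make_planted(seed)
            hub = self.plant_hub(net, truth)
            ranked, _ = en.select_specific_neighbors(
                net, truth.set_members, en.SelectionConfig()
            )
            names = [rc.candidate for rc in ranked]
            if hub in names:
                hits += 1
        assert hits >= 19  # selected in >=95% of seeds

    def test_below_cross_interaction_threshold_excluded(self):
        # candidate with only 2 edges into each set is excluded regardless of p
        g = nx.Graph()
        s1 = [f"a{i}" for i in range(4)]
        s2 = [f"b{i}" for i in range(4)]
        chain = s1 + s2 + ["z"]
        g.add_edges_from(zip(chain, chain[1:]))
        g.add_edges_from([("x", "a0"), ("x", "a1"), ("x", "b0"), ("x", "b1")])
        ranked, _ = en.select_specific_neighbors(
            g,
            {"s1": set(s1), "s2": set(s2)},
            en.SelectionConfig(top_fraction=1.0, min_cross_interactions=3),
        )
        assert "x" not in [rc.candidate for rc in ranked]

    def test_qualification_invariant_to_set_order(self, rng):
        net, truth = self.make_planted(3)
        sets = truth.set_members
        r1, _ = en.select_specific_neighbors(net, dict(sets))
        r2, _ = en.select_specific_neighbors(
            net, dict(reversed(list(sets.items())))
        )
        assert [rc.candidate for rc in r1] == [rc.candidate for rc in r2]

    def test_selection_bounded_by_cross_interaction_pool(self):
        net, truth = self.make_planted(5)
        cfg = en.SelectionConfig()
        ranked, _ = en.select_specific_neighbors(net, truth.set_members, cfg)
        eligible = 0
        for cand in net.nodes:
            n_ok = sum(
                1
                for members in truth.set_members.values()
                if sum(1 for n in net[cand] if n in members - {cand}) >= 3
            )
            if n_ok >= cfg.min_sets:
                eligible += 1
        assert len(ranked) <= eligible

    def test_rank_convention_flip(self):
        net, truth = self.make_planted(7)
        hub = self.plant_hub(net, truth)
        default, _ = en.select_specific_neighbors(
            net, truth.set_members, en.SelectionConfig()
        )
        flipped, _ = en.select_specific_neighbors(
            net,
            truth.set_members,
            en.SelectionConfig(best_p_gets_largest_rank=False),
        )
        assert {rc.candidate for rc in default} == {rc.candidate for rc in flipped}
        # hub is the strongest candidate: first under the default convention
        assert default[0].candidate == hub

    def test_requires_at_least_two_sets(self, toy_graph):
        with pytest.raises(ValueError):
            en.select_specific_neighbors(toy_graph, {"only": {"1"}})
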