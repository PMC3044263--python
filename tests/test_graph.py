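"""Reference-graph construction and the penalized shortest-path metric."""

import networkx as nx
import pytest

from conftest import brute_force_path_distance, run_path_oracle_trials
from pathfill.graph import (
    build_linkage_graph,
    build_reference_graph,
    effective_edge_weight,
    penalized_shortest_path,
)
from pathfill.model import (
    HomologyHit,
    OperonPair,
    Params,
    ValidationError,
)


def simple_graph(edges):
    """edges: iterable of (a, b, kind, weight)."""
    g = nx.Graph()
    for a, b, kind, w in edges:
        g.add_edge(a, b, kind=kind, weight=w)
    return g


class TestBuildReferenceGraph:
    def test_two_genome_example(self, make_catalog, params):
        cat = make_catalog({"G1": ["a1", "a2"], "G2": ["b1"]})
        pairs = [OperonPair("G1", "a1", "a2", 0.9)]
        hits = [HomologyHit("a1", "b1", 1e-37)]
        g = build_reference_graph(cat, pairs, hits, params)
        assert g.number_of_edges() == 2
        assert g["a1"]["a2"]["weight"] == pytest.approx(0.1)
        assert g["a1"]["a2"]["kind"] == "operon"
        assert g["a1"]["b1"]["weight"] == pytest.approx(1 - 37 / 185)
        assert g["a1"]["b1"]["kind"] == "similarity"

    def test_intra_genome_hit_produces_no_edge(self, make_catalog, params):
        cat = make_catalog({"G1": ["a1", "a2", "a3"]})
        g = build_reference_graph(cat, [], [HomologyHit("a1", "a3", 1e-99)],
                                  params)
        assert g.number_of_edges() == 0
        assert g.number_of_nodes() == 3  # isolated vertices retained

    def test_evalue_cutoff_filters_weak_hits(self, make_catalog, params):
        cat = make_catalog({"G1": ["a1"], "G2": ["b1"]})
        g = build_reference_graph(cat, [], [HomologyHit("a1", "b1", 0.01)],
                                  params)
        assert g.number_of_edges() == 0

    def test_asymmetric_hits_symmetrized_by_min(self, make_catalog, params):
        cat = make_catalog({"G1": ["a1"], "G2": ["b1"]})
        hits = [HomologyHit("a1", "b1", 1e-37), HomologyHit("b1", "a1", 1e-74)]
        g = build_reference_graph(cat, [], hits, params)
        assert g["a1"]["b1"]["weight"] == pytest.approx(1 - 74 / 185)

    def test_operon_pair_spanning_genomes_rejected(self, make_catalog, params):
        cat = make_catalog({"G1": ["a1", "a2"], "G2": ["b1"]})
        with pytest.raises(ValidationError):
            build_reference_graph(
                cat, [OperonPair("G2", "a1", "a2", 0.9)], [], params
            )


class TestPenalizedShortestPath:
    def test_single_operon_edge_closed_form(self, params):
        g = simple_graph([("a", "b", "operon", 0.25)])
        p = penalized_shortest_path(g, "a", "b", params)
        assert p.distance == pytest.approx(0.25 + params.system_error)
        assert p.k == 1

    def test_single_similarity_edge_alpha_rescaled(self, params):
        g = simple_graph([("a", "b", "similarity", 0.8)])
        p = penalized_shortest_path(g, "a", "b", params)
        assert p.distance == pytest.approx(
            0.8 * 185 / 380 + params.system_error
        )

    def test_two_hop_route_beats_direct_edge(self, params):
        # 0.1 + 0.1 + 2*0.06 = 0.32 < 0.5 + 0.06 = 0.56
        g = simple_graph([
            ("a", "m", "operon", 0.1),
            ("m", "b", "operon", 0.1),
            ("a", "b", "operon", 0.5),
            ("b", "x", "operon", 0.9),
            ("x", "y", "operon", 0.9),
        ])
        p = penalized_shortest_path(g, "a", "b", params)
        assert p.distance == pytest.approx(0.32)
        assert p.vertices == ("a", "m", "b")

    def test_heavy_penalty_flips_route_choice(self):
        g = simple_graph([
            ("a", "m", "operon", 0.1),
            ("m", "b", "operon", 0.1),
            ("a", "b", "operon", 0.5),
        ])
        p = penalized_shortest_path(g, "a", "b", Params(system_error=0.5))
        assert p.vertices == ("a", "b")

    def test_disconnected_pair_undefined(self, params):
        g = simple_graph([("a", "b", "operon", 0.1)])
        g.add_node("z")
        assert penalized_shortest_path(g, "a", "z", params) is None

    def test_source_equals_target_rejected(self, params):
        g = simple_graph([("a", "b", "operon", 0.1)])
        with pytest.raises(ValidationError):
            penalized_shortest_path(g, "a", "a", params)

    def test_zero_penalty_equals_classic_shortest_path(self, params):
        g = simple_graph([
            ("a", "m", "operon", 0.2),
            ("m", "b", "operon", 0.2),
            ("a", "b", "operon", 0.3),
        ])
        p0 = penalized_shortest_path(g, "a", "b", params.with_(system_error=0))
        classic = nx.shortest_path_length(g, "a", "b", weight="weight")
        assert p0.distance == pytest.approx(classic)

    def test_alpha_scope_all_scales_operon_edges_too(self):
        g = simple_graph([("a", "b", "operon", 0.4)])
        p = penalized_shortest_path(
            g, "a", "b", Params(alpha_scope="all", system_error=0.0)
        )
        assert p.distance == pytest.approx(0.4 * 185 / 380)

    def test_alpha_zero_drops_similarity_edges(self, params):
        g = simple_graph([
            ("a", "b", "similarity", 0.1),
            ("a", "m", "operon", 0.4),
            ("m", "b", "operon", 0.4),
        ])
        p = penalized_shortest_path(g, "a", "b", params.with_(alpha=0.0))
        assert p.vertices == ("a", "m", "b")

    def test_tie_break_prefers_fewer_edges_then_lexicographic(self):
        params = Params(system_error=0.0)
        g = simple_graph([
            ("a", "b", "operon", 0.4),
            ("a", "m", "operon", 0.2),
            ("m", "b", "operon", 0.2),
        ])
        p = penalized_shortest_path(g, "a", "b", params)
        assert p.vertices == ("a", "b")
        g2 = simple_graph([
            ("a", "m", "operon", 0.2),
            ("m", "b", "operon", 0.2),
            ("a", "n", "operon", 0.2),
            ("n", "b", "operon", 0.2),
        ])
        p2 = penalized_shortest_path(g2, "a", "b", params)
        assert p2.vertices == ("a", "m", "b")


class TestOracleEquivalence:
    def test_matches_exhaustive_enumeration(self):
        compared, worst = run_path_oracle_trials(60, seed=1234)
        assert compared > 10
        assert worst < 1e-9

    def test_penalty_monotonicity_on_random_graphs(self):
        import numpy as np

        from conftest import random_reference_graph

        rng = np.random.default_rng(99)
        for _ in range(30):
            g = random_reference_graph(rng)
            vs = sorted(g.nodes)
            s, t = vs[0], vs[-1]
            if s == t:
                continue
            lo = penalized_shortest_path(g, s, t, Params(system_error=0.0))
            hi = penalized_shortest_path(g, s, t, Params(system_error=0.2))
            if lo is None:
                assert hi is None
            else:
                assert hi.distance >= lo.distance - 1e-12

    def test_isolated_vertex_changes_nothing(self, params):
        g = simple_graph([
            ("a", "m", "operon", 0.1),
            ("m", "b", "similarity", 0.3),
        ])
        before = penalized_shortest_path(g, "a", "b", params).distance
        g.add_node("zzz")
        after = penalized_shortest_path(g, "a", "b", params).distance
        assert after == before


class TestLinkageGraph:
    @pytest.fixture
    def chain_setup(self, make_catalog):
        # target gene t0 connected to t1..t9 through a reference operon chain
        cat = make_catalog({
            "T": [f"t{i}" for i in range(12)],
            "R": [f"r{i}" for i in range(12)],
        })
        pairs = [OperonPair("R", f"r{i}", f"r{i+1}", 0.95) for i in range(11)]
        hits = [HomologyHit(f"t{i}", f"r{i}", 1e-100) for i in range(10)]
        g = build_reference_graph(cat, pairs, hits, Params())
        return cat, g

    def test_top_k_truncation_matches_sort_oracle(self, chain_setup):
        cat, g = chain_setup
        params = Params(K=5)
        lg = build_linkage_graph(g, cat, "T", ["t0"], params)
        top = lg.top("t0")
        assert len(top) == 5
        # oracle: distances to every reachable target gene, sorted
        all_d = sorted(
            (penalized_shortest_path(g, "t0", f"t{i}", params).distance, f"t{i}")
            for i in range(1, 10)
        )
        assert [gene for gene, _ in top] == [gene for _, gene in all_d[:5]]
        assert all(
            d == pytest.approx(expected)
            for (_, d), (expected, _) in zip(top, all_d)
        )

    def test_fewer_than_k_candidates(self, make_catalog):
        cat = make_catalog({"T": ["t0", "t1", "t2", "t3"], "R": ["r0", "r1"]})
        pairs = [OperonPair("R", "r0", "r1", 0.99)]
        hits = [HomologyHit("t0", "r0", 1e-50), HomologyHit("t1", "r1", 1e-50)]
        g = build_reference_graph(cat, pairs, hits, Params())
        lg = build_linkage_graph(g, cat, "T", ["t0"], Params(K=5))
        assert [gene for gene, _ in lg.top("t0")] == ["t1"]

    def test_seed_not_its_own_candidate(self, chain_setup):
        cat, g = chain_setup
        lg = build_linkage_graph(g, cat, "T", ["t0"], Params())
        assert "t0" not in {gene for gene, _ in lg.top("t0")}

    def test_empty_seed_set_rejected(self, chain_setup):
        cat, g = chain_setup
        with pytest.raises(ValidationError):
            build_linkage_graph(g, cat, "T", [], Params())

    def test_retained_distance_bounded_by_kth(self, chain_setup):
        cat, g = chain_setup
        lg = build_linkage_graph(g, cat, "T", ["t0"], Params(K=3))
        top = lg.top("t0")
        kth = top[-1][1]
        assert all(d <= kth for _, d in top)
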