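"""Reaction-graph construction rules, statistics and export."""

from fractions import Fraction

import networkx as nx
import numpy as np
import pytest

from compartgem.model import Model, Reaction
from compartgem.netgraph import (
    average_path_length,
    build_graph,
    compartment_unique_metabolites,
    density,
    diameter,
    export_graph,
)

from oracles import oracle_graph_stats


def _two_step(reversible_second=False):
    m = Model()
    for base in "ABC":
        m.add_metabolite(base, "c")
    m.add_reaction(Reaction("R1", {"A[c]": Fraction(-1), "B[c]": Fraction(1)}, reversible=False))
    m.add_reaction(
        Reaction("R2", {"B[c]": Fraction(-1), "C[c]": Fraction(1)}, reversible=reversible_second)
    )
    m.currency_list = frozenset()
    return m


class TestBuildRules:
    def test_irreversible_chain_gives_one_directed_edge(self):
        g = build_graph(_two_step())
        assert set(g.edges) == {("R1", "R2")}

    def test_reversible_consumer_does_not_add_back_edge(self):
        # A->B, B<->C: both orientations of R2 contribute roles independently,
        # but R1 never consumes anything R2 can produce
        g = build_graph(_two_step(reversible_second=True))
        assert set(g.edges) == {("R1", "R2")}

    def test_two_reversible_reactions_link_both_ways(self):
        m = _two_step(reversible_second=True)
        m.reactions["R1"].reversible = True
        m.reactions["R1"].lower_bound = -1000.0
        g = build_graph(m)
        assert set(g.edges) == {("R1", "R2"), ("R2", "R1")}

    def test_currency_metabolite_forms_no_edge(self):
        m = Model()
        m.add_metabolite("A", "c")
        m.add_metabolite("atp", "c")
        m.add_metabolite("B", "c")
        m.add_reaction(Reaction("R1", {"A[c]": Fraction(-1), "atp[c]": Fraction(1)}, reversible=False))
        m.add_reaction(Reaction("R2", {"atp[c]": Fraction(-1), "B[c]": Fraction(1)}, reversible=False))
        assert set(build_graph(m).edges) == set()
        # with an empty currency list the edge appears
        assert set(build_graph(m, currency_list=()).edges) == {("R1", "R2")}

    def test_shared_metabolite_must_match_compartment(self):
        m = Model()
        m.add_metabolite("A", "c")
        m.add_metabolite("B", "c")
        m.add_metabolite("B", "m")
        m.add_metabolite("C", "m")
        m.currency_list = frozenset()
        m.add_reaction(Reaction("R1", {"A[c]": Fraction(-1), "B[c]": Fraction(1)}, reversible=False))
        m.add_reaction(Reaction("R2", {"B[m]": Fraction(-1), "C[m]": Fraction(1)}, reversible=False))
        assert set(build_graph(m).edges) == set()

    def test_growing_currency_list_only_removes_edges(self, syn_models):
        model, _ = syn_models
        full = set(build_graph(model, currency_list=()).edges)
        default = set(build_graph(model).edges)
        bigger = set(
            build_graph(model, currency_list=set(model.currency_list) | {"nut0"}).edges
        )
        assert default <= full
        assert bigger <= default


class TestStatistics:
    def test_complete_digraph_density_one(self):
        g = nx.complete_graph(3, create_using=nx.DiGraph)
        assert density(g) == 1.0

    def test_chain_density_and_paths(self):
        g = nx.DiGraph([("R1", "R2"), ("R2", "R3")])
        assert density(g) == pytest.approx(2 / 6)
        assert diameter(g) == 2
        assert average_path_length(g) == pytest.approx((1 + 1 + 2) / 3)

    def test_directed_four_cycle(self):
        g = nx.cycle_graph(4, create_using=nx.DiGraph)
        assert diameter(g) == 3
        assert average_path_length(g) == pytest.approx(2.0)

    def test_unreachable_pairs_are_excluded_not_infinite(self):
        g = nx.DiGraph()
        g.add_edge("a", "b")
        g.add_node("c")  # isolated
        assert diameter(g) == 1
        assert average_path_length(g) == pytest.approx(1.0)

    def test_single_node_graph_errors(self):
        g = nx.DiGraph()
        g.add_node("only")
        with pytest.raises(ValueError):
            density(g)
        with pytest.raises(ValueError):
            diameter(g)

    def test_agrees_with_floyd_warshall_on_random_digraphs(self):
        rng = np.random.default_rng(42)
        for _ in range(25):
            n = int(rng.integers(2, 9))
            p = float(rng.uniform(0.2, 0.8))
            g = nx.gnp_random_graph(n, p, directed=True, seed=int(rng.integers(2**31)))
            g = nx.relabel_nodes(g, {i: f"n{i}" for i in g.nodes})
            dens_o, diam_o, apl_o = oracle_graph_stats(g)
            assert density(g) == pytest.approx(dens_o)
            if diam_o == -1:
                with pytest.raises(ValueError):
                    diameter(g)
            else:
                assert diameter(g) == diam_o
                assert average_path_length(g) == pytest.approx(apl_o)

    def test_invariant_under_relabelling(self):
        g = nx.gnp_random_graph(7, 0.4, directed=True, seed=3)
        h = nx.relabel_nodes(g, {i: f"x{i}" for i in g.nodes})
        assert density(g) == density(h)
        assert diameter(g) == diameter(h)
        assert average_path_length(g) == pytest.approx(average_path_length(h))


class TestUniqueMetabolites:
    def test_multi_compartment_metabolite_not_reported(self):
        m = Model()
        m.add_metabolite("A", "c")
        m.add_metabolite("A", "m")
        m.add_metabolite("B", "r")
        m.currency_list = frozenset()
        unique = compartment_unique_metabolites(m)
        assert unique == {"r": {"B"}}

    def test_matches_generator_ground_truth(self, syn_models):
        model, truth = syn_models
        assert compartment_unique_metabolites(model) == truth.unique_compartment


class TestExport:
    @pytest.mark.parametrize("fmt,reader", [("graphml", nx.read_graphml), ("gml", nx.read_gml)])
    def test_round_trip_preserves_structure(self, tmp_path, fmt, reader, syn_model):
        model, _ = syn_model
        g = build_graph(model)
        path = tmp_path / f"graph.{fmt}"
        export_graph(g, str(path), fmt)
        back = reader(str(path))
        assert set(back.nodes) == set(g.nodes)
        assert set(back.edges) == set(g.edges)
        any_node = next(iter(back.nodes))
        assert "compartments" in back.nodes[any_node]

    def test_unknown_format_rejected(self, tmp_path, chain_model):
        g = build_graph(chain_model)
        with pytest.raises(ValueError):
            export_graph(g, str(tmp_path / "g.dot"), "dot")
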