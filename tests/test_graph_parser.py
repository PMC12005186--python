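"""Coarse-graph dialect: nodes, edges, branches, rings, sugar, annotations."""

import networkx as nx
import pytest
from hypothesis import given, settings, strategies as st

import cgline as cg
from cgline.graph_parser import tokenize


class TestTokenizer:
    def test_plain_nodes(self):
        tokens = tokenize("[#PEO][#PEO]")
        assert [t[0] for t in tokens] == ["NODE", "NODE"]

    def test_multiplication_token(self):
        tokens = tokenize("[#PEO]|4")
        assert tokens[-1][:2] == ("MULTIPLY", 4)

    @pytest.mark.parametrize("bad", ["[#A](", "[#A", "[#A] [#B]", "[#A]£", "[]"])
    def test_malformed_input_positions(self, bad):
        with pytest.raises(cg.ParseError):
            cg.parse_cg_graph(bad)


class TestParse:
    def test_peg_polymer_path(self):
        graph = cg.parse_cg_graph("[#OH][#PEO]|4[#OH]")
        labels = [graph.nodes[n]["label"] for n in graph.nodes]
        assert labels == ["OH", "PEO", "PEO", "PEO", "PEO", "OH"]
        assert nx.is_connected(graph) and graph.number_of_edges() == 5
        assert all(graph.degree(n) <= 2 for n in graph.nodes)

    def test_single_node(self):
        graph = cg.parse_cg_graph("[#A]")
        assert graph.number_of_nodes() == 1 and graph.number_of_edges() == 0

    def test_crown_ether_cycle(self):
        graph = cg.parse_cg_graph("[#PEO]1[#PEO]|4[#PEO]1")
        assert graph.number_of_nodes() == 6
        assert sorted(len(c) for c in nx.cycle_basis(graph)) == [6]

    def test_period_is_virtual_edge_not_disconnection(self):
        graph = cg.parse_cg_graph("[#A].[#B]")
        assert graph.number_of_edges() == 1
        assert graph[0][1]["order"] == 0

    def test_charge_annotation(self):
        graph = cg.parse_cg_graph("[#SN4a;q=-1]")
        assert graph.nodes[0]["label"] == "SN4a"
        assert graph.nodes[0]["annotations"]["q"] == -1

    def test_positional_annotations_q_then_w(self):
        graph = cg.parse_cg_graph("[#A;0;1.5]")
        assert graph.nodes[0]["annotations"] == {"q": 0, "w": 1.5}

    def test_percent_marker_consumes_all_digits(self):
        graph = cg.parse_cg_graph("[#A]%123[#B][#C]%123")
        assert graph.has_edge(0, 2)

    def test_bond_orders(self):
        graph = cg.parse_cg_graph("[#A]=[#B]#[#C]$[#D]")
        orders = [graph[u][v]["order"] for u, v in cg.ordered_edges(graph)]
        assert orders == [2, 3, 4]

    def test_branch_attachment(self):
        # connection after a closed branch links to the branching point
        graph = cg.parse_cg_graph("[#A][#B]([#C])[#D]")
        assert set(graph.neighbors(1)) == {0, 2, 3}

    def test_edge_list_order_is_appearance_order(self):
        graph = cg.parse_cg_graph("[#A]1[#B][#C]1[#D]")
        assert cg.ordered_edges(graph) == [(0, 1), (1, 2), (0, 2), (2, 3)]

    def test_ring_marker_reuse(self):
        graph = cg.parse_cg_graph("[#A]1[#B]1[#C]1[#D]1")
        assert graph.number_of_edges() == 5
        assert graph.has_edge(0, 2) and graph.has_edge(1, 3)

    @pytest.mark.parametrize("bad", [
        "[#A]1[#B]",              # unmatched ring marker
        "[#A]|0",                 # factor < 1
        "|3[#A]",                 # multiplication without target
        "[#A]=",                  # dangling bond
        "[#A;1;2;3]",             # too many positional annotations
        "[#A]1=[#B]#1",           # conflicting ring bond orders
    ])
    def test_errors(self, bad):
        with pytest.raises(cg.ParseError):
            cg.parse_cg_graph(bad)

    def test_multiplication_limit(self):
        with pytest.raises(cg.ParseError):
            cg.parse_cg_graph("[#A]|99", max_multiplication=10)


class TestMultiplication:
    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(min_value=1, max_value=10),
           st.text(alphabet="ABC123", min_size=1, max_size=4))
    def test_node_multiplication_equals_repetition(self, n, label):
        sugar = cg.parse_cg_graph(f"[#{label}]|{n}")
        explicit = cg.parse_cg_graph(f"[#{label}]" * n)
        assert cg.cg_isomorphic(sugar, explicit)

    def test_branch_multiplication(self):
        sugar = cg.parse_cg_graph("[#B]([#C])|2")
        explicit = cg.parse_cg_graph("[#B]([#C])[#B]([#C])")
        assert cg.cg_isomorphic(sugar, explicit)

    def test_branch_multiplication_brush(self):
        # polymer-brush idiom: backbone bead with grafted side chain, repeated
        sugar = cg.parse_cg_graph("[#A][#B]([#C][#C])|3")
        explicit = cg.parse_cg_graph(
            "[#A][#B]([#C][#C])[#B]([#C][#C])[#B]([#C][#C])")
        assert cg.cg_isomorphic(sugar, explicit)

    def test_inbound_order_is_cloned(self):
        graph = cg.parse_cg_graph("[#A]=[#B]|3")
        assert all(d["order"] == 2 for *_, d in graph.edges(data=True))
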