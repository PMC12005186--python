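"""Aromaticity normalization.

An assembled atomic graph may carry aromatic flags copied verbatim from its
fragments.  Flags are kept only for atoms participating in
delocalization-induced molecular equivalence (DIME): the delocalized system
must admit *at least two* alternating single/double assignments (perfect
matchings) that introduce no charges.  Systems with exactly one assignment
(thiophene, furan, pyrrole) are demoted to explicit single/double bonds;
systems with none are corrected where hydrogens can absorb the slack, and an
error is raised otherwise.

Kekule bond orders are always assigned, even for systems that stay aromatic,
because hydrogen completion needs concrete valences.
"""

import networkx as nx

from .elements import lowest_valence
from .errors import AromaticityError


def _bond_order_sum(graph, node):
    return sum(d.get("order", 1) for _, _, d in graph.edges(node, data=True))


def _double_bond_capacity(graph, node):
    """How many extra bond orders *node* can accept without charging."""
    data = graph.nodes[node]
    if data.get("charge", 0) != 0:
        return 0
    total = _bond_order_sum(graph, node) + data.get("hcount", 0)
    valence = lowest_valence(data["element"], total)
    if valence is None:
        return 0
    return valence - total


def _count_perfect_matchings(adjacency, nodes, cap=2):
    """Count perfect matchings (up to *cap*) and return one of them."""
    nodes = frozenset(nodes)

    def rec(remaining):
        if not remaining:
            return 1, []
        u = min(remaining, key=lambda n: len(adjacency[n] & remaining))
        candidates = adjacency[u] & remaining
        if not candidates:
            return 0, None
        total, first = 0, None
        for v in sorted(candidates):
            sub_count, sub_matching = rec(remaining - {u, v})
            if sub_count and first is None:
                first = sub_matching + [(u, v)]
            total += sub_count
            if total >= cap:
                return total, first
        return total, first

    return rec(nodes)


def normalize_aromaticity(graph):
    """Normalize aromatic flags and assign Kekule bond orders in place.

    Raises :class:`AromaticityError` when a flagged system can neither be
    kekulized nor corrected.
    """
    aromatic_atoms = {n for n, d in graph.nodes(data=True) if d.get("aromatic")}
    if not aromatic_atoms:
        return graph
    aromatic_edges = [(u, v) for u, v, d in graph.edges(data=True)
                      if d.get("aromatic") and u in aromatic_atoms and v in aromatic_atoms]
    for u, v in aromatic_edges:   # re-derive Kekule orders from scratch
        graph[u][v]["order"] = 1
    system = nx.Graph(aromatic_edges)
    system.add_nodes_from(aromatic_atoms)

    for component in nx.connected_components(system):
        eligible = {n for n in component if _double_bond_capacity(graph, n) >= 1}
        adjacency = {n: {m for m in system[n] if m in eligible} for n in eligible}
        count, matching = _count_perfect_matchings(adjacency, eligible, cap=2)
        if count == 0:
            cover = nx.max_weight_matching(nx.Graph(
                (u, v) for u in adjacency for v in adjacency[u]), maxcardinality=True)
            covered = {n for pair in cover for n in pair}
            uncovered = eligible - covered
            bad = [n for n in uncovered if "hcount" in graph.nodes[n]]
            if bad:
                raise AromaticityError(
                    f"aromatic assignment cannot be corrected: atoms {sorted(bad)} "
                    "can neither take a double bond nor extra hydrogens")
            matching, aromatic_kept = list(cover), False
        else:
            aromatic_kept = count >= 2
        for u, v in matching or ():
            graph[u][v]["order"] = 2
        if not aromatic_kept:
            for node in component:
                graph.nodes[node]["aromatic"] = False
            for u, v in system.edges(component):
                if graph.has_edge(u, v):
                    graph[u][v]["aromatic"] = False
    return graph
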