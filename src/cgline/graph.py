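"""Molecule graphs and helpers.

A molecule at one resolution is stored as a :class:`networkx.Graph`.

Node attributes (coarse dialect)
    ``label``        fragment name or bead type (``""`` for wildcards)
    ``is_wildcard``  bool
    ``annotations``  dict; only explicitly written keys are present
                     (``q`` charge, ``w`` weight, ``x`` chirality, ``s``
                     selection list, plus arbitrary user keys)

Node attributes (atomic dialect)
    ``element``   element symbol, ``"*"`` for a wildcard atom
    ``aromatic``  bool
    ``charge``    number (only if written)
    ``hcount``    explicit hydrogen count (only if written)
    ``weight``    mapping weight (only if written; default 1)
    ``chirality`` ``"R"`` or ``"S"`` (only if written)
    ``select``    list of selection tokens (wildcards only)
    ``isotope``   int (only if written)

Edge attributes
    ``order``   integer bond order 0-4 (0 = virtual edge)
    ``index``   insertion counter; the order of first appearance in the
                string is semantically meaningful and preserved everywhere
    ``aromatic``  bool, delocalized bond
    ``stereo`` / ``stereo_from``  cis/trans mark as written
"""

from itertools import count

import networkx as nx

_EDGE_COUNTER = "_edge_counter"
_NODE_COUNTER = "_node_counter"


def new_graph(**attrs):
    g = nx.Graph(**attrs)
    g.graph[_EDGE_COUNTER] = count()
    g.graph[_NODE_COUNTER] = count()
    return g


def add_node(g, **attrs):
    """Append a node with the next free integer id; returns the id."""
    if _NODE_COUNTER not in g.graph:
        g.graph[_NODE_COUNTER] = count(max(g.nodes, default=-1) + 1)
    node = next(g.graph[_NODE_COUNTER])
    g.add_node(node, **attrs)
    return node


def add_edge(g, u, v, order=1, **attrs):
    """Add an edge remembering its insertion index."""
    if _EDGE_COUNTER not in g.graph:
        g.graph[_EDGE_COUNTER] = count(
            1 + max((d.get("index", -1) for _, _, d in g.edges(data=True)), default=-1)
        )
    attrs.setdefault("written", (u, v))
    g.add_edge(u, v, order=order, index=next(g.graph[_EDGE_COUNTER]), **attrs)


def ordered_edges(g, data=False):
    """Edges sorted by first appearance in the source string."""
    edges = sorted(g.edges(data=True), key=lambda e: e[2].get("index", 0))
    if data:
        return edges
    return [(u, v) for u, v, _ in edges]


def ordered_neighbors(g, node):
    """Neighbors of *node* sorted by the incident edge's insertion index."""
    return sorted(g.neighbors(node), key=lambda nbr: g[node][nbr].get("index", 0))


def node_weight(g, node):
    data = g.nodes[node]
    if "weight" in data:
        return data["weight"]
    return data.get("annotations", {}).get("w", 1.0)


def node_charge(g, node):
    data = g.nodes[node]
    if "charge" in data:
        return data["charge"]
    return data.get("annotations", {}).get("q", 0.0)


def copy_graph(g):
    out = nx.Graph()
    out.add_nodes_from((n, dict(d)) for n, d in g.nodes(data=True))
    out.add_edges_from((u, v, dict(d)) for u, v, d in g.edges(data=True))
    for n, d in out.nodes(data=True):
        if "annotations" in d:
            d["annotations"] = dict(d["annotations"])
        if "select" in d and d["select"] is not None:
            d["select"] = list(d["select"])
    out.graph[_EDGE_COUNTER] = count(
        1 + max((d.get("index", -1) for _, _, d in out.edges(data=True)), default=-1)
    )
    out.graph[_NODE_COUNTER] = count(max(out.nodes, default=-1) + 1)
    return out


def _cg_node_match(a, b):
    return (
        a.get("label") == b.get("label")
        and a.get("is_wildcard", False) == b.get("is_wildcard", False)
        and a.get("annotations", {}) == b.get("annotations", {})
    )


def _cg_edge_match(a, b):
    return a.get("order", 1) == b.get("order", 1)


def cg_isomorphic(g1, g2):
    """Label-, annotation- and order-preserving isomorphism of coarse graphs."""
    return nx.is_isomorphic(g1, g2, node_match=_cg_node_match, edge_match=_cg_edge_match)


def _mol_node_match(a, b):
    return (
        a.get("element") == b.get("element")
        and bool(a.get("aromatic")) == bool(b.get("aromatic"))
        and a.get("charge", 0) == b.get("charge", 0)
    )


def _mol_edge_match(a, b):
    if bool(a.get("aromatic")) != bool(b.get("aromatic")):
        return False
    if a.get("aromatic"):
        # Kekule assignment within a delocalized system is not unique.
        return True
    return a.get("order", 1) == b.get("order", 1)


def mol_isomorphic(g1, g2):
    """Element/aromaticity/charge/bond-order preserving isomorphism."""
    return nx.is_isomorphic(g1, g2, node_match=_mol_node_match, edge_match=_mol_edge_match)


def graphs_identical(g1, g2):
    """Exact node/edge attribute equality (ignores internal counters)."""
    return (dict(g1.nodes(data=True)) == dict(g2.nodes(data=True))
            and {frozenset(e): d for *e, d in g1.edges(data=True)}
            == {frozenset(e): d for *e, d in g2.edges(data=True)})


def molecular_formula(g):
    """Hill-ordered molecular formula of an atomic graph (wildcards ignored)."""
    counts = {}
    for _, data in g.nodes(data=True):
        el = data.get("element", "*")
        if el == "*":
            continue
        counts[el] = counts.get(el, 0) + 1
    parts = []
    for el in ["C", "H"] + sorted(k for k in counts if k not in ("C", "H")):
        n = counts.get(el, 0)
        if n:
            parts.append(el + (str(n) if n > 1 else ""))
    return "".join(parts)


def heavy_atoms(g):
    return [n for n, d in g.nodes(data=True) if d.get("element") not in ("H", None)]
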