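"""Serializing graphs and layer stacks back to strings.

The writer guarantees an *isomorphic* round trip (labels, bond orders and
annotations preserved), not a byte-identical one: node order is kept, ring
markers are renumbered from the smallest free integer and the multiplication
sugar ``|n`` is never emitted.  Fragment bodies written in the atomic dialect
reproduce the printed form for simple strings (descriptors at their recorded
positions, including the prefix form ``[$]CC...``).

:func:`export_smiles` emits plain OpenSMILES for a finished molecule:
hydrogens are made implicit where standard, atoms stay lowercase only where
delocalization-induced equivalence holds, and ``x=R/S`` annotations are
converted to ``@``/``@@`` through a best-effort CIP ranking (atoms whose
substituents cannot be ranked keep no chirality mark; a warning is logged).
Extension attributes (weights, selections) are dropped on SMILES export.
"""

import logging

import networkx as nx

from . import graph as G
from .elements import ORGANIC_SUBSET, AROMATIC_ELEMENTS, implicit_hydrogens
from .errors import CGLineError
from .graph_parser import ORDER_SYMBOLS

LOGGER = logging.getLogger(__name__)


def format_number(value):
    if isinstance(value, float) and value.is_integer():
        return str(int(value))
    return str(value)


def _format_annotations(annotations):
    parts = []
    for key in ("q", "w", "x", "s"):
        if key not in annotations:
            continue
        value = annotations[key]
        if key == "q" and value == 0:
            continue
        if key == "w" and value == 1:
            continue
        if key == "s":
            parts.append(f";s={','.join(value)}")
        else:
            parts.append(f";{key}={format_number(value)}")
    for key in sorted(set(annotations) - {"q", "w", "x", "s"}):
        parts.append(f";{key}={annotations[key]}")
    return "".join(parts)


def _cg_token(graph, node):
    data = graph.nodes[node]
    head = "*" if data.get("is_wildcard") else "#" + data["label"]
    return f"[{head}{_format_annotations(data.get('annotations', {}))}]"


def _atom_token(graph, node, hcount_override=None):
    data = graph.nodes[node]
    element = data["element"]
    aromatic = data.get("aromatic", False)
    symbol = element.lower() if aromatic else element
    # explicitly written atom attributes are re-emitted verbatim (an explicit
    # w=1 stays, unlike coarse-node annotations where defaults are dropped)
    parts = []
    if "weight" in data:
        parts.append(f";w={format_number(data['weight'])}")
    if "chirality" in data:
        parts.append(f";x={data['chirality']}")
    if data.get("select") is not None:
        parts.append(f";s={','.join(data['select'])}")
    extra = "".join(parts)
    hcount = data.get("hcount") if hcount_override is None else hcount_override
    charge = data.get("charge", 0)
    plain_ok = (element in ORGANIC_SUBSET or element == "*") and charge == 0 \
        and "isotope" not in data and not extra and hcount is None \
        and not data.get("bracket") \
        and (not aromatic or element in {"B", "C", "N", "O", "P", "S"})
    if plain_ok:
        return symbol
    token = "["
    if "isotope" in data:
        token += str(data["isotope"])
    token += symbol
    if hcount:
        token += "H" + (str(hcount) if hcount != 1 else "")
    elif hcount == 0 and hcount_override is None and "hcount" in data:
        token += "H0"
    if charge:
        token += ("+" if charge > 0 else "-") + \
            (format_number(abs(charge)) if abs(charge) != 1 else "")
    token += extra + "]"
    return token


def _bond_symbol_cg(data, closing=False):
    return ORDER_SYMBOLS[data.get("order", 1)]


def _bond_symbol_atomic(data, from_node):
    if data.get("aromatic"):
        return ""
    if data.get("stereo"):
        symbol = data["stereo"]
        if data.get("stereo_from") is not None and data["stereo_from"] != from_node:
            symbol = "/" if symbol == "\\" else "\\"
        return symbol
    return ORDER_SYMBOLS[data.get("order", 1)]


class _Serializer:
    def __init__(self, graph, token_fn, bond_fn, descriptors=None,
                 neighbor_log=None):
        self.graph = graph
        self.token_fn = token_fn
        self.bond_fn = bond_fn
        self.descs = {}
        for desc in descriptors or ():
            self.descs.setdefault(desc.host, []).append(desc)
        for bucket in self.descs.values():
            bucket.sort(key=lambda d: d.written_position)
        self.markers_in_use = set()
        self.open_marker_of = {}      # frozenset(edge) -> marker
        self.neighbor_log = neighbor_log  # node -> emitted neighbor order

    def _next_marker(self):
        marker = 1
        while marker in self.markers_in_use:
            marker += 1
        self.markers_in_use.add(marker)
        return marker

    @staticmethod
    def _marker_text(marker):
        return str(marker) if marker < 10 else "%" + str(marker)

    def serialize(self, start):
        graph = self.graph
        visited = {start}
        tree_children = {}
        back_edges = {n: [] for n in graph.nodes}
        order = [start]
        stack = [start]
        parent = {start: None}
        while stack:
            node = stack.pop()
            children = []
            for nbr in G.ordered_neighbors(graph, node):
                if nbr == parent[node]:
                    continue
                if nbr in visited:
                    continue
                children.append(nbr)
            # find back edges (to already-ordered, non-parent nodes)
            tree_children[node] = children
            for child in reversed(children):
                visited.add(child)
                parent[child] = node
                stack.append(child)
                order.append(child)
        emitted = set()
        # back edges: any edge not parent-child
        tree = {frozenset((c, p)) for c, p in parent.items() if p is not None}
        for u, v in graph.edges:
            if frozenset((u, v)) not in tree:
                back_edges[u].append(v)
                back_edges[v].append(u)
        for node in back_edges:
            back_edges[node].sort(key=lambda nbr: graph[node][nbr].get("index", 0))

        out = []

        def emit(node, parent_node):
            emitted.add(node)
            neighbors_in_order = [] if parent_node is None else [parent_node]
            prefix_descs = [d for d in self.descs.get(node, ())
                            if d.prefix and parent_node is None]
            for desc in prefix_descs:
                out.append(desc.to_string())
                if desc.bond_order != 1:
                    out.append(ORDER_SYMBOLS[desc.bond_order])
            out.append(self.token_fn(self.graph, node))
            for partner in back_edges[node]:
                key = frozenset((node, partner))
                data = self.graph[node][partner]
                if key in self.open_marker_of:
                    marker = self.open_marker_of.pop(key)
                    out.append(self.bond_fn(data, node))
                    out.append(self._marker_text(marker))
                    self.markers_in_use.discard(marker)
                else:
                    marker = self._next_marker()
                    self.open_marker_of[key] = marker
                    out.append(self._marker_text(marker))
                neighbors_in_order.append(partner)
            for desc in self.descs.get(node, ()):
                if desc in prefix_descs:
                    continue
                if desc.bond_order != 1:
                    out.append(ORDER_SYMBOLS[desc.bond_order])
                out.append(desc.to_string())
            children = tree_children[node]
            if self.neighbor_log is not None:
                self.neighbor_log[node] = (parent_node, neighbors_in_order + children)
            for i, child in enumerate(children):
                bond = self.bond_fn(self.graph[node][child], node)
                if i < len(children) - 1:
                    out.append("(")
                    out.append(bond)
                    emit(child, node)
                    out.append(")")
                else:
                    out.append(bond)
                    emit(child, node)

        emit(start, None)
        return "".join(out)


def write_cg_graph(graph):
    """Serialize a coarse graph (deterministic, multiplication-free)."""
    if graph.number_of_nodes() == 0:
        raise CGLineError("cannot write an empty graph")
    if not nx.is_connected(graph):
        raise CGLineError("cannot write a disconnected coarse graph")
    start = min(graph.nodes)
    return _Serializer(graph, _cg_token, _bond_symbol_cg).serialize(start)


def write_fragment_body(fragment):
    """Serialize one fragment body in its own dialect."""
    graph = fragment.graph
    if not nx.is_connected(graph):
        raise CGLineError(f"fragment '{fragment.name}' is disconnected")
    start = min(graph.nodes)
    if fragment.dialect == "cg_graph":
        serializer = _Serializer(graph, _cg_token, _bond_symbol_cg,
                                 descriptors=fragment.descriptors)
    else:
        serializer = _Serializer(graph, _atom_token, _bond_symbol_atomic,
                                 descriptors=fragment.descriptors)
    return serializer.serialize(start)


def write_full(layers):
    """Serialize a full layer stack back to one string."""
    blocks = []
    if layers.base is not None:
        blocks.append("{" + write_cg_graph(layers.base) + "}")
    for fragments in layers.fragment_layers:
        entries = [f"#{name}={write_fragment_body(fragments[name])}"
                   for name in sorted(fragments)]
        blocks.append("{" + ",".join(entries) + "}")
    return ".".join(blocks)


# ---------------------------------------------------------------------------
# OpenSMILES export

def _fold_hydrogens(molecule):
    """Return (working copy, node -> folded implicit H count)."""
    work = G.copy_graph(molecule)
    folded = {}
    for node, data in list(work.nodes(data=True)):
        if data.get("element") != "H" or work.degree(node) != 1:
            continue
        if data.get("charge", 0) or "isotope" in data or "weight" in data:
            continue
        (neighbor,) = work.neighbors(node)
        if work.nodes[neighbor].get("element") in ("H", None, "*"):
            continue
        if work[node][neighbor].get("order", 1) != 1:
            continue
        folded[neighbor] = folded.get(neighbor, 0) + 1
        work.remove_node(node)
    return work, folded


def _cip_rank(molecule, center, neighbor, depth=8):
    """Comparable key approximating CIP priority of the *neighbor* branch."""
    def atomic_number(node):
        from .elements import ATOMIC_MASSES
        # mass order tracks Z well enough for ranking common elements
        element = molecule.nodes[node].get("element", "*")
        table = {"H": 1, "B": 5, "C": 6, "N": 7, "O": 8, "F": 9, "Si": 14,
                 "P": 15, "S": 16, "Cl": 17, "Br": 35, "I": 53, "Se": 34}
        return table.get(element, int(ATOMIC_MASSES.get(element, 0) // 2))

    if neighbor == "H":
        return ((1,),)
    levels = []
    frontier = [(center, neighbor)]
    for _ in range(depth):
        sphere = []
        next_frontier = []
        for came_from, node in frontier:
            z = atomic_number(node)
            sphere.append(z)
            for nbr in molecule.neighbors(node):
                if nbr == came_from:
                    continue
                next_frontier.append((node, nbr))
                extra = molecule[node][nbr].get("order", 1) - 1
                sphere.extend([atomic_number(nbr)] * extra)  # phantom atoms
        levels.append(tuple(sorted(sphere, reverse=True)))
        if not next_frontier:
            break
        frontier = next_frontier
    return tuple(levels)


def _permutation_parity(sequence, reference):
    perm = [reference.index(x) for x in sequence]
    parity = 0
    for i in range(len(perm)):
        for j in range(i + 1, len(perm)):
            if perm[i] > perm[j]:
                parity ^= 1
    return parity


def _chirality_symbol(molecule, node, log_entry, folded_h):
    """Translate an R/S annotation into @/@@ for the written order."""
    parent_node, written_neighbors = log_entry
    neighbors = list(written_neighbors)
    if folded_h:
        # an implicit H sits right after the preceding atom (first if none)
        neighbors.insert(0 if parent_node is None else 1, "H")
    if len(neighbors) != 4:
        LOGGER.warning("chiral atom %s does not have 4 substituents; mark dropped", node)
        return ""
    ranks = {n: _cip_rank(molecule, node, n) for n in neighbors}
    ordered = sorted(neighbors, key=lambda n: ranks[n], reverse=True)
    for a, b in zip(ordered, ordered[1:]):
        if ranks[a] == ranks[b]:
            LOGGER.warning("CIP tie at atom %s; chirality mark dropped", node)
            return ""
    p1, p2, p3, p4 = ordered
    parity = _permutation_parity(neighbors, [p4, p1, p2, p3])
    if molecule.nodes[node]["chirality"] == "R":
        return "@" if parity == 0 else "@@"
    return "@@" if parity == 0 else "@"


def export_smiles(molecule, *, chirality=True):
    """Write a finished atomic graph as an OpenSMILES string."""
    if any("element" not in d for _, d in molecule.nodes(data=True)):
        raise CGLineError("graph is not atomic; SMILES export needs the "
                          "finest resolution to be an atomic layer")
    work, folded = _fold_hydrogens(molecule)
    neighbor_log = {}

    def token(graph, node):
        data = graph.nodes[node]
        element = data.get("element")
        h = folded.get(node, 0)
        chiral = ""
        if chirality and data.get("chirality"):
            chiral = _chirality_symbol(work, node,
                                       neighbor_log.get(node, (None, [])),
                                       folded.get(node, 0))
        bondsum = sum(d.get("order", 1) for _, _, d in graph.edges(node, data=True))
        plain_ok = (element in ORGANIC_SUBSET and not chiral
                    and data.get("charge", 0) == 0 and "isotope" not in data
                    and h == implicit_hydrogens(element, bondsum)
                    and (not data.get("aromatic") or element in AROMATIC_ELEMENTS))
        symbol = element.lower() if data.get("aromatic") else element
        if element == "*" and not data.get("select"):
            return "*"
        if plain_ok:
            return symbol
        token_text = "[" + (str(data["isotope"]) if "isotope" in data else "")
        token_text += symbol + chiral
        if h:
            token_text += "H" + (str(h) if h != 1 else "")
        charge = data.get("charge", 0)
        if charge:
            token_text += ("+" if charge > 0 else "-") + \
                (format_number(abs(charge)) if abs(charge) != 1 else "")
        return token_text + "]"

    parts = []
    for component in nx.connected_components(work):
        sub = work.subgraph(component)
        start = min(component)
        if chirality and any(work.nodes[n].get("chirality") for n in component):
            # first pass records written neighbor order for the CIP step
            probe = _Serializer(sub, lambda g, n: "", _bond_symbol_atomic,
                                neighbor_log=neighbor_log)
            probe.serialize(start)
        serializer = _Serializer(sub, token, _bond_symbol_atomic)
        parts.append(serializer.serialize(start))
    return ".".join(parts)
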